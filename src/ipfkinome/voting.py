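"""Signal-to-noise weighted-voting classification of fibrosis severity.

The classifier follows the classic weighted-voting scheme for expression
class prediction. For each gene x with class means/SDs (mu, sigma) in the
severe (Ashcroft >= 6) and non-severe (< 6) strata:

    weight      S_x = (mu_pos - mu_neg) / (sigma_pos + sigma_neg)
    boundary    b_x = (mu_pos + mu_neg) / 2
    vote        V_x = S_x * (g_x - b_x)      for a test sample's value g_x

Genes enter the model when their class-mean difference crosses a threshold
(+t -> "induced", -t -> "suppressed"; t = 1 by default, so the study's
26/15 induced/suppressed split is a data outcome, not a constant). A test
sample is called severe when the summed vote is positive; an exact zero is
called non-severe (conservative tie policy) with a tie flag.

:class:`WeightedVotingClassifier` is a scikit-learn estimator (samples x
genes, ``fit``/``predict``/``decision_function``); the module-level
functions wrap it for the gene x sample expression containers and the
sample sheet, fitting on a single training patient's two Ashcroft strata
and scoring held-out samples.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .normalize import ExpressionMatrix
from .panel import SEVERE_ASHCROFT, SampleSheet, ValidationError

SCALES = ("rpkm", "log2")


def signal_to_noise(values_pos, values_neg, ddof: int = 0) -> float:
    """S = (mu_pos - mu_neg) / (sigma_pos + sigma_neg) for one gene."""
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each class needs at least 2 values for the "
                              "signal-to-noise statistic")
    denom = a.std(ddof=ddof) + b.std(ddof=ddof)
    if denom == 0:
        raise ValidationError("degenerate gene: both class SDs are zero")
    return float((a.mean() - b.mean()) / denom)


class WeightedVotingClassifier(ClassifierMixin, BaseEstimator):
    """Signal-to-noise weighted-voting classifier.

    Parameters
    ----------
    threshold : float, default=1.0
        Class-mean difference beyond which a gene is selected (induced when
        the positive-class mean exceeds the negative-class mean by more than
        ``threshold``, suppressed when it falls short by more).
    ddof : int, default=0
        Delta degrees of freedom for the class SDs (0 = population SD).
    positive_class : object, default=None
        Label treated as the positive (severe) class; defaults to the
        larger label under numpy ordering.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    selected_features_ : ndarray of selected feature indices
    weights_ : ndarray, signal-to-noise weight S_x per selected gene
    boundaries_ : ndarray, decision boundary b_x per selected gene
    gene_classes_ : ndarray of {"induced", "suppressed"} per selected gene
    mean_difference_ : ndarray, positive-minus-negative class mean per feature
    """

    def __init__(self, threshold: float = 1.0, ddof: int = 0,
                 positive_class=None):
        self.threshold = threshold
        self.ddof = ddof
        self.positive_class = positive_class

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(
                f"weighted voting is a two-class method; got {classes.shape[0]} "
                f"class(es)")
        pos = classes[-1] if self.positive_class is None else self.positive_class
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} not present in y")
        neg = classes[classes != pos][0]
        self.classes_ = np.array([neg, pos])
        Xp, Xn = X[y == pos], X[y == neg]
        if Xp.shape[0] < 2 or Xn.shape[0] < 2:
            raise ValueError("each class needs at least 2 training samples")
        mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
        sd_p = Xp.std(axis=0, ddof=self.ddof)
        sd_n = Xn.std(axis=0, ddof=self.ddof)
        diff = mu_p - mu_n
        self.mean_difference_ = diff
        sel = np.flatnonzero((diff > self.threshold) | (diff < -self.threshold))
        denom = sd_p[sel] + sd_n[sel]
        if np.any(denom == 0):
            bad = sel[denom == 0]
            names = (self.feature_names_in_[bad]
                     if hasattr(self, "feature_names_in_") else bad)
            raise ValueError(f"degenerate gene(s) with zero class SDs: "
                             f"{list(names)}")
        self.selected_features_ = sel
        self.weights_ = diff[sel] / denom
        self.boundaries_ = (mu_p[sel] + mu_n[sel]) / 2.0
        self.gene_classes_ = np.where(diff[sel] > 0, "induced", "suppressed")
        self.n_features_in_ = X.shape[1]
        return self

    def vote_matrix(self, X) -> np.ndarray:
        """Per-gene votes V_x = S_x (g_x - b_x), shape (n_samples, n_selected)."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}")
        G = X[:, self.selected_features_]
        return self.weights_ * (G - self.boundaries_)

    def decision_function(self, X) -> np.ndarray:
        """Summed weighted vote per sample; positive favours the severe class."""
        return self.vote_matrix(X).sum(axis=1)

    def predict(self, X):
        score = self.decision_function(X)
        if np.any(score == 0):
            warnings.warn("tie (total vote exactly 0) resolved to the "
                          "non-severe class", stacklevel=2)
        return np.where(score > 0, self.classes_[1], self.classes_[0])


@dataclasses.dataclass(frozen=True)
class WeightedVotingModel:
    """Fitted per-gene weights/boundaries plus training metadata."""

    table: pd.DataFrame  # index gene_id; columns class_label, weight, boundary
    training_patient: str
    positive_samples: tuple[str, ...]
    negative_samples: tuple[str, ...]
    threshold: float
    scale: str
    log_pseudocount: float
    severe_threshold: float = SEVERE_ASHCROFT

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def induced_genes(self) -> list[str]:
        return list(self.table.index[self.table["class_label"] == "induced"])

    @property
    def suppressed_genes(self) -> list[str]:
        return list(self.table.index[self.table["class_label"] == "suppressed"])

    def save(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"# training_patient: {self.training_patient}\n")
            fh.write(f"# threshold: {self.threshold}\n")
            fh.write(f"# scale: {self.scale}\n")
            fh.write(f"# log_pseudocount: {self.log_pseudocount}\n")
            fh.write(f"# severe_threshold: {self.severe_threshold}\n")
            fh.write(f"# positive_samples: {','.join(self.positive_samples)}\n")
            fh.write(f"# negative_samples: {','.join(self.negative_samples)}\n")
            self.table.to_csv(fh, sep=sep, index_label="gene_id",
                              float_format="%.10g")

    @classmethod
    def load(cls, path: str | Path, sep: str = "\t") -> "WeightedVotingModel":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
        table = pd.read_csv(path, sep=sep, comment="#", index_col=0)
        return cls(table=table,
                   training_patient=meta.get("training_patient", ""),
                   positive_samples=tuple(filter(None, meta.get(
                       "positive_samples", "").split(","))),
                   negative_samples=tuple(filter(None, meta.get(
                       "negative_samples", "").split(","))),
                   threshold=float(meta.get("threshold", 1.0)),
                   scale=meta.get("scale", "rpkm"),
                   log_pseudocount=float(meta.get("log_pseudocount", 1.0)),
                   severe_threshold=float(meta.get("severe_threshold",
                                                   SEVERE_ASHCROFT)))


def _scaled_values(expr: ExpressionMatrix, scale: str,
                   log_pseudocount: float) -> pd.DataFrame:
    if scale not in SCALES:
        raise ValidationError(f"unknown expression scale: {scale!r}")
    if scale == "rpkm":
        if expr.log_transformed:
            raise ValidationError("scale='rpkm' requires raw RPKM values")
        return expr.values
    if expr.log_transformed:
        return expr.values
    if log_pseudocount <= 0:
        raise ValidationError("log pseudocount must be positive")
    return np.log2(expr.values + log_pseudocount)


def _training_strata(sheet: SampleSheet, training_patient: str,
                     severe_threshold: float) -> tuple[list[str], list[str]]:
    samples = sheet.samples_of(training_patient)
    pos = [s for s in samples if sheet.frame.loc[s, "ashcroft_score"] >= severe_threshold]
    neg = [s for s in samples if sheet.frame.loc[s, "ashcroft_score"] < severe_threshold]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"training patient {training_patient!r} needs >= 2 samples in each "
            f"Ashcroft stratum (got {len(pos)} severe, {len(neg)} non-severe)")
    return pos, neg


def select_genes(expr: ExpressionMatrix, sheet: SampleSheet,
                 training_patient: str, threshold: float = 1.0,
                 scale: str = "rpkm", log_pseudocount: float = 1.0,
                 severe_threshold: float = SEVERE_ASHCROFT
                 ) -> tuple[list[str], list[str]]:
    """Induced / suppressed gene lists from one patient's two strata."""
    pos, neg = _training_strata(sheet, training_patient, severe_threshold)
    V = _scaled_values(expr, scale, log_pseudocount)
    diff = V[pos].mean(axis=1) - V[neg].mean(axis=1)
    induced = list(diff.index[diff > threshold])
    suppressed = list(diff.index[diff < -threshold])
    return induced, suppressed


def fit_model(expr: ExpressionMatrix, sheet: SampleSheet, training_patient: str,
              threshold: float = 1.0, scale: str = "rpkm",
              log_pseudocount: float = 1.0, ddof: int = 0,
              severe_threshold: float = SEVERE_ASHCROFT) -> WeightedVotingModel:
    """Fit weights and boundaries on the training patient's samples only."""
    pos, neg = _training_strata(sheet, training_patient, severe_threshold)
    V = _scaled_values(expr, scale, log_pseudocount)
    X = V[pos + neg].T  # samples x genes
    y = np.array(["severe"] * len(pos) + ["non_severe"] * len(neg))
    est = WeightedVotingClassifier(threshold=threshold, ddof=ddof,
                                   positive_class="severe").fit(X, y)
    genes = V.index[est.selected_features_]
    table = pd.DataFrame({
        "class_label": est.gene_classes_,
        "weight": est.weights_,
        "boundary": est.boundaries_,
    }, index=genes)
    table.index.name = "gene_id"
    return WeightedVotingModel(table=table, training_patient=training_patient,
                               positive_samples=tuple(pos),
                               negative_samples=tuple(neg),
                               threshold=threshold, scale=scale,
                               log_pseudocount=log_pseudocount,
                               severe_threshold=severe_threshold)


def vote_table(model: WeightedVotingModel, expr: ExpressionMatrix,
               samples=None) -> pd.DataFrame:
    """Per-gene votes V_x for each requested sample (genes x samples)."""
    V = _scaled_values(expr, model.scale, model.log_pseudocount)
    if samples is None:
        samples = list(V.columns)
    missing = [g for g in model.genes if g not in V.index]
    if missing:
        raise ValidationError(
            f"model gene(s) absent from expression matrix: {missing}")
    G = V.loc[model.genes, list(samples)]
    w = model.table["weight"]
    b = model.table["boundary"]
    return G.sub(b, axis=0).mul(w, axis=0)


def score_samples(model: WeightedVotingModel, expr: ExpressionMatrix,
                  samples=None) -> pd.DataFrame:
    """Summed vote, predicted class and tie flag per sample."""
    votes = vote_table(model, expr, samples)
    total = votes.sum(axis=0)
    tie = total == 0
    if tie.any():
        warnings.warn("tie (total vote exactly 0) resolved to non-severe",
                      stacklevel=2)
    out = pd.DataFrame({
        "total_score": total,
        "predicted_class": np.where(total > 0, "severe", "non_severe"),
        "tie": tie,
    })
    out.index.name = "sample_id"
    return out


@dataclasses.dataclass(frozen=True)
class ModelEvaluation:
    confusion: pd.DataFrame  # rows: true stratum, columns: predicted
    accuracy: float


def evaluate_model(scores: pd.DataFrame, sheet: SampleSheet,
                   severe_threshold: float = SEVERE_ASHCROFT) -> ModelEvaluation:
    """Confusion table and accuracy of predicted vs true Ashcroft stratum."""
    unknown = [s for s in scores.index if s not in sheet.frame.index]
    if unknown:
        raise ValidationError(f"sample(s) with unknown stratum: {unknown}")
    true = pd.Series({s: sheet.stratum_of(s, severe_threshold)
                      for s in scores.index})
    pred = scores["predicted_class"]
    labels = ["non_severe", "severe"]
    conf = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    conf.index.name = "true"
    conf.columns.name = "predicted"
    return ModelEvaluation(confusion=conf,
                           accuracy=float((true.values == pred.values).mean()))
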