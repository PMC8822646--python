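"""RPKM normalization and panel-level expression filters.

RPKM (reads per kilobase of transcript per million mapped reads) is the
classic within-sample normalization for targeted RNA panels:

    rpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * mapped_total[s])

The denominator uses the mapping-wide read total per sample, carried
explicitly by :class:`~ipfkinome.panel.CountMatrix`.

The module also implements the clinically-actionable subpanel filter: the
inhibitor-flagged genes are restricted to those whose summary RPKM is not
below the overall median RPKM of the full expression matrix, and the
excluded genes are reported.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CountMatrix, GenePanel, ValidationError, read_result_table

#: RPKM scale factor: kilobase (1e3) times per-million mapped reads (1e6).
RPKM_SCALE = 1e9


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values, genes x samples.

    ``log_transformed`` records whether the values are on the
    log2(RPKM + pseudocount) scale; raw RPKM matrices must be non-negative.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("expression matrix contains non-finite values")
        if not self.log_transformed and (v < 0).any():
            raise ValidationError("raw RPKM values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample ids in expression matrix")
        object.__setattr__(self, "values", self.values.astype(float))

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        v = self.values
        if genes is not None:
            missing = [g for g in genes if g not in v.index]
            if missing:
                raise KeyError(f"gene(s) absent from expression matrix: {missing}")
            v = v.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in v.columns]
            if missing:
                raise KeyError(f"sample(s) absent from expression matrix: {missing}")
            v = v[list(samples)]
        return ExpressionMatrix(v, self.log_transformed)


def compute_rpkm(counts: CountMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Convert raw counts to RPKM using panel transcript lengths."""
    missing = [g for g in counts.genes if g not in panel.frame.index]
    if missing:
        raise ValidationError(f"gene(s) absent from panel: {missing}")
    lengths = panel.lengths.loc[counts.genes].to_numpy(dtype=float)
    totals = counts.mapped_totals.to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValidationError("zero mapped total")
    rpkm = counts.counts.to_numpy(dtype=float) * RPKM_SCALE / (
        lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns))


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(RPKM + pseudocount); used for displays and clustering."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if expr.log_transformed:
        raise ValidationError("expression matrix is already log-transformed")
    return ExpressionMatrix(np.log2(expr.values + pseudocount), log_transformed=True)


def inverse_log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if not expr.log_transformed:
        raise ValidationError("expression matrix is not log-transformed")
    return ExpressionMatrix(np.exp2(expr.values) - pseudocount, log_transformed=False)


def overall_median(expr: ExpressionMatrix) -> float:
    """Median over all gene x sample entries of the matrix."""
    return float(np.median(expr.values.to_numpy()))


@dataclasses.dataclass(frozen=True)
class SubpanelFilterResult:
    """Surviving inhibitor subpanel plus the exclusion report.

    ``threshold`` records the overall-median cutoff actually applied, so the
    filter can be re-applied idempotently to its own output.
    """

    expression: ExpressionMatrix
    excluded: pd.DataFrame  # index gene; columns gene_summary, threshold, reason
    threshold: float
    summary: str


def filter_inhibitor_subpanel(expr: ExpressionMatrix, panel: GenePanel,
                              summary: str = "median",
                              reference_median: float | None = None,
                              ) -> SubpanelFilterResult:
    """Restrict to inhibitor-flagged genes above the overall median RPKM.

    A candidate gene survives when its per-gene summary RPKM (median across
    samples by default, mean selectable) is not lower than the overall
    median RPKM of the full matrix ``expr`` (or ``reference_median`` when
    given, e.g. the threshold recorded by a previous application).
    """
    if expr.log_transformed:
        raise ValidationError("subpanel filter operates on raw RPKM values")
    if summary not in ("median", "mean"):
        raise ValidationError(f"unknown summary convention: {summary!r}")
    flagged = set(panel.inhibitor_genes)
    present = [g for g in expr.genes if g in flagged]
    if not present:
        raise ValidationError("no inhibitor-flagged genes present in matrix")
    threshold = (overall_median(expr) if reference_median is None
                 else float(reference_median))
    sub = expr.values.loc[present]
    per_gene = sub.median(axis=1) if summary == "median" else sub.mean(axis=1)
    keep = per_gene >= threshold
    excluded = pd.DataFrame({
        "gene_summary": per_gene[~keep],
        "threshold": threshold,
        "reason": "below overall median RPKM",
    })
    excluded.index.name = "gene_id"
    return SubpanelFilterResult(
        expression=ExpressionMatrix(sub.loc[keep]),
        excluded=excluded,
        threshold=threshold,
        summary=summary,
    )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            sep: str = "\t") -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")


def read_expression_matrix(path: str | Path, sep: str = "\t",
                           log_transformed: bool = False) -> ExpressionMatrix:
    df = read_result_table(path, sep=sep)
    return ExpressionMatrix(df, log_transformed=log_transformed)
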