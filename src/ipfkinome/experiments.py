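"""Replicated simulation experiments quantifying pipeline behaviour.

Each function runs many seeded replicates of a documented synthetic study
condition and summarises how well a pipeline stage recovers the planted
structure (or how well it is calibrated under a null). They are used both
by the test suite and by ``scripts/acceptance.py``.

The selection/voting experiments evaluate the classifier on the
log2(RPKM + 0.1) scale: the planted severity effects are log2 effects and
the threshold-1 gene selection is scale-dependent, so the log2 scale with a
small pseudocount keeps a planted |log2 effect| of 2 above the selection
threshold across the panel's baseline range (see docs/methods.md).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import adjust_matrix, cluster_samples, compare_partitions
from .differential import two_sample_test
from .diversity import compute_diversity, test_group_diversity
from .normalize import ExpressionMatrix, compute_rpkm
from .simulate import (SimulationConfig, default_study_config,
                       exchangeable_null_config, low_noise_study_config,
                       null_calibration_config, simulate_dataset,
                       strong_separation_config)
from .voting import fit_model, score_samples, select_genes

#: Expression scale used by the recovery experiments (see module docstring).
VOTING_SCALE = "log2"
VOTING_LOG_PSEUDOCOUNT = 0.1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def classifier_holdout_recovery(n_reps: int = 100, seed: int = 0,
                                config: SimulationConfig | None = None,
                                training_patient: str = "IPF_1") -> dict:
    """Fit on the 6-sample patient's strata, score the other multi-sample
    IPF patients; report how often every held-out sample is sign-correct."""
    config = config or low_noise_study_config()
    all_correct = np.zeros(n_reps, dtype=bool)
    accuracies = np.zeros(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        model = fit_model(expr, ds.sheet, training_patient,
                          threshold=1.0, scale=VOTING_SCALE,
                          log_pseudocount=VOTING_LOG_PSEUDOCOUNT)
        held = [smp for p in ds.sheet.patients
                if p != training_patient and ds.sheet.group_of(p) == "IPF"
                and len(ds.sheet.samples_of(p)) >= 2
                for smp in ds.sheet.samples_of(p)]
        scores = score_samples(model, expr, held)
        truth = np.array([ds.sheet.stratum_of(smp) for smp in held])
        correct = scores["predicted_class"].to_numpy() == truth
        all_correct[i] = bool(correct.all())
        accuracies[i] = float(correct.mean())
    return {"all_correct_rate": float(all_correct.mean()),
            "mean_accuracy": float(accuracies.mean()),
            "n_reps": n_reps}


def gene_selection_recovery(n_reps: int = 100, seed: int = 0,
                            config: SimulationConfig | None = None,
                            training_patient: str = "IPF_1") -> dict:
    """Recovery of planted induced/suppressed genes by threshold-1 selection."""
    config = config or low_noise_study_config()
    sens = np.zeros(n_reps)
    n_false = np.zeros(n_reps)
    success = np.zeros(n_reps, dtype=bool)
    exact = np.zeros(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        induced, suppressed = select_genes(
            expr, ds.sheet, training_patient, threshold=1.0,
            scale=VOTING_SCALE, log_pseudocount=VOTING_LOG_PSEUDOCOUNT)
        true_ind = set(ds.truth.induced_genes)
        true_sup = set(ds.truth.suppressed_genes)
        hit = len(true_ind & set(induced)) + len(true_sup & set(suppressed))
        n_true = len(true_ind) + len(true_sup)
        false = (len(set(induced) - true_ind) + len(set(suppressed) - true_sup))
        sens[i] = hit / n_true
        n_false[i] = false
        success[i] = sens[i] >= 0.9 and false <= 2
        exact[i] = hit == n_true and false == 0
    return {"success_rate": float(success.mean()),
            "exact_recovery_rate": float(exact.mean()),
            "mean_sensitivity": float(sens.mean()),
            "mean_false_selections": float(n_false.mean()),
            "n_reps": n_reps}


def diversity_direction_rate(n_reps: int = 200, seed: int = 0,
                             multiplier: float = 3.0) -> dict:
    """How often IPF diversity exceeds control diversity (median summary)."""
    import dataclasses as _dc
    config = _dc.replace(default_study_config(), ipf_dispersion_multiplier=multiplier)
    positive = np.zeros(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        report = compute_diversity(expr, ds.sheet)
        res = test_group_diversity(report, ds.sheet)
        positive[i] = res.direction > 0
    return {"positive_direction_rate": float(positive.mean()), "n_reps": n_reps}


def diversity_null_rejection_rate(n_reps: int = 500, seed: int = 0,
                                  alpha: float = 0.05) -> dict:
    """Type-I error of the group diversity test under identical groups."""
    config = null_calibration_config()
    reject = np.zeros(n_reps, dtype=bool)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        report = compute_diversity(expr, ds.sheet)
        res = test_group_diversity(report, ds.sheet)
        reject[i] = res.p_value <= alpha
    rate = float(reject.mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {"rejection_rate": rate, "alpha": alpha, "se": se, "n_reps": n_reps}


def _true_stratum_labels(sheet) -> list[str]:
    return [sheet.stratum_of(s) for s in sheet.samples]


def clustering_agreement(n_reps: int = 100, seed: int = 0,
                         config: SimulationConfig | None = None,
                         ari_threshold: float = 0.8) -> dict:
    """How often a k=2 cut isolates the severe stratum under strong effects."""
    config = config or strong_separation_config()
    ari = np.zeros(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        adj = adjust_matrix(expr)
        dend = cluster_samples(adj)
        labels = dend.cut(2)
        ari[i] = compare_partitions(labels.values,
                                    _true_stratum_labels(ds.sheet))
    return {"agreement_rate": float((ari >= ari_threshold).mean()),
            "mean_ari": float(ari.mean()), "n_reps": n_reps}


def clustering_null_gap(n_reps: int = 100, seed: int = 0,
                        config: SimulationConfig | None = None) -> dict:
    """Mean ARI against true strata minus the permutation-null ARI, under
    the exchangeable null; near zero when severity carries no signal."""
    config = config or exchangeable_null_config()
    rng = np.random.default_rng(seed + 1)
    diffs = np.zeros(n_reps)
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        ds = simulate_dataset(config, seed=int(s))
        expr = compute_rpkm(ds.counts, ds.panel)
        labels = cluster_samples(adjust_matrix(expr)).cut(2).values
        truth = np.array(_true_stratum_labels(ds.sheet))
        perm = rng.permutation(truth)
        diffs[i] = (compare_partitions(labels, truth)
                    - compare_partitions(labels, perm))
    se = float(diffs.std(ddof=1) / np.sqrt(n_reps))
    return {"mean_gap": float(diffs.mean()), "se": se, "n_reps": n_reps}


def pvalue_uniformity_ks(n_genes: int = 1000, n_a: int = 10, n_b: int = 8,
                         seed: int = 0, mode: str = "welch") -> dict:
    """KS distance of null two-sample t-test p-values from uniform."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    a_ids = [f"A{i}" for i in range(n_a)]
    b_ids = [f"B{i}" for i in range(n_b)]
    values = rng.normal(10.0, 2.0, (n_genes, n_a + n_b))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=a_ids + b_ids),
                            log_transformed=True)
    res = two_sample_test(expr, a_ids, b_ids, mode=mode)
    ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
    return {"ks_distance": float(ks.statistic), "n_genes": n_genes}
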