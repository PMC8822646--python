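"""Within-patient gene-expression diversity.

Fibrotic lungs are spatially heterogeneous; sampling several segments of
the same patient therefore probes how variable the expression programme is
inside one lung. For each patient with at least two samples and each gene,
the diversity index is the range of that gene's RPKM across the patient's
samples, scaled by the gene's standard deviation over *all* samples:

    scaled_range[p, g] = (max_s rpkm[g, s in p] - min_s rpkm[g, s in p]) / sd_g

Patients contributing a single sample are excluded (a range needs two
values); genes with zero overall SD are dropped with a warning. Patient
level summaries (median / upper quartile / mean over genes) feed a
rank-based IPF-vs-control comparison.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .normalize import ExpressionMatrix
from .panel import GROUP_CONTROL, GROUP_IPF, SampleSheet, ValidationError


@dataclasses.dataclass(frozen=True)
class DiversityReport:
    long: pd.DataFrame            # columns: patient_id, gene_id, scaled_range
    patient_summary: pd.DataFrame  # index patient; median, upper_quartile, mean, n_samples
    eligible_patients: tuple[str, ...]
    dropped_genes: tuple[str, ...]
    gene_sd: pd.Series


def compute_diversity(expr: ExpressionMatrix, sheet: SampleSheet,
                      sd_mode: str = "per_gene", ddof: int = 0) -> DiversityReport:
    """Per-patient, per-gene scaled expression ranges with patient summaries."""
    if sd_mode not in ("per_gene", "pooled"):
        raise ValidationError(f"unknown sd_mode: {sd_mode!r}")
    X = expr.values
    missing = [s for s in sheet.samples if s not in X.columns]
    if missing:
        raise ValidationError(f"sample(s) absent from expression matrix: {missing}")
    eligible = [p for p in sheet.patients if len(sheet.samples_of(p)) >= 2]
    if not eligible:
        raise ValidationError("no patient contributes two or more samples")
    if sd_mode == "per_gene":
        sds = pd.Series(X.to_numpy().std(axis=1, ddof=ddof), index=X.index)
    else:
        sds = pd.Series(float(X.to_numpy().std(ddof=ddof)), index=X.index)
    zero = ~(sds > 0)
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} gene(s) with zero overall SD",
            stacklevel=2)
    genes = X.index[~zero]
    sds = sds[~zero]
    rows = []
    summaries = []
    for p in eligible:
        sub = X.loc[genes, sheet.samples_of(p)]
        scaled = (sub.max(axis=1) - sub.min(axis=1)) / sds
        rows.append(pd.DataFrame({
            "patient_id": p, "gene_id": scaled.index, "scaled_range": scaled.values}))
        summaries.append({
            "patient_id": p,
            "median": float(scaled.median()),
            "upper_quartile": float(scaled.quantile(0.75)),
            "mean": float(scaled.mean()),
            "n_samples": len(sub.columns),
        })
    long = pd.concat(rows, ignore_index=True)
    patient_summary = pd.DataFrame(summaries).set_index("patient_id")
    return DiversityReport(long=long, patient_summary=patient_summary,
                           eligible_patients=tuple(eligible),
                           dropped_genes=tuple(X.index[zero]), gene_sd=sds)


@dataclasses.dataclass(frozen=True)
class GroupDiversityTest:
    direction: int          # +1: IPF median diversity above control, -1 below, 0 tie
    statistic: float        # Mann-Whitney U for the IPF group
    p_value: float
    ipf_values: pd.Series   # per-patient summaries entering the test
    control_values: pd.Series
    summary: str


def test_group_diversity(report: DiversityReport, sheet: SampleSheet,
                         summary: str = "median",
                         alternative: str = "two-sided") -> GroupDiversityTest:
    """Rank-based IPF vs control comparison of patient-level diversity."""
    if summary not in ("median", "upper_quartile", "mean"):
        raise ValidationError(f"unknown patient summary: {summary!r}")
    vals = report.patient_summary[summary]
    groups = {p: sheet.group_of(p) for p in report.eligible_patients}
    ipf = vals[[p for p in vals.index if groups[p] == GROUP_IPF]]
    ctl = vals[[p for p in vals.index if groups[p] == GROUP_CONTROL]]
    if len(ipf) == 0 or len(ctl) == 0:
        raise ValidationError("a group is empty after the >=2-samples "
                              "eligibility filter")
    if len(ipf) < 2 or len(ctl) < 2:
        raise ValidationError(
            f"insufficient eligible patients for a two-sample test "
            f"(IPF n={len(ipf)}, control n={len(ctl)})")
    stat, p = mannwhitneyu(ipf, ctl, alternative=alternative)
    diff = float(ipf.median() - ctl.median())
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return GroupDiversityTest(direction=direction, statistic=float(stat),
                              p_value=float(p), ipf_values=ipf,
                              control_values=ctl, summary=summary)
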