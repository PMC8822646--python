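"""Fold-change ranking of IPF versus control expression.

The core quantity is the log2 ratio of group-mean RPKM with a small
pseudocount keeping ratios finite when a group mean is zero:

    log2_ratio[g] = log2((mean_case[g] + eps) / (mean_ref[g] + eps))

A gene is "upregulated by more than twofold" when log2_ratio > 1 (strict).
Rankings are produced for the integrated 13-vs-8 comparison and per IPF
case against all controls; differentially expressed genes are counted per
Ashcroft stratum (severe: score >= 6; moderate: score < 6). Per-gene
significance comes from a two-tailed t-test (Welch by default; Student and
an explicitly-paired variant selectable). Optional Benjamini-Hochberg
adjusted p-values are available behind a flag.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ExpressionMatrix
from .panel import (GROUP_CONTROL, GROUP_IPF, SEVERE_ASHCROFT, SampleSheet,
                    ValidationError)

TEST_MODES = ("welch", "student", "paired")


def resolve_selector(sheet: SampleSheet, selector) -> list[str]:
    """Resolve a group name, patient id, sample id or explicit sample list."""
    if isinstance(selector, str):
        low = selector.strip().lower()
        if low == "ipf":
            return sheet.ipf_samples
        if low in ("control", "ctrl"):
            return sheet.control_samples
        if selector in sheet.frame["patient_id"].values:
            return sheet.samples_of(selector)
        if selector in sheet.frame.index:
            return [selector]
        raise KeyError(f"selector {selector!r} matches no group, patient or sample")
    samples = list(selector)
    unknown = [s for s in samples if s not in sheet.frame.index]
    if unknown:
        raise KeyError(f"unknown sample id(s): {unknown}")
    return samples


def two_sample_test(expr: ExpressionMatrix, group_a: Sequence[str],
                    group_b: Sequence[str], mode: str = "welch",
                    pairing: Sequence[tuple[str, str]] | None = None
                    ) -> pd.DataFrame:
    """Per-gene two-tailed t-test between two sample sets.

    ``paired`` mode requires equal group sizes and, when the natural order
    is not the pairing, an explicit ``pairing`` map of (a, b) sample tuples;
    unequal sizes are never silently truncated.
    """
    if mode not in TEST_MODES:
        raise ValidationError(f"unknown test mode: {mode!r}")
    A = expr.values[list(group_a)].to_numpy(dtype=float)
    B = expr.values[list(group_b)].to_numpy(dtype=float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")
    if mode == "paired":
        if pairing is not None:
            a_ids = [a for a, _ in pairing]
            b_ids = [b for _, b in pairing]
            A = expr.values[a_ids].to_numpy(dtype=float)
            B = expr.values[b_ids].to_numpy(dtype=float)
        elif A.shape[1] != B.shape[1]:
            raise ValidationError(
                "paired test with unequal group sizes requires an explicit "
                "pairing map (groups are never silently truncated)")
        res = stats.ttest_rel(A, B, axis=1)
    else:
        res = stats.ttest_ind(A, B, axis=1, equal_var=(mode == "student"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # Genes constant and equal in both groups: no evidence of difference.
    degenerate = ~np.isfinite(t) & np.isclose(A.mean(axis=1), B.mean(axis=1))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame({"statistic": t, "p_value": p}, index=expr.values.index)


def log2_ratios(expr: ExpressionMatrix, case_samples: Sequence[str],
                ref_samples: Sequence[str], epsilon: float = 0.1) -> pd.DataFrame:
    """Group means and log2 ratio per gene; eps=0 leaves zero-mean genes unranked."""
    if epsilon < 0:
        raise ValidationError("epsilon must be non-negative")
    if expr.log_transformed:
        raise ValidationError("fold-change ratios are computed on raw RPKM")
    case_mean = expr.values[list(case_samples)].mean(axis=1)
    ref_mean = expr.values[list(ref_samples)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((case_mean + epsilon) / (ref_mean + epsilon))
    ratio = ratio.where(np.isfinite(ratio), np.nan)
    return pd.DataFrame({
        "case_mean": case_mean, "reference_mean": ref_mean, "log2_ratio": ratio})


def rank_upregulated(expr: ExpressionMatrix, sheet: SampleSheet, case,
                     reference="control", epsilon: float = 0.1,
                     mode: str = "welch", top: int | None = None,
                     adjust: bool = False) -> pd.DataFrame:
    """Fold-change ranking of ``case`` vs ``reference`` samples.

    Returns a table sorted by descending log2 ratio (gene id as tie-break)
    with group means, the test statistic/p-value and a strict ``> twofold``
    flag; ``top`` truncates to the k most upregulated genes.
    """
    case_s = resolve_selector(sheet, case)
    ref_s = resolve_selector(sheet, reference)
    if not case_s or not ref_s:
        raise ValidationError("empty case or reference selection")
    overlap = sorted(set(case_s) & set(ref_s))
    if overlap:
        raise ValidationError(f"case and reference selections overlap: {overlap}")
    table = log2_ratios(expr, case_s, ref_s, epsilon=epsilon)
    test = two_sample_test(expr, case_s, ref_s, mode=mode)
    table = table.join(test)
    if adjust:
        table["p_adjusted"] = stats.false_discovery_control(
            table["p_value"].to_numpy(), method="bh")
    table["passes_twofold"] = table["log2_ratio"] > 1.0
    table = (table.reset_index(names="gene_id")
                  .sort_values(["log2_ratio", "gene_id"],
                               ascending=[False, True], na_position="last",
                               kind="mergesort")
                  .set_index("gene_id"))
    if top is not None:
        table = table.head(int(top))
    return table


def count_degs(expr: ExpressionMatrix, sheet: SampleSheet, stratum: str,
               direction: str = "both", epsilon: float = 0.1,
               severe_threshold: float = SEVERE_ASHCROFT) -> int:
    """Count genes beyond twofold between an Ashcroft stratum and controls."""
    key = stratum.strip().lower().replace(" ", "")
    if key in ("severe", "ashcroft>=6"):
        case_s = sheet.severe_samples(severe_threshold)
    elif key in ("moderate", "ashcroft<6"):
        case_s = sheet.moderate_samples(severe_threshold)
    else:
        raise ValidationError(f"unknown stratum selector: {stratum!r}")
    if not case_s:
        raise ValidationError(f"stratum {stratum!r} contains no samples")
    ref_s = sheet.control_samples
    if not ref_s:
        raise ValidationError("no control samples")
    ratio = log2_ratios(expr, case_s, ref_s, epsilon=epsilon)["log2_ratio"]
    if direction == "up":
        return int((ratio > 1.0).sum())
    if direction == "down":
        return int((ratio < -1.0).sum())
    if direction == "both":
        return int((ratio.abs() > 1.0).sum())
    raise ValidationError(f"unknown direction: {direction!r}")


def deg_count_table(expr: ExpressionMatrix, sheet: SampleSheet,
                    epsilon: float = 0.1) -> pd.DataFrame:
    """Stratum x direction table of twofold DEG counts vs control."""
    rows = {}
    for stratum in ("moderate", "severe"):
        rows[stratum] = {d: count_degs(expr, sheet, stratum, d, epsilon)
                         for d in ("up", "down", "both")}
    out = pd.DataFrame(rows).T
    out.index.name = "stratum"
    return out
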