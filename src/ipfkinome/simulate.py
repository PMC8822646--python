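"""Synthetic kinome-panel datasets with the study's statistical structure.

The study's raw sequencing data are not publicly deposited, so every stage
of the pipeline is exercised on simulated data that reproduce the design:
21 lung samples from 9 patients (13 IPF samples over 5 patients with
6/3/2/1/1 samples each, 8 control samples over 4 patients with 2 each), a
612-gene panel with a 46-gene clinically-actionable inhibitor flag,
Ashcroft-linked induced/suppressed gene effects, and a larger
within-patient dispersion for IPF than control tissue.

Generative model (all on the log2-RPKM scale):

    log2 mu[g, s] = baseline[g] + effect[g] * severity[s]
                    + patient_offset[p(s), g] + segment_noise[s, g]

with binary severity (Ashcroft >= 6) by default, segment noise inflated by
the heterogeneity multiplier for IPF samples, and read counts drawn
negative-binomially with mean mu * length * mapped_total / 1e9. A single
seeded generator drives all randomness; the same seed gives bit-identical
output.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .panel import (GROUP_CONTROL, GROUP_IPF, SEVERE_ASHCROFT, CountMatrix,
                    GenePanel, SampleSheet, ValidationError)


@dataclasses.dataclass(frozen=True)
class PatientSpec:
    """One patient: id, group, and per-sample Ashcroft scores (None = missing)."""

    patient_id: str
    group: str
    ashcroft: tuple[Optional[int], ...]

    @property
    def n_samples(self) -> int:
        return len(self.ashcroft)


#: The study roster: 13 IPF samples over 5 patients, 8 control over 4.
#: The 6-sample patient carries 3 severe (>= 6) and 3 moderate samples so a
#: classifier can be trained on its two strata.
DEFAULT_ROSTER: tuple[PatientSpec, ...] = (
    PatientSpec("IPF_1", GROUP_IPF, (7, 7, 6, 3, 4, 5)),
    PatientSpec("IPF_2", GROUP_IPF, (7, 6, 3)),
    PatientSpec("IPF_3", GROUP_IPF, (7, 4)),
    PatientSpec("IPF_4", GROUP_IPF, (6,)),
    PatientSpec("IPF_5", GROUP_IPF, (7,)),
    PatientSpec("CTRL_1", GROUP_CONTROL, (None, None)),
    PatientSpec("CTRL_2", GROUP_CONTROL, (None, None)),
    PatientSpec("CTRL_3", GROUP_CONTROL, (None, None)),
    PatientSpec("CTRL_4", GROUP_CONTROL, (None, None)),
)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Generative settings; defaults mirror the study design."""

    n_genes: int = 612
    n_cancer_related: int = 46
    n_inhibitor_flagged: int = 46
    roster: tuple[PatientSpec, ...] = DEFAULT_ROSTER
    baseline_log2_mean: float = 5.0      # median baseline ~32 RPKM
    baseline_log2_sd: float = 1.5
    n_induced: int = 30
    n_suppressed: int = 10
    log2_effect: float = 2.0             # severity effect, log2 units
    patient_sd: float = 0.3              # per patient x gene offset, log2 units
    segment_sd: float = 0.2              # per sample x gene noise, log2 units
    ipf_dispersion_multiplier: float = 3.0  # within-patient noise inflation, IPF
    nb_dispersion: float = 50.0          # NB size; larger = closer to Poisson
    length_range_bp: tuple[int, int] = (500, 10_000)
    mapped_total_range: tuple[int, int] = (2_000_000, 4_000_000)
    severity_mode: str = "binary"        # or "linear" (Ashcroft / 8)
    severe_threshold: int = SEVERE_ASHCROFT
    seed: int = 12021

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_cancer_related < 0 or self.n_cancer_related > self.n_genes:
            raise ValidationError("n_cancer_related outside 0..n_genes")
        if self.n_inhibitor_flagged < 0 or self.n_inhibitor_flagged > self.n_genes:
            raise ValidationError("n_inhibitor_flagged outside 0..n_genes")
        if self.n_induced + self.n_suppressed > self.n_genes:
            raise ValidationError("more effect genes than genes")
        for name in ("baseline_log2_sd", "patient_sd", "segment_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.ipf_dispersion_multiplier <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("multiplier and dispersion must be positive")
        if self.severity_mode not in ("binary", "linear"):
            raise ValidationError(f"unknown severity_mode: {self.severity_mode!r}")
        lo, hi = self.length_range_bp
        if not (1 <= lo <= hi):
            raise ValidationError("invalid transcript length range")
        lo, hi = self.mapped_total_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid mapped-total range")
        if not self.roster:
            raise ValidationError("empty patient roster")
        ids = [p.patient_id for p in self.roster]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient ids in roster")
        for p in self.roster:
            if p.group not in (GROUP_IPF, GROUP_CONTROL):
                raise ValidationError(f"unknown group for {p.patient_id}: {p.group}")
            if p.n_samples < 1:
                raise ValidationError(f"patient {p.patient_id} has no samples")
            if p.group == GROUP_IPF and any(a is None for a in p.ashcroft):
                raise ValidationError(
                    f"IPF patient {p.patient_id} has a missing Ashcroft score")

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.roster)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted effect genes, effect size, severity and noise-free means."""

    induced_genes: tuple[str, ...]
    suppressed_genes: tuple[str, ...]
    log2_effect: float
    severity: pd.Series        # per sample, 0/1 (binary) or Ashcroft/8 (linear)
    mean_rpkm: pd.DataFrame    # genes x samples expected RPKM mu[g, s]

    def to_frame(self) -> pd.DataFrame:
        rows = ([(g, "induced", self.log2_effect) for g in self.induced_genes]
                + [(g, "suppressed", -self.log2_effect)
                   for g in self.suppressed_genes])
        return pd.DataFrame(rows, columns=["gene_id", "effect_class",
                                           "log2_effect"]).set_index("gene_id")


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    counts: CountMatrix
    sheet: SampleSheet
    panel: GenePanel
    truth: GroundTruth


def default_study_config(seed: int = 12021) -> SimulationConfig:
    """The 21-sample, 9-patient, 612-gene configuration of the study layout."""
    return SimulationConfig(seed=seed)


def low_noise_study_config(seed: int = 12021) -> SimulationConfig:
    """Study layout under the documented low-noise condition.

    Heterogeneity inflation off, tight replicates (negative-binomial size
    500) and deep coverage (20-40M mapped reads) so that shot noise at the
    low-expression end of the panel does not blur the planted +/-2 log2
    effects at the selection threshold. This is the condition for the
    gene-selection and classifier recovery experiments.
    """
    return dataclasses.replace(default_study_config(seed),
                               ipf_dispersion_multiplier=1.0,
                               nb_dispersion=500.0,
                               mapped_total_range=(20_000_000, 40_000_000))


def strong_separation_config(seed: int = 12021) -> SimulationConfig:
    """Strong planted severity effects for the clustering separation check:

    80 effect genes at |log2 effect| 3, small patient offsets, no
    within-patient inflation, so the severe stratum dominates the
    correlation structure of the 612-gene matrix.
    """
    return dataclasses.replace(default_study_config(seed),
                               n_induced=60, n_suppressed=20, log2_effect=3.0,
                               patient_sd=0.1, ipf_dispersion_multiplier=1.0)


def null_study_config(seed: int = 12021) -> SimulationConfig:
    """Study layout with no severity effects (for chance-level baselines)."""
    return dataclasses.replace(default_study_config(seed),
                               n_induced=0, n_suppressed=0)


def exchangeable_null_config(seed: int = 12021) -> SimulationConfig:
    """Study layout with fully exchangeable samples.

    No severity effects, no patient blocks, no group-linked dispersion:
    the clustering of samples is then pure noise, which is the right
    baseline for chance-level partition agreement. (With patient blocks
    kept, a k=2 cut tends to isolate a patient, and because severity strata
    are nested within patients this alone induces a small positive
    agreement with the true strata — a property of the design, not of the
    clustering; see the methods note.)
    """
    return dataclasses.replace(default_study_config(seed),
                               n_induced=0, n_suppressed=0,
                               patient_sd=0.0, ipf_dispersion_multiplier=1.0)


def null_calibration_config(n_patients_per_group: int = 10,
                            n_samples_per_patient: int = 2,
                            n_genes: int = 200,
                            seed: int = 12021) -> SimulationConfig:
    """Balanced identical-groups roster for type-I-error calibration.

    Both groups are generated identically (no effects, multiplier 1); the
    roster is balanced and large enough that an exact rank test has
    achievable levels near 0.05.
    """
    roster = tuple(
        [PatientSpec(f"IPF_{i+1}", GROUP_IPF, (3,) * n_samples_per_patient)
         for i in range(n_patients_per_group)]
        + [PatientSpec(f"CTRL_{i+1}", GROUP_CONTROL,
                       (None,) * n_samples_per_patient)
           for i in range(n_patients_per_group)])
    return dataclasses.replace(
        default_study_config(seed), roster=roster, n_genes=n_genes,
        n_cancer_related=min(15, n_genes), n_inhibitor_flagged=min(15, n_genes),
        n_induced=0, n_suppressed=0, ipf_dispersion_multiplier=1.0)


def _loguniform_ints(rng: np.random.Generator, lo: int, hi: int,
                     size: int) -> np.ndarray:
    u = rng.uniform(np.log(lo), np.log(hi), size)
    return np.clip(np.rint(np.exp(u)).astype(np.int64), lo, hi)


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulatedDataset:
    """Draw one dataset; ``seed`` overrides ``config.seed`` when given."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_g = config.n_genes

    genes = [f"G{i:04d}" for i in range(1, n_g + 1)]
    category = np.array(["kinase"] * n_g, dtype=object)
    if config.n_cancer_related:
        category[-config.n_cancer_related:] = "cancer_related"
    kinase_idx = np.flatnonzero(category == "kinase")
    pool = kinase_idx if len(kinase_idx) >= config.n_inhibitor_flagged else np.arange(n_g)
    inhibitor = np.zeros(n_g, dtype=bool)
    inhibitor[rng.choice(pool, size=config.n_inhibitor_flagged, replace=False)] = True
    lengths = _loguniform_ints(rng, *config.length_range_bp, n_g)
    panel = GenePanel(pd.DataFrame({
        "transcript_length_bp": lengths,
        "category": category,
        "inhibitor_available": inhibitor,
    }, index=pd.Index(genes, name="gene_id")))

    sample_rows = []
    for p in config.roster:
        for k, score in enumerate(p.ashcroft, start=1):
            sample_rows.append({
                "sample_id": f"{p.patient_id}_S{k}",
                "patient_id": p.patient_id,
                "group": p.group,
                "ashcroft_score": np.nan if score is None else score,
                "segment_label": f"segment_{k}",
            })
    sheet = SampleSheet(pd.DataFrame(sample_rows).set_index("sample_id"))
    samples = sheet.samples
    n_s = len(samples)

    if config.severity_mode == "binary":
        severity = np.array([
            1.0 if (r["group"] == GROUP_IPF
                    and r["ashcroft_score"] >= config.severe_threshold) else 0.0
            for _, r in sheet.frame.iterrows()])
    else:
        severity = np.array([
            (r["ashcroft_score"] / 8.0) if r["group"] == GROUP_IPF else 0.0
            for _, r in sheet.frame.iterrows()])

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_g)
    effect = np.zeros(n_g)
    n_eff = config.n_induced + config.n_suppressed
    eff_idx = (rng.choice(n_g, size=n_eff, replace=False) if n_eff else
               np.array([], dtype=int))
    induced_idx = eff_idx[:config.n_induced]
    suppressed_idx = eff_idx[config.n_induced:]
    effect[induced_idx] = config.log2_effect
    effect[suppressed_idx] = -config.log2_effect

    patients = sheet.patients
    offsets = rng.normal(0.0, config.patient_sd, (len(patients), n_g))
    patient_of = {p: i for i, p in enumerate(patients)}
    is_ipf = sheet.frame["group"].to_numpy() == GROUP_IPF
    seg_sd = np.where(is_ipf,
                      config.segment_sd * config.ipf_dispersion_multiplier,
                      config.segment_sd)
    seg = rng.normal(0.0, 1.0, (n_g, n_s)) * seg_sd[None, :]

    log2_mu = (baseline[:, None] + effect[:, None] * severity[None, :]
               + offsets[[patient_of[p] for p in sheet.frame["patient_id"]], :].T
               + seg)
    mu = np.exp2(log2_mu)

    totals = rng.integers(config.mapped_total_range[0],
                          config.mapped_total_range[1] + 1, n_s)
    mean_counts = mu * lengths[:, None] * totals[None, :] / 1e9
    size = config.nb_dispersion
    p_nb = size / (size + mean_counts)
    counts = rng.negative_binomial(size, p_nb)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        pd.Series(totals, index=samples, name="mapped_total"))
    truth = GroundTruth(
        induced_genes=tuple(np.array(genes)[induced_idx]),
        suppressed_genes=tuple(np.array(genes)[suppressed_idx]),
        log2_effect=config.log2_effect,
        severity=pd.Series(severity, index=samples, name="severity"),
        mean_rpkm=pd.DataFrame(mu, index=pd.Index(genes, name="gene_id"),
                               columns=samples))
    return SimulatedDataset(counts=cm, sheet=sheet, panel=panel, truth=truth)
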