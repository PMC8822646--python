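# Methods

`ipfkinome` re-implements, as a tested pipeline, a kinome-panel expression
analysis of multi-segment lung tissue from patients with idiopathic
pulmonary fibrosis (IPF) and controls. The design it targets: 21 samples
from 9 patients — 13 IPF samples over 5 patients (6, 3, 2, 1, 1 samples
each; the 6-sample patient underwent bilateral pneumonectomy) and 8 control
samples over 4 patients (2 each) — profiled on a targeted panel of 612
kinase-coding and cancer-related genes. Fibrosis severity is graded
histologically with the Ashcroft score (0–8) and dichotomized at ≥ 6
(severe) versus < 6 (normal-to-moderate). Because the original raw
sequencing data are not publicly deposited, all quantitative claims made by
the tests and the acceptance script are about synthetic data generated
under this design.

## Normalization

Counts are converted to RPKM (reads per kilobase of transcript per million
mapped reads):

    rpkm[g, s] = counts[g, s] · 1e9 / (length_bp[g] · mapped_total[s])

The per-million denominator is the mapping-wide read total carried
explicitly per sample, never the panel column sum: a targeted panel
captures only a subset of the library, so substituting column sums would
inflate all values by the inverse capture fraction. The file format
therefore requires totals (reserved row or sidecar) and refuses to guess.

Log displays use log2(RPKM + 1); fold-change ratios are computed on raw
RPKM group means (not means of logs), matching how integrated log2 ratios
of group means are conventionally reported.

## Clustering adjustment

Before clustering, the matrix is adjusted in two steps: each sample column
is centred on its own median (absorbing per-sample depth/compression
shifts), then each gene row of the centred matrix is divided by that gene's
standard deviation across all samples. Choices the description of this
scheme leaves open, and how they were resolved:

* **SD scope** — "standard deviation of all samples" is read as the
  per-gene SD across samples; a pooled whole-matrix SD is available via
  `sd_mode="pooled"`. Per-gene scaling is what gives every gene equal
  weight in the distance, which is the usual point of the step.
* **SD convention** — population (ddof 0) by default, the convention of the
  classic expression-clustering software; ddof is configurable and recorded
  in the output.
* **Zero-variance genes** are dropped with a warning rather than producing
  infinities (a single-gene matrix degenerates to all zeros after median
  centring and is dropped entirely).

Agglomeration uses uncentred Pearson correlation distance with average
linkage by default (centred correlation and Euclidean; single/complete also
available). The agglomeration is implemented in-package so that equal merge
distances break deterministically towards the lexicographically smallest
leaf pair; heights are validated in tests against scipy's independent
implementation. Flat cuts use `scipy.cluster.hierarchy.fcluster`. Note that
per-gene rescaling after adjustment is *not* in general topology-preserving
under correlation distances (it reweights genes inside the column inner
products); only a global rescaling is, and only that is asserted.

Partition agreement is quantified with the adjusted Rand index: 1 iff two
labelings are identical up to renaming, expectation 0 under chance. It can
be slightly negative; it is not clipped.

## Expression diversity

For each patient contributing ≥ 2 samples and each gene,

    scaled_range[p, g] = (max − min RPKM over p's samples) / sd_g

where `sd_g` is the gene's SD over all samples (same reading and ddof as the
clustering adjustment). Patients with one sample are excluded — a range
needs two values. Patient-level summaries over genes (median by default;
upper quartile and mean also emitted, since the original figure's
aggregation is not recoverable) are compared between IPF and control
patients with a two-sided exact Mann-Whitney test; the reported direction
is the sign of the difference of group medians. With only 3 eligible IPF
vs 4 control patients the exact test's smallest achievable two-sided
p-value is 2/35 ≈ 0.057, so significance at 0.05 is unattainable at the
study's size — the test is calibrated, the design is just small. Type-I
error is therefore checked on a balanced calibration roster (10 patients
per group, 2 samples each, 200 genes), where the exact test's achievable
size is ≈ 0.042.

## Differential ranking

log2 ratios of group-mean RPKM use a pseudocount ε = 0.1 RPKM (configurable;
with ε = 0, zero-reference genes are reported unranked rather than
infinite). "Upregulated by more than twofold" is the strict inequality
log2 ratio > 1. DEG counts per Ashcroft stratum (severe/moderate IPF
samples vs all controls) use |log2 ratio| > 1, direction-filtered.

Per-gene significance uses a two-tailed t-test, Welch by default: the
groups are unequal (13 vs 8) and unpaired. A paired mode exists because the
original analysis names one, but IPF and control samples come from
different patients with no natural pairing, so the paired mode demands an
explicit pairing map and never truncates silently; the default stays
unpaired. No multiple-testing correction is applied by default (none is
applied in the analysis being reproduced); Benjamini–Hochberg adjusted
p-values are available behind a flag.

## Weighted-voting severity classifier

The classic signal-to-noise weighted-voting scheme for two-class expression
prediction, with the severe stratum (Ashcroft ≥ 6) as the positive class:

    S_x = (μ_pos − μ_neg) / (σ_pos + σ_neg)      per-gene weight
    b_x = (μ_pos + μ_neg) / 2                    decision boundary
    V_x = S_x (g_x − b_x)                        vote of gene x for sample g

Genes with class-mean difference > +1 become "induced", < −1 "suppressed";
the threshold is a parameter (default 1), so the induced/suppressed split
observed on any dataset is a data outcome, not a code constant. The model
is fitted on one training patient's two strata (the 6-sample patient with
3 severe + 3 moderate samples, in the study design); a held-out sample is
called severe when ΣV_x > 0. An exact zero resolves conservatively to
non-severe with a logged tie flag. Class SDs use ddof 0, consistent with
the rest of the package. No prediction-strength cutoff is applied.

The expression scale entering S_x is configurable (`rpkm` default, `log2`
selectable) and recorded in model metadata, since threshold-1 selection is
scale-dependent and the original description names no transform. The
recovery experiments use log2(RPKM + 0.1): planted effects are log2
effects, and a pseudocount of 1 would compress a −2 log2 effect below the
selection threshold for genes under ~6 RPKM, while 0.1 keeps the statistic
effect-faithful across the panel's baseline range. This was fixed from the
signal-to-noise analysis below before the acceptance experiments were run.

`WeightedVotingClassifier` is a scikit-learn estimator (samples × genes,
`fit`/`predict`/`decision_function`, `get_params`, clonable), so it
composes with sklearn model selection; the module-level wrappers adapt it
to the gene × sample expression containers and the sample sheet.

## Synthetic-data generator

All randomness flows through one seeded NumPy generator; the same seed
gives bit-identical datasets. On the log2-RPKM scale,

    log2 μ[g, s] = baseline_g + effect_g · severity_s
                   + patient_offset[p(s), g] + segment_noise[s, g]

with counts drawn negative-binomially around μ · length · total / 1e9.
Defaults (the simulated study conditions):

| parameter | default | meaning |
|---|---|---|
| genes | 612 (46 cancer-related, 46 inhibitor-flagged) | panel size |
| roster | 5 IPF patients (6/3/2/1/1 samples), 4 controls (2 each) | study layout |
| baseline | log2 ~ Normal(5, 1.5) | median ≈ 32 RPKM, spread 1–1000 |
| effects | 30 induced +2, 10 suppressed −2 (log2), binary in Ashcroft ≥ 6 | severity signature |
| patient offset SD | 0.3 log2 | between-patient block structure |
| segment noise SD | 0.2 log2 | within-patient spatial variability |
| IPF dispersion multiplier | 3 | the within-patient heterogeneity headline |
| NB size | 50 | biological replicate overdispersion |
| lengths | log-uniform 500–10,000 bp | transcript lengths |
| mapped totals | uniform 2–4 M | desktop-sequencer depth |

The panel's published arithmetic (612 genes "including" 517 kinase-coding
and 46 cancer-related) leaves 49 genes unclassified; the generator labels
them kinase, since the panel type has exactly two categories. A linear
severity mode (effect ∝ Ashcroft/8) exists but the binary stratification is
what every analysis here uses.

What the generator emulates: the sample/patient layout, an
Ashcroft-dichotomized expression signature, between-patient heterogeneity
of baseline expression, inflated within-patient dispersion in IPF, and
overdispersed counts at realistic depth. What it does not: cell-type
composition shifts, GC/length bias, alignment artifacts, correlated gene
modules, spatial gradients along the lung, or treatment effects. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
correct and well-calibrated under the stated generative assumptions — not
that the biological conclusions of any particular tissue study are robust.

### Documented experiment conditions

The replicated experiments in `ipfkinome.experiments` use three named
variants, all fixed from the following pre-hoc signal-to-noise analysis:

* **Low-noise condition** (`low_noise_study_config`): multiplier 1, NB size
  500, totals 20–40 M. Used for gene-selection and classifier recovery. At
  the default 2–4 M depth, genes below ~4 RPKM receive only a handful of
  reads and their log-scale shot noise alone produces ≈ 1 spurious
  threshold-1 selection per run; at 20–40 M the training-difference noise
  SD is ≈ 0.2 log2 against a planted margin of 1, making recovery a test of
  correctness rather than of sequencing depth.
* **Strong-separation condition** (`strong_separation_config`): 80 effect
  genes at |log2 effect| 3, patient SD 0.1, multiplier 1. Used for the k=2
  clustering check: the severe-stratum similarity contribution (~0.2 on the
  uncentred-correlation scale) then dominates both the noise floor (~0.04)
  and the patient-block contribution (~0.01).
* **Exchangeable null** (`exchangeable_null_config`): no effects, no
  patient blocks, no group-linked dispersion. Used for the chance-level
  clustering baseline. With patient blocks kept, a k=2 cut tends to isolate
  a patient, and because severity strata are nested within patients this
  alone induces a small positive stratum agreement (measured ≈ +0.02 ARI
  with the default multiplier) — a property of nested designs worth knowing
  when interpreting real dendrograms, but not a clustering defect.

Null-calibration experiments (t-test uniformity, diversity type-I error)
use 1000 genes and the balanced 10+10-patient roster respectively;
replicate counts are 100 (recovery), 200 (diversity direction) and 500
(calibration), which keeps the full suite under a minute for these checks.

## Numerical and policy details

* Inhibitor-subpanel filter: a flagged gene survives when its per-gene
  summary RPKM (median across samples by default, mean selectable) is not
  below the overall median of all gene × sample entries of the full
  matrix. The applied threshold is recorded in the result, and re-applying
  the filter with that recorded threshold is the identity — recomputing the
  median on the already-reduced matrix would, by construction, drop about
  half the survivors again.
* Ties in merge distance: lexicographically smallest leaf pair, making
  dendrograms independent of input column order.
* Result tables are written with a total ordering (sort key plus index
  tie-break) and 6 significant digits; every table carries a `#` comment
  block naming its generating options.
* Validation is fail-loud: duplicate ids, negative or fractional counts
  (with cell coordinates), missing mapped totals, IPF samples without
  Ashcroft scores, and patients assigned to both groups are all rejected at
  load time.

## Known limitations

* The diversity index divides a within-patient range by an all-sample SD
  that itself contains the between-group signal; groups with planted
  effects therefore shrink the scaled ranges of effect genes for everyone.
  The group contrast is driven by dispersion, as intended, but absolute
  index values are not comparable across panels with different effect
  structure.
* With five IPF and four control patients none of the patient-level
  inference is powered; the package reproduces the analysis shape, and its
  simulation experiments quantify behaviour at that size honestly (e.g.
  the unattainability of p < 0.05 in the diversity contrast).
* The weighted-voting classifier inherits the instability of
  signal-to-noise weights estimated from three samples per stratum: a gene
  whose training SDs are accidentally tiny gets an outsized weight. The
  conservative tie policy and the holdout evaluation surface this; no
  shrinkage is applied because none is applied in the scheme being
  reproduced.
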