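# Methods

This note records the quantitative model the package implements, the
defaults and why they were chosen, and the places where the design was
genuinely open.

## Input model

One delimited text file per plate, one row per well, with at least a
sample name, a target name and a Cq value. Dialect is sniffed from the
header: the delimiter among tab/comma/semicolon that yields the most
header fields wins; a decimal comma is assumed only in semicolon-delimited
files whose cells match `digits,digits` (in comma-delimited files that
pattern is indistinguishable from two fields, so it is never treated as a
decimal there). Header names are matched case-insensitively, ignoring
spaces/underscores/dots, against a synonym table covering common vendor
vocabularies (`Cq/Ct/Cp`, `Sample/Sample Name/Content/Name`,
`Target/Gene/Detector/Primer/Assay`, `Well/Pos/Position`). Non-numeric Cq
cells (`NA`, `N/A`, `Undetermined`, `No Cq`, `-`, empty) and numeric
Cq ≤ 0 become missing; rows are never silently dropped. Plate labels
default to file-name stems, with ordinal suffixes on collisions.

## Quality control

Two parameters, both in cycles:

- **Cq window** `[cq_min, cq_max]`, default `[5, 35]`, closed at both
  ends so the documented default keeps a Cq of exactly 35. Values outside
  are set missing and logged.
- **Replicate SD threshold**, default 0.3 (the replicate-variability level
  recommended by the MIQE guidelines). Within each
  (plate, sample, target) group the filter removes the *smallest* set of
  replicates after which the sample SD (n−1 denominator) is at or below
  the threshold, keeping at least two values. Among minimal removal sets
  it prefers the one whose removed values deviate most from the group
  median, ties going to the later replicate; for a single removal this is
  exactly "drop the value farthest from the median". The search is
  exhaustive for groups of up to 10 replicates (technical replicate
  groups are tiny) and falls back to one-at-a-time greedy removal above
  that. An important consequence of minimality: a purely greedy
  farthest-from-median iteration occasionally removes two replicates
  where one suffices (about 1% of random 5-replicate groups), which the
  exhaustive search avoids. If only two values survive and still disagree
  beyond the threshold, both are kept and the pair is flagged — two
  points cannot identify which one is divergent. For the same reason the
  filter cannot catch majority contamination: when two of three
  replicates are shifted by the same artefact, the lone correct value is
  the one that looks divergent.

Replicates are averaged within the plate (single-plate mode) or pooled
across plates after calibration (multi-plate mode); group SD uses the n−1
denominator and is undefined for fewer than two values.

## Inter-plate calibration

With an IPC sample measured on every plate, per target (pooled over
targets when the IPC covers only one, or as fallback for targets the IPC
misses on some plate):

1. `G` = geometric mean of all IPC Cq values across plates,
2. per-replicate scaling factors `s_i = cq_i / G`,
3. per-plate correction factor `CF_p = mean(s_i on plate p)`
   (with the common denominator `G` this coincides with the ratio of the
   plate's mean IPC Cq to `G`),
4. every Cq on plate `p` is divided by `CF_p`.

The correction is *multiplicative on the Cq scale*. A constant run shift
is closer to additive in reality, and dividing cannot remove an additive
offset exactly: for a 0.5-cycle offset around Cq 20 a residual of roughly
2% on the fold-change scale remains after calibration. The division rule
is kept deliberately — it is the established formulation this pipeline
follows — and the residual is documented and covered by tests.
Calibrating a single plate is forced to the exact identity. Layouts
following the sample-maximization strategy (each sample's targets and
reference genes on one plate) need no calibration at all: additive
offsets cancel inside ΔCq.

## Quantification and error propagation

Means first: technical replicates are averaged per (sample, target), then
ΔCq = mean Cq(target) − reference value, where the reference value is the
arithmetic mean over reference genes of each gene's mean Cq. SDs
propagate in quadrature (`sd_ref = sqrt(Σ sd_g²)/k` for k reference
genes; single-replicate groups contribute zero). RQ = 2^−ΔCq,
ΔΔCq = ΔCq(sample) − ΔCq(calibrator), FC = 2^−ΔΔCq. The fold-change SD
uses first-order (delta-method) propagation,
`FC.sd = ln(2) · FC · sqrt(sd_ΔCq(sample)² + sd_ΔCq(calibrator)²)` —
smooth, symmetric and standard; the asymmetric interval
`2^−(ΔΔCq ± sd)` can be derived from the stored full-precision columns.
Calibrator rows are pinned to ΔΔCq = 0, FC = 1, FC.sd = 0 exactly. All
stored values are full precision; the two-digit rounding of the
`*_display.csv` exports is display-only.

## Significance testing

Observations are replicate-level ΔCq values. Each surviving technical
replicate is paired with the *same replicate index* of the reference
gene(s) (mean over reference genes; a reference replicate removed by QC
falls back to that gene's replicate mean). Pairing keeps observations
independent: subtracting the sample's *averaged* reference value instead
would give all replicates of a group a shared noise term that the pooled
residual variance cannot see, understating the standard error — in
simulation that design shows a ~12% type-I rate at nominal 5%, while the
paired design is calibrated (~5%). This is the one place the package
deviates from a means-first formulation; the ΔCq/ΔΔCq point estimates are
unaffected.

Per gene, a two-group linear model (sample vs control) yields the effect
(mean ΔCq difference; negative = upregulated), a pooled residual variance
and residual df `n₁ + n₂ − 2`. With moderation enabled (default), the
per-gene variances are shrunk toward a common prior: hyperparameters
(d₀, s₀²) are estimated by moment-matching the log residual variances
against a scaled-F model (digamma/trigamma inversion, with small
variances offset to `1e-5 ×` their median, and complete shrinkage
d₀ = ∞, s₀² = mean variance when the log variances show no excess
spread); the moderated variance is
`s̃² = (d₀ s₀² + d s²)/(d₀ + d)` with `d₀ + d` degrees of freedom. This
reproduces Bioconductor limma's `squeezeVar` to numerical precision
(cross-checked in the test suite via Rscript). `d₀ = 0` recovers the
ordinary t-test exactly, also available via `--no-moderation`.

Two-sided p-values come from the t distribution (normal when d₀ = ∞).
Adjustment — BH step-up, Holm step-down or Bonferroni, implemented from
their definitions and cross-checked against statsmodels to 1e-12 — is
applied across the genes of one sample-vs-control comparison.
Significance stars: `****` < 1e-4, `***` < 1e-3, `**` < 0.01, `*` < 0.05
on the adjusted p-value.

## Synthetic data generator

`relq.simulate` emulates a two-condition relative-quantification design:
control `C` plus test samples, genes of interest and reference genes
(fold change fixed at 1), ≥3 technical replicates, optional multi-plate
layouts with additive per-plate Cq offsets and an IPC sample on every
plate. Wells are drawn as

    Cq = base_cq(gene) − log2(fc_true(sample, gene)) + plate_offset + N(0, σ)

with deterministic per-gene baselines (±4 cycles around 20 by default),
Gaussian replicate noise on the Cq scale (default σ = 0.05 cycles,
typical of careful pipetting), and optional outlier replicates shifted by
a fixed number of cycles (default 5). Default design: 2 samples, 7 genes
of interest at 4-fold induction, 1 reference gene, 3 replicates, 1 plate.
`split_reference_plate` places all reference wells on plate 1 to create
cross-plate ΔCq contrasts that are genuinely biased (by `2^offset`) until
calibrated. Ground truth (fold changes, injected outliers, offsets) is
returned as separate tables so tests never re-derive it from the
generator internals; everything is reproducible from the seed.

What the generator does *not* emulate: efficiency differences between
assays, amplification curves, non-Gaussian heavy-tailed replicate errors,
inhibitor effects, or biological replicate variance. Passing the recovery
and type-I tests therefore demonstrates correctness of the arithmetic and
calibration of the statistics under the stated noise model, not
robustness to assay-level artefacts.

With σ = 0.05 and 3 replicates the propagated ΔΔCq error SD is
`2σ/√3 ≈ 0.058` cycles (≈4% on FC), so single pairs beyond 10% are
expected at the few-percent level; recovery tests and the acceptance
script therefore bound the seed-median of the worst pair by 10% and every
pair by a ~5σ guard, and additionally require unbiasedness, rather than
asserting a hard all-pairs bound that fails for a sizeable minority of
seeds.

## Problem sizes

The test suite and acceptance script run entirely on simulated data:
96-well-scale plates, 10-seed recovery ensembles, 200 null simulations
(1,400 gene tests), 1,000 random p-vectors and 480 filter groups for the
oracle comparisons. These sizes give stable statistics while keeping a
full run in the tens of seconds.

## Known limitations

- No efficiency correction (Pfaffl-style): the doubling model is assumed.
- Two-condition contrasts only; no multi-group designs or mixed models
  for biological replicates.
- Inter-plate calibration divides Cq values, so an additive run shift is
  removed only approximately (see above).
- Outlier filtering is variance-based and cannot arbitrate two-replicate
  groups or majority-contaminated groups.
- Parsing targets delimited text exports; proprietary binary instrument
  formats are out of scope.
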