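# Methods

This note documents the models, numerical conventions and design choices
behind `cispairs`, and what the synthetic benchmark does and does not
establish about real data.

## Synthetic study conditions

The generators encode one fixed set of study conditions; their defaults
are the conditions under which the test suite and acceptance script run.

**Annotation.** Transcripts are laid out in disjoint loci on the
configured chromosomes. A planted pair is a minus-strand lncRNA whose TSS
(its `end` coordinate) sits 1–200 kb upstream of a plus-strand coding
gene's TSS — a divergent configuration within the 0.5 Mb pairing bound.
Every decoy transcript occupies its own locus; locus slots are sized
(pairing bound + maximal locus extent + 10 kb) so that any two TSSs in
different loci are at least the pairing bound apart. Recovery therefore
has geometric margins by construction, and the generator raises a sizing
error naming any chromosome too short for this layout. Coordinates are
1-based inclusive (GTF dialect) and TSS-to-TSS distance is the default
pairing metric (a gene-boundary alternative would change little here
since loci are far apart).

**Array experiment.** Four samples (duplicate control/treated), 3 probes
per probe set. log₂ intensity = baseline + probe affinity
(N(0, 0.3)) + effect·treated + N(0, noise_sd), with noise_sd = 0.25 —
the probe multiplicity and noise level are not properties of the modeled
biology but plausible array values, kept as config knobs. Decoy baselines
are Uniform(log₂ 8, log₂ 4096), so ~29 % of decoys fall below the 50.0
presence floor and the filter is exercised without a separate knob.
Planted effects are lnc_fc = 2.5 (up) and 1/mrna_fc = 1/3.6 (down).

Planted baselines are *not* drawn from the full decoy range: a feature
whose baseline starts below the floor would be silently filtered, and a
feature near the top of the intensity support gets clamped by quantile
normalization at the extreme ranks. Instead planted lncRNAs draw
log₂-uniform from (8, 9) and planted coding genes from (10, 11) — mRNAs
being brighter than lncRNAs is itself typical of arrays — which keeps
every planted value inside the support where quantile normalization is
locally rank-linear, and lets the coding genes' downward shift offset the
lncRNAs' upward rank displacement. This matters because the simulated
screen has only ~53 features: with 15 % of probes carrying large
one-directional shifts, quantile normalization across 4 samples would
otherwise attenuate planted fold changes by 0.2–0.35 log₂. On a
genome-wide array the differential fraction is far smaller and this
attenuation is negligible; the placement reproduces that regime at small
scale. Even so, with a 2.5× effect screened at 2.0× under noise_sd 0.25
the margin is finite: roughly 1 random seed in 15–20 loses one planted
lncRNA to the screen. The fixed-seed tests and the seed-aggregated
recovery rate in the acceptance script reflect this honestly rather than
hiding it.

**Paired cohort.** 51 patients (42 smokers — the study-size convention
this emulates), tumor values of the two genes bivariate lognormal with
log₂ sd 0.6. The latent normal correlation is the exact inversion of the
lognormal identity r = (e^{ρσ²} − 1)/(e^{σ²} − 1), so the linear-scale
Pearson correlation of tumor values equals target_r (−0.27) in
expectation. Normal-tissue values are tumor values divided (gene A) or
multiplied (gene B) by the planted fold (5.9× up, 7.4× down) times
log₂-normal ratio noise of sd noise_sd; with noise_sd = 0 every ratio is
exact. The planted ratio dispersion is modest (≈ ×/÷1.5), narrower than a
real qRT-PCR cohort's range.

**Single cell.** Each (cell type × exposure) stratum draws a fair
dominance coin per cell; the dominant gene receives increment δ, the
dominated gene does not, and both get U(0, c) background. Because
cov = −δ²/4 and var = δ²/4 + c²/12 exactly, solving δ² /4 = |r| and
c²/12 = 1 − |r| plants the stratum's Pearson correlation exactly in
expectation on a unit-variance scale — no simulation-based calibration is
needed, and the bounded noise keeps the sampling variance of the
recovered r̂ near 1/√n (±0.02 at 20,000 cells is a ≈3σ band). All strata
share mean 3 and variance 1, so the pooled coefficient is the
cell-weighted stratum average rather than a between-strata artifact.
A positive target_r cannot arise from exclusivity; such strata fall back
to a shared uniform latent component (logged). Real scRNA counts are
integer, zero-inflated and library-size confounded; none of that is
modeled — these values behave like normalized expression scores, and the
benchmark only establishes correlation recovery, not count-model realism.

**Streams.** Every generator call uses `default_rng(SeedSequence([seed,
crc32(call-name)]))`: one independent stream per call, so adding a
generator never perturbs another's output, and fixed seed ⇒ byte-identical
outputs.

## Preprocessing

The presence filter keeps features with ≥ `min_samples` (default 2)
values ≥ `floor` (default 50.0), *inclusive* — a value exactly at the
floor counts. It runs before normalization by default (configurable via
`filter_before_normalization`); at genome scale the order is immaterial.
RMA's model-based background correction is deliberately not
reimplemented: for this pipeline the floor filter plays that role.

Quantile normalization assigns each value the across-sample mean of its
rank's values; tied values within a sample receive the mean of the
reference values their tied ranks would take (the ties = average
dialect). For tie-free data all normalized sorted columns are identical —
exactly — and the map is idempotent and rank-preserving. With ties that
span distinct reference values (e.g. a constant column) the tied sample's
sorted vector necessarily deviates from the reference; this is inherent
to the dialect, not a defect.

Median polish follows Tukey's convention: start from zero effects, sweep
row then column medians (midpoint for even lengths), stop when the
largest absolute sweep change is < 1e-6 or after 20 sweeps. The
summarized value per sample is 2^(overall + column effect); with
median-zero row effects this differs from a row-anchored parameterization
by a constant per-feature offset, which cancels in every fold change.
Single-probe features pass through unchanged.

## Screen and pairing

Fold changes use arithmetic means of linear intensities (the scale on
which linear fold values are conventionally reported; a geometric-mean
option exists). A zero condition mean flags the record undefined and
excludes it downstream. The screen keeps FC ≥ threshold (default 2.0 —
the field's convention; both planted effects pass it) and is monotone in
the threshold.

Pairing takes every (differentially expressed lncRNA, differentially
expressed coding gene) pair on the same chromosome with TSS distance
strictly below `max_distance` (default 500,000 bp: 499,999 is in,
500,000 is out). The implementation uses per-chromosome sorted-TSS
binary-search windows and is tested to agree exactly with the O(n²)
three-predicate scan. Orientation: same strand → tandem; opposite strands
with the minus-strand TSS ≤ plus-strand TSS → divergent, otherwise
convergent. No direction requirement is imposed at discovery time;
anti-concordance (lncRNA and mRNA moving oppositely) is applied only in
ranking, whose stable key is (anti-concordant first, product of member
fold changes descending, distance ascending).

## Correlation

Pearson r uses n−1 covariance/variance denominators; p is the two-sided
Student-t tail on n−2 df, computed in log space (`t.logsf`), so the
reported log₁₀ p is exact even when the linear p underflows — at 50,000+
cells this matters. |r| = 1 reports p = 0 with a "perfect" flag. Strata
with n < 3 or zero variance are reported flagged, never dropped, so
per-stratum counts always sum to the global count. A Fisher-z
between-stratum comparison exists as clearly-labeled plumbing but is
excluded from default reports, which present coefficients side by side.
Expression values are used as provided (`log1p` available but off).

## Inference

**Signed-rank.** Zeros are dropped (Wilcoxon's convention, flagged — not
Pratt's), midranks for tied |d|. Exact two-sided p by the 2ⁿ
sign-assignment distribution (O(n·W) dynamic program) when n ≤ 25 and
tie-free; otherwise normal approximation with tie-corrected variance
n(n+1)(2n+1)/24 − Σ(t³−t)/48 and 0.5 continuity correction. Two-sided
p = min(1, 2·min(P≤, P≥)).

**Mann–Whitney.** U from joint midranks; exact p by the Gaussian-binomial
rank-arrangement distribution when n·m ≤ 400 and tie-free, else the
tie-corrected normal approximation with continuity correction. Beyond the
exact cutoffs the two modes agree within 0.005 on tie-free data (tested).

**BCa bootstrap** for θ = median(x) − median(y): B ≥ 999 (default 2000)
replicates resampling groups independently (`paired=True` resamples
patient pairs — provided because a matched design can argue either way;
independent is the default for two-group comparisons).
z₀ = Φ⁻¹((#{θ* < θ̂} + ½#{θ* = θ̂})/B) — the half-count avoids Φ⁻¹(0/1)
blow-ups; a fully degenerate bootstrap distribution short-circuits to
[θ̂, θ̂] with a flag, and an all-one-sided count is clipped to ±Φ⁻¹(1 −
1/2B) with a flag. Acceleration a = Σd³/(6(Σd²)^{3/2}) over leave-one-out
median differences pooled across both groups (a = 0 with a flag if the
jackknife variance is zero). Endpoints are the bootstrap quantiles at
α₁ = Φ(z₀ + (z₀+z_{α/2})/(1 − a(z₀+z_{α/2}))) and the mirror; with
z₀ = a = 0 these reduce algebraically to the percentile interval.
Empirical coverage at nominal 95 % (n = 60 per group, B = 2000) measures
93–97 % over 500 simulations.

**min-P adjustment.** "Resampling to account for multiple tests" is
implemented as the single-step Westfall–Young min-P procedure: B joint
permutations of group labels (or joint sign flips for paired data) across
all features; adjusted pᵢ = (1 + #{b : min_b ≤ p_raw,i})/(B + 1), then
enforced monotone in the raw p. Raw and permuted p-values use the same
kernel — the permutation-exact moments of the rank statistic
(Var(W) = n₁n₂s²_R/N, which handles ties without explicit tie counts)
under a normal approximation — so the comparison is like-for-like, and
the whole computation vectorizes to one matrix product per draw. The
+1/(B+1) correction makes the procedure finitely valid and slightly
conservative; under a 10-feature global null the family-wise error at
nominal 5 % measures 3–7 %, and duplicated features incur no penalty
(their permutation distributions coincide).

## Clustering

Feature rows are clustered on log₂ intensities; correlation distance is
1 − r, euclidean operates on standardized rows (display convention, raw
mode available). The agglomeration is scipy's nearest-neighbor-chain
linkage (average or complete — both monotone, so merge heights are
nondecreasing); exact ties resolve by its fixed chain order, which is
deterministic and repeatable for fixed input. Zero-variance rows get the
maximal correlation distance (2.0) to every other row and are flagged.
The leaf order is the left-before-right tree traversal. An O(n³) naive
agglomeration in the test suite is the independent reference for the
merge heights.

## Pipeline

`run_pipeline` executes simulate (or load) → preprocess → differential →
pairs → correlate → stats → cluster, writes per-stage TSV/JSON artifacts
and a manifest with the full config, seed, package version and per-stage
record counts — the discovery funnel is auditable stage by stage, and the
manifest alone suffices to re-execute the run. Stage failure leaves
completed artifacts intact and the manifest names the failing stage.
`validate_inputs` reports all findings (missing files, design/matrix
mismatches, invalid coordinates, orphan features) without mutating
anything. YAML config; CLI flags override config values.

## Problem sizes

The default simulated screen uses 3 planted pairs + 50 decoys (3 probes
each, 4 samples), the cohort 51 patients, the demo single-cell population
12,000 cells (recovery checks use 20,000 cells per stratum), B = 2000 for
all resampling, and 300–500 simulations for the coverage and FWER
experiments — sizes at which every planted quantity is measurable against
its Monte-Carlo error on a single CPU in minutes.

## Known limitations

- The synthetic array has ~170 probes; quantile normalization's behavior
  at genome scale (where the differential fraction is tiny) is emulated
  by planted-feature placement, not by scale.
- Single-cell values are continuous scores, not counts; no zero
  inflation, library-size variation, batch effects or read-level noise
  anywhere in the generators.
- No moderated variance statistics in the screen (fold-change only, by
  design), and no enrichment, motif or methylation analysis.
- Exact rank tests require tie-free data; with ties the tie-corrected
  approximation is used at any n.
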