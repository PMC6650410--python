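# Methods

This note documents the statistical procedures implemented in `pepage`,
the assumptions behind the synthetic-data generator, the numerical
conventions, and the design choices made where the problem was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Data model

A CE-MS run reduces one urine sample to a peptide list: triples of
monoisotopic mass (Da), CE migration time (min) and signal amplitude
(arbitrary units). The pipeline deliberately starts *after* spectral
deconvolution — raw spectra, isotope envelopes and charge states are
instrument-side concerns and out of scope. Masses are handled in daltons
internally; kilodalton input is converted at I/O when declared.

## 2. Internal-standard normalization

Migration times drift smoothly between runs and overall intensity scales
with urine concentration. Both are corrected against internal polypeptide
standards (endogenous peptides reliably present in every sample):

- **Time**: a monotone piecewise-linear map through the (detected,
  reference) standard time pairs, linearly extrapolated beyond the
  outermost anchors. Detected standards land exactly on the reference
  times; an affine distortion of the whole run is inverted exactly.
- **Amplitude**: one global factor per sample, the median of
  reference/detected amplitude ratios over the standards. The median makes
  the factor robust to a single aberrant standard.

Standards are located in unnormalized profiles by mass (within the ppm
tolerance) *and* coarse position (within ±6 min of the reference time,
configurable). Mass alone is ambiguous: an unrelated peptide of
near-identical mass elsewhere in the run must not hijack an anchor.
At least two detected standards are required; otherwise normalization
fails loudly, listing what was found. This scheme is this package's own
stand-in for the (unpublished) normalization used by proprietary CE-MS
software; it makes no claim of equivalence.

## 3. Cross-sample matching

Two observations may be assigned to the same master peptide only if

- their mass difference is within a ppm window of the **smaller** mass:
  50 ppm below 4 kDa, 150 ppm above 6 kDa, linearly interpolated between
  (the anchor choice is ours — the rule is stated per pair, not per
  anchor; using the smaller mass is conservative and symmetric); and
- their migration times agree within a tolerance that ramps linearly from
  1.0 min at the start of the observed run span to 2.5 min at the end,
  evaluated at the midpoint of the two times. The published rule states
  only the 1–2.5 min range; interpreting it as a ramp (early peptides
  tight, late peptides loose) matches how CE diffusion broadens peaks and
  is exposed as configuration.

Clustering is greedy agglomerative in ascending mass order with
single-linkage semantics (union-find over all tolerance-satisfying pairs).
On every random instance of ≤ 30 observations tried (100 seeds), the
partition equals the brute-force single-linkage oracle computed from the
all-pairs graph; this equivalence is asserted in the acceptance suite.
Within a cluster each sample keeps at most one observation — the one
closest in mass to the amplitude-weighted consensus, ties broken by time
then local id — and the consensus (mass, time) is recomputed from the kept
members. Clusters present in fewer than 30 % of samples (configurable) are
dropped. Master ids are integers 1..K in ascending consensus mass;
published opaque peptide ids are treated as external labels and not
reproduced. Matching is invariant to sample order, and observation counts
reconcile exactly: assigned + same-sample duplicates + presence-dropped =
pooled.

Missing amplitudes stay missing through screening and are imputed as 0
only at the classifier stage (§5).

## 4. Differential screening

For each master peptide and each pair of age groups, the base statistic is
the standardized Wilcoxon rank-sum with tie-corrected variance,

|Z| = |W − n_A(n+1)/2| / sqrt( n_A n_B/12 · [ (n+1) − Σ(t³−t)/(n(n−1)) ] ),

computed on pairwise-complete observations. |Z| (rather than the raw rank
sum) keeps peptides with different missingness patterns on one scale.

Family-wise error is controlled by the Westfall–Young **maxT step-down**
procedure: a single stream of label permutations is shared by all peptides
of a comparison (required for the method's validity); peptides are ordered
by decreasing observed |Z|; for each permutation the successive maxima of
permuted |Z| over the step-down sets are taken; the adjusted p of the i-th
peptide is the smoothed exceedance fraction (+1 in numerator and
denominator, so p ∈ (0, 1] and never exactly 0), with monotonicity down
the ordering enforced by a cumulative maximum. Permutations default to
10 000 Monte-Carlo draws (full enumeration of label assignments at 13 vs
13 is astronomically infeasible); the stream is seeded and keyed to master
ids sorted ascending, so results are invariant to row order. A peptide
left with fewer than two observed values in either group under some
labelling contributes |Z| = 0 for that labelling.

Verified properties (all computed by the test suite): single-peptide
adjusted p equals its raw permutation p; perfectly duplicated rows share
one adjusted p; agreement within 0.02 with exhaustive enumeration on
3-vs-3 toys; adjusted p ≥ raw p; never anti-conservative relative to
Bonferroni beyond Monte-Carlo error; family-wise error on 200 null
synthetic cohorts (13 vs 13, 100 peptides, 2 000 permutations) inside
[0.02, 0.08] at α = 0.05. The +1 smoothing makes the procedure slightly
conservative, which is visible as an empirical FWER below the nominal 5 %.

**Consensus selection**: with three age groups all three pairwise
comparisons run; a peptide is selected when its adjusted p < α (default
0.05) in at least 2 comparisons (configurable).

## 5. SVM age score

Features are log2(1 + amplitude) with missing → 0 before the transform (an
undetected peptide is zero signal); the transform is configuration. The
classifier is a soft-margin RBF SVM, C = 3.2 and γ = 0.008 by default.
Training is binary on the **extreme age groups** (youngest vs oldest) of
one treatment arm; middle-aged and treated samples are scored post hoc
against the same hyperplane. The published description implies one scalar
score with intermediate values for intermediate ages, which a single
hyperplane provides; the original training-label scheme is not stated, so
this choice is ours. The RBF kernel is inferred from the presence of a γ
value; no kernel is named in the source description.

A sample's score is its signed Euclidean distance to the maximal-margin
hyperplane in the kernel-induced feature space:

score(x) = ( Σᵢ αᵢyᵢ K(xᵢ, x) + b ) / ‖w‖,  ‖w‖² = Σᵢⱼ αᵢyᵢαⱼyⱼ K(xᵢ, xⱼ),

positive toward the older pole. Scoring is evaluated directly from the
stored dual coefficients and support vectors, so a serialized model (JSON
text schema: panel, preprocessing, support vectors, dual coefficients,
intercept, ‖w‖) reproduces scores bit-for-bit without retraining; the
dual-form evaluation agrees with the library decision function to 1e−8.
Raw (unnormalized) decision values remain available.

**Take-one-out panel reduction**: greedy backward elimination. Each round
tentatively drops every remaining peptide and evaluates cross-validated
accuracy without it; the best drop is committed provided accuracy does not
fall below the current panel's (so redundant peptides are pruned even when
CV is flat), ties drop the lowest master id; the procedure stops when
every drop would strictly hurt or one peptide remains. Final CV accuracy
is therefore never below the initial panel's. Accuracy is the CV
criterion; whether the original software optimized accuracy or another
statistic after cross-validation is unstated. Cross-validation defaults to
leave-one-out when the smaller class has ≤ 15 samples, else seeded
stratified 5-fold. Training sorts samples by id first, so results are
invariant to input order.

## 6. Downstream quantifications

- **Weibel glomerular volume**: V = A^1.5 · 1.38/1.01 (sphere shape
  coefficient over size-distribution coefficient). Per-animal summaries
  default to the mean of per-glomerulus volumes over a slide; applying the
  formula to the mean area is available as an option (the aggregation
  order is not stated in the source description; mean-of-volumes is the
  stereologically natural choice and, by Jensen's inequality, the larger).
- **qPCR relative expression**: 2^(Ct_GAPDH−Ct_gene) · [1 −
  2^−(Ct_RT⁻−Ct_gene)]; an absent RT⁻ signal sets the bracket to 1, and
  Ct_RT⁻ < Ct_gene violates the invariant (contamination cannot exceed
  total signal) and is rejected.
- **Two-way ANOVA** (age × treatment with interaction) uses Type-II sums
  of squares so unbalanced cell counts are handled; on balanced designs
  the sums of squares partition the total exactly. Tukey HSD runs over the
  age × treatment cell means, flagged at 0.05/0.01/0.001 (*/**/***).
  Conventions for degenerate inputs: constant data gives F = 0, p = 1
  everywhere; a zero-residual fit with a real effect gives F = ∞, p = 0.
  The null rejection rate of the interaction test is calibrated by
  simulation in the test suite (2 000 null datasets, 3 × 2 design, n = 5
  per cell).
- **Annotation consistency**: for a sequenced fragment, stop = start +
  residue_count − 1, where each character of the sequence — lowercase
  modified residues (hydroxyproline `p`, oxidized `m`) included — counts
  as one residue. The 12 sequenced peptides of the published mouse aging
  panel ship as a package fixture and all pass.

## 7. Synthetic cohort generator

The generator emulates the reference study design — 3 age groups × 13
animals (39 mice), optionally a second treatment arm — with known planted
structure:

| parameter | default | rationale |
|---|---|---|
| `n_per_group` | 13 | reference cohort size per age group |
| `n_master_peptides` | 200 | "a few hundred" detectable urinary peptides |
| `n_affected` | 10 | planted aging peptides |
| `effect_log2fc` | 2.0 | per-age-step log2 fold change, random sign per peptide |
| `amplitude_sd_log` | 1.0 | within-group biological + technical log2 SD (≈ 100 % CV) |
| `amplitude_between_sd_log` | 2.0 | spread of baseline abundances across peptides |
| `mass_jitter_ppm` | 15 | per-observation mass error SD, well inside the 50 ppm window |
| `migration_warp_scale` | 1.0 | per-sample monotone quadratic time distortion (~minutes) |
| `sample_scale_sd_log` | 0.5 | per-sample global intensity scale (urine concentration) |
| `dropout_rate` | 0.1 | missing-at-random detection failures |
| `n_standards` | 5 | internal standards, evenly spaced over the run |

Amplitudes are log-normal (log2-normal, strictly): no abundance
distribution is published for such data and log-normal is the standard
peptidomics assumption. The migration warp is a monotone quadratic
`t + c0 + c1(t−t0) + a(t−t0)²` with clipped coefficients, so
standard-based alignment has a genuinely nonlinear distortion to undo.
Dropout is amplitude-independent (MAR) by default; an
intensity-dependent mode (`intensity_dependent_dropout`) exists for stress
tests. Standards are never dropped and carry no intra-sample amplitude
noise beyond the global sample scale — modelling them as high-abundance,
stable peptides; consequently amplitude normalization recovers the sample
scale exactly. Treated arms shift the *effective age* of affected peptides
by `treatment_age_shift` age steps (e.g. −2 makes a treated-old arm
young-like), which is how the rejuvenation direction is planted.

Master (mass, time) positions are rejection-sampled so that no two
peptides are simultaneously within a generous multiple of the mass window
(3× tolerance + 10× jitter SD) and of the time window; planted identities
are then well defined under the matching tolerances and a noise-free
cohort reconstructs exactly, with no missing cells. This is a deliberate
idealization: real peptidomes contain genuinely ambiguous near-isobaric
pairs, and the generator's resolvability guarantee means passing tests say
nothing about how matching degrades under true co-migration. Other real
features not emulated: correlated peptide families (shared parent
proteins), batch effects, heavy-tailed amplitude noise, and
missing-not-at-random structure beyond the optional stress mode.

Units and ranges (masses 0.8–8 kDa, migration 19–45 min, amplitudes
around 2^10) are free parameters chosen to look like small-animal urinary
CE-MS data; no dynamic range is published for the real data, so none of
these is calibrated to the study.

## 8. Problem sizes used by the checks

The acceptance suite and `scripts/acceptance.py` use: 200 null cohorts
(13 vs 13, 100 peptides, 2 000 permutations) for family-wise error; 50
cohorts at the default planted effect for screen recall; 50 seeds for
noise-peptide elimination; 100 cohorts at `effect_log2fc = 1.5` with a
rejuvenated treated arm for score ordering; 100 random instances of ≤ 30
observations for the matching oracle; 2 000 simulated null datasets for
ANOVA calibration. The acceptance script scales some replicate counts down
(25–100 cohorts per quantity) — sizes chosen to keep Monte-Carlo error
comfortably inside the property bands while the whole script stays fast.

## 9. Known limitations

- The normalization and preprocessing of the original proprietary software
  are unpublished; this package's schemes are explicit, configurable
  stand-ins, not reproductions.
- Cohort-specific biological results (published per-group scores,
  differential-peptide counts, the literal 40-peptide panel, fibrosis
  percentages, kidney-weight changes) require the original animals and are
  intentionally not reproduction targets; the package reproduces the
  *procedures* and validates them on synthetic ground truth.
- Screening is two-group Wilcoxon only: no covariate adjustment, no
  FDR-style alternatives, at most the three pairwise comparisons of a
  three-age design.
- `maxt_adjust` silently scores untestable permuted labellings (fewer than
  two observed values in a group) as |Z| = 0, which is conservative.
- The SVM is binary; ordinal or three-class formulations are out of scope.
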