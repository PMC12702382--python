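# Methods

## Fold parcellation

Gyral crowns are convex and carry positive curvature in this package's
convention; sulcal fundi are concave and negative. A vertex with curvature
`r` joins the gyral part of its atlas region when `r > r_thr` and the
sulcal part when `r < r_thr` (default `r_thr = 0.15`, the threshold that
best separates gyral from sulcal functional signal profiles in this
literature). The tie `r == r_thr` is assigned sulcal — the gyral rule is
taken as strict — and is configurable (`tie_rule`). Vertices with region
label 0 (medial wall, unlabeled cortex) are never assigned. Adapters for
real surface files must verify the curvature sign convention and flip it
if the source encodes sulci as positive.

All `2 × n_regions` (region, fold) nodes are always materialized, ordered
by region id with the gyral part first, so connectivity matrices have a
fixed dimension (64 for the 32-region atlas) across subjects; fold parts
with no vertices are flagged empty rather than dropped, and their rows
propagate as NaN through signal aggregation and PLV so they can be
excluded explicitly downstream. Vertex-to-ROI signal reduction is an
unweighted mean (median available via `aggregation`); nothing in the
pipeline depends on the choice beyond robustness to vertex outliers.
Hemisphere is carried as node metadata only.

## Structural connectivity

`SC(i,j)` for `i ≠ j` is the count of streamlines with endpoint ROIs
`{i, j}` divided by the whole-brain streamline total; the diagonal holds
within-ROI streamlines, and streamlines with any endpoint outside the ROI
set contribute only to the denominator. Consequently

    sum over distinct pairs + diagonal sum + unassigned fraction = 1

for every matrix. Edge classes are GG (both gyral), SS (both sulcal), GS
(mixed). Class-mean strengths average over **all** distinct pairs of the
class — zeros included, diagonal excluded — because the class average is a
property of the pair population, not of the observed connections; a
nonzero-only variant exists (`include_zeros=False`). Pairs touching an
empty fold node are excluded, not imputed as zero. The GG/GS ratio is the
quotient of the two class means and is an error (not infinity) when the
GS mean is zero.

## Phase synchronization

ROI series are band-pass filtered with a design-order-2 Butterworth
(0.02–0.10 Hz) applied forward and backward (`sosfiltfilt`). Zero-phase
filtering is essential here: a causal filter's frequency-dependent phase
lag would contaminate the Hilbert phases that every downstream measure
consumes. The analytic-signal phase is wrapped to (−π, π], and 50 samples
(≈ 20 s at TR = 0.392 s) are trimmed from each end, absorbing filter and
Hilbert edge effects.

The Kuramoto order parameter is implemented in its standard normalized
form `r(t) = |M⁻¹ Σ_{j∈S} exp(iφ_j(t))| ∈ [0, 1]` for a node subset `S`
(global, gyral, sulcal, or explicit indices); the mean synchronization is
its time average. Only the normalized variant is exposed: an
unnormalized sum has no fixed scale, and the [0, 1] range is what makes
mean-synchronization values comparable across subset sizes. For finite
samples of incoherent phases the expected value is not 0 but the mean
resultant length of a 2-D random walk, `√π / (2√M)` — the closed form the
tests check against. `PLV(a,b) = |T⁻¹ Σ_t exp(i(φ_a − φ_b))|` has the same
finite-sample floor `√π / (2√T)`. Band robustness sweeps are run by
calling the pipeline with alternative `(low, high)` pairs; no bands are
hard-coded beyond the default.

## Network-based statistics

Edge-wise two-sample t statistics use the pooled-variance (Student) form,
one-sided in the configured direction (a Welch variant is available);
edges with zero variance in both groups get t = 0 rather than NaN.
Edges with `t > T` (default threshold 3.1) form a graph whose connected
components are the candidate effects, with extent measured in edges.
The null distribution reassigns the pooled subjects to two groups of the
original sizes without replacement (default 5000 permutations, vectorized
in batches over the subject-by-edge matrix) and records each
permutation's maximal component extent. Component p-values use the
add-one convention `p = (1 + #{null ≥ obs}) / (1 + n_perm)`, which can
never be zero, and are compared to α = 0.05. Results are invariant to
subject ordering and reproducible from the seed. The procedure is strictly
two-group per invocation.

## Hubs

Nodal degree is the sum of incident PLV weights (diagonal excluded; NaN
nodes stay NaN and are skipped in the others' sums). Per-subject hub sets
take the `floor(0.05 × N)` highest-degree nodes — 3 of 64, matching
per-subject gyral/sulcal hub counts that range 0–3 — with cutoff ties
broken by node index. The group-level "aggregated ranking" is implemented
as top-set membership frequency (fraction of subjects whose hub set
contains the node); a mean-percentile-rank alternative is provided since
the phrase admits both readings, and the two agree on strongly ranked
nodes. Group hubs are the top `floor(0.10 × N)` by score. The gyral and
sulcal hub-count contingency tables count subjects with 0..3 hubs of each
class, and groups are compared with a one-sided Mann-Whitney U using
midranks, tie-corrected normal approximation and continuity correction —
the convention that reproduces the reference p-values (0.248 gyral, 0.360
sulcal) from the published contingency tables to three decimals. Rank
tests are invariant to the monotone relabeling of counts as percentages.

## Group statistics

Welch's ANOVA (heteroscedasticity-robust F with Welch–Satterthwaite
denominator df) is implemented directly — it is called tens of thousands
of times in calibration — and cross-checked against an independent
implementation in the tests; with two groups it equals Welch's t squared.
Levene's test uses the classical mean-centered variant (median-centered
Brown–Forsythe by option). Tukey HSD computes Tukey–Kramer studentized-
range statistics with pooled within-group variance and p-values from the
studentized range distribution; applying a pooled-variance post-hoc after
a heteroscedasticity-motivated omnibus is statistically inconsistent but
is retained as the reference workflow (use Welch pairwise tests when
variances differ badly). Propensity matching fits a logistic model of
treated-vs-pool membership, then greedily matches treated subjects in
descending propensity order to the nearest unused pool subject, without
replacement and with no caliper; sex is encoded 0/1 and balance is
reported as standardized mean differences before/after. Cohort group
rules: FT requires GA ≥ 37 and scan PMA ≥ 37; PT GA ≤ 37, PMA ≥ 37; PP
GA ≤ 37, PMA ≤ 37; the boundary GA = 37 satisfies both preterm and term
rules and is assigned FT. Radiology scores above 4 are excluded.

## Synthetic cohort generator

The generator emulates the statistical structure of a matched three-group
neonatal cohort, not its biophysics:

- **Metadata**: gestational age, scan age and birth weight are normal
  draws per group and sex (means/SDs of the emulated population, e.g.
  full-term males 40.07 ± 0.88 weeks GA), rejection-sampled onto the
  group definitions. GA is drawn first and scan age conditionally
  (scan ≥ birth), so the GA marginal stays calibrated. Radiology scores
  are uniform on 1–4.
- **Connectomes**: distinct-pair weights are gamma draws (shape 2) around
  class means GG:GS:SS = 3.0 : 1.5 : 0.8, echoing the concentration of
  long-range wiring within gyri. Preterm subjects' GG weights are
  multiplied by 0.7. A fixed 20% of the full-term whole-brain streamline
  budget falls outside the ROI pairs (unassigned endpoints), and the GG
  mass lost to attenuation joins that residual; this keeps the normalized
  GS and SS entries group-null — only GG carries a planted difference —
  and reproduces the normalization identity above. Weights become counts
  via a multinomial draw of 6 × 10⁴ streamlines, and the emitted endpoint
  list regenerates the emitted matrix exactly through `build_sc`.
- **Dynamics**: phases follow
  `dφ_i = [ω_i + K Σ_j A_ij sin(φ_j − φ_i)] dt + σ dW_i`
  (Euler–Maruyama, dt = TR/10, burn-in 20 s discarded), with `A` the
  subject's normalized SC matrix. Intrinsic frequencies are
  0.050 ± 0.004 Hz for gyral and 0.070 ± 0.015 Hz for sulcal nodes —
  gyri narrow and low, sulci broad and high — and σ = 0.15 rad·s^(−1/2).
  The observed signal is cos(φ) plus Gaussian noise (SD 0.1) sampled
  every TR. The default coupling K = 5 was chosen by a pilot sweep to
  place the full-term cohort on the rising branch of the synchronization
  curve (mean global order parameter ≈ 0.5), where the tightly tuned,
  densely coupled gyral cluster drives global synchrony: attenuating GG
  lowers the global mean order parameter by ≈ 0.1 against a
  between-subject SD of ≈ 0.05. At strong coupling the effect inverts —
  redistributed cross-coupling entrains the sulci — so the default
  deliberately sits in the cluster-driven regime. An optional
  between-subject lognormal spread of the GG scale (`gg_subject_sd`)
  produces the positive within-group correlation between the GG/GS ratio
  and global synchronization.
- **Surface fixture**: 20 vertices per fold part with curvature drawn at
  ±0.8 (SD 0.2), so thresholding at 0.15 recovers the design for > 99% of
  vertices; vertex signals are the node's simulated series plus noise.

BOLD realism is deliberately minimal: no hemodynamic response
convolution, no physiological confounds, no head motion, no spatial
autocorrelation of noise. Passing tests therefore demonstrate that the
pipeline recovers planted structure from phase-coupled signals with these
noise sources — not that it is robust to everything real fMRI contains.

## Problem sizes and numerical choices

Desk-scale runs use 240 s of simulated acquisition (612 TR; the
generator's default is the study-scale 2300 TR) and 40 subjects per group
for the end-to-end recovery checks; FWER calibration uses 200 null
datasets × 500 permutations, power checks 50 seeds, and statistical
calibration 10⁴ replicates. Integration raises an error if any
Euler–Maruyama step moves a phase by more than π. All generators and the
permutation engine are reproducible from explicit seeds; identical inputs
give bit-identical KOP/PLV outputs. Degenerate inputs are errors or
flagged NaN, never silent: all-zero signal rows, empty node subsets,
zero-variance groups, constant regressors, zero GS means, and
Mann-Whitney samples with no variation at all.

## Known limitations

- The hub "aggregated ranking" phrase is ambiguous in the source
  workflow; membership frequency is the default reading (see above).
- Tukey HSD after Welch's ANOVA inherits the pooled-variance assumption.
- The generator's group effect enters only through the GG block and the
  streamline residual; it does not model regional heterogeneity,
  hemispheric asymmetry, or age-dependent maturation within groups.
- Real-data adapters (GIFTI surfaces, NIfTI label volumes) are not
  included; the I/O layer reads the delimited text formats documented in
  `foldconn.io`.
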