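# Methods

This note documents the models, estimators and design choices behind
asymparc, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data model

The generator emulates the *statistical* structure of a cross-species
seed-region tractography study, not the imaging physics: no diffusion
signal, streamlines, surfaces or registration are simulated, and left and
right hemispheres correspond by seed index rather than by geometric
mirroring.

**Connectivity.** A species has M seed vertices per hemisphere partitioned
into k_true blocks, and N whole-brain targets. Row *i* of a
subject-hemisphere matrix is the block's mean fingerprint plus additive
Gaussian noise rectified at zero (`max(0, x + ε)`), which preserves the
non-negativity that downstream log-transformation assumes while mimicking
count-derived probabilistic values. Rectification biases the mean upward
wherever the fingerprint is within ~2 noise SDs of zero; the
sampling-consistency test therefore checks convergence on a spec whose
values sit well above that regime, and the preset fingerprints keep their
informative targets several SDs above zero. Right-hemisphere rows are then
multiplied element-wise by the cluster's effect vector (1 = symmetric), so
with zero noise the planted right/left ratio — and hence the AI sign
convention (negative = leftward) — is exact by construction.

**Volumes.** Per subject, total gray-matter volume G is log-uniform in a
species range; subregion *j*'s bilateral mean volume is
`exp(b_j)·G^{a_j}` and is split as L = V̄(1 − AI/2), R = V̄(1 + AI/2),
which makes 2(R−L)/(R+L) equal the planted AI identically. Lognormal
noise `exp(N(0, σ_vol))` is applied **per hemisphere, independently**:
noise on the bilateral mean alone would cancel in the AI and leave every
subject's asymmetry exactly at the planted value, degenerating every
downstream test. With σ_vol = 0 the planting is exact, as the unit tests
require.

**Presets.** The three shipped species use M = 80 seeds (4 contiguous
blocks of 20) and N = 120 targets: each block "prefers" a band of 25
targets (mean 2.0 vs background 0.2, plus one tall anchor target at 6.0),
and 20 targets are background-only so the population-map threshold has
something to exclude. Effects are planted on cluster-preferred,
mid-magnitude targets and never on the anchor, keeping each matrix's
maximum — and therefore the max-normalization — comparable between
hemispheres. Study conditions: a null macaque-like species (n = 8, no
effects), a chimp-like species (n = 27, volumetric AIs −0.15/−0.10/
+0.10/+0.15, connectional effects ×0.78/×1.28 on 8 targets per cluster)
and a human-like species (n = 40, same volumetric pattern, ×0.74/×1.35 on
18 targets per cluster). Sample sizes follow the comparative samples such
studies use; planted AI magnitudes (|AI| ≈ 0.1–0.2) are typical of
reported subregion volumetric asymmetries; GMV ranges (macaque 45–70 cm³,
chimp 180–280 cm³, human 420–680 cm³) are anatomically plausible cortical
gray-matter volumes. Shared allometric truth across species — exponents
1.15/1.20/1.25/1.30, intercepts anchored to 1.5–3 cm³ subregion volumes at
a human-scale G — makes the pooled cross-species regression well-posed.
Profile noise SD defaults to 0.4 (no per-subject variance is published
for such data; the value gives per-cluster fingerprint SEs small enough
that planted effects are detectable at the preset sample sizes without
being trivial).

**What passing tests do not show.** Synthetic profiles have no spatial
autocorrelation, no registration error, no inter-subject topography
differences, and noise is homoscedastic; recovery rates here are
upper bounds on what identical settings would achieve on real
tractography data.

## Profile processing

Raw values are mapped through log(1+x) — zeros stay zero, preserving
sparsity — then the whole matrix is divided by its maximum. An all-zero
matrix passes through unchanged with a warning. Smoothing replaces metric
kernels with `rounds` of uniform neighborhood averaging over a
seed-adjacency graph (row-stochastic operator with self-loops, rounds = 0
by default since the synthetic data has no geometry); per-target totals
over seeds are conserved exactly on degree-regular graphs only, since the
row-stochastic operator is column-stochastic only there. Population maps
are across-subject means thresholded strictly (> keeps), and the group
mask is the union of the left and mirrored-right supports. Thresholds are
configuration values (default 0.15 for the presets); published analyses
on real data have used species-specific values around 0.2–0.5 chosen by
data quality, which no rule here derives.

## Parcellation and k selection

Pearson correlations between seed fingerprints (constant rows get zero
similarity and a warning) are averaged across subjects, shifted to
affinities by (r+1)/2 — monotone over [−1, 1]; clipping negatives is
available as `affinity="clip"` — and clustered by normalized-Laplacian
spectral embedding into k dimensions followed by k-means (10 restarts,
fixed seed, eigensolver tolerance 1e-8). Labels are canonicalized by
first appearance along the seed axis, making outputs diffable.

Cross-partition correspondence is solved as a Hungarian assignment on the
k×k co-occurrence table, reporting a Dice coefficient per matched pair.
The k scan parcellates every group (species × hemisphere) for each k and
records two consistency measures over group pairs: mean pairwise adjusted
Rand index, and the **minimum matched-pair Dice**. Selection — the
largest k reaching τ (default 0.8), else the argmax with a flag — uses
the minimum Dice. Rationale: mean ARI degrades too slowly when k exceeds
the true cluster count, because a noise-driven split of one block leaves
all other blocks agreeing (on the 400-seed benchmark the mean ARI at one
k above truth still exceeds 0.8, which would make the max-k rule
overshoot); the minimum matched Dice instead demands that *every* cluster
has a counterpart in every group, which is what "coherent organization
across all groups" means operationally. `score_method="ari"` restores
selection on mean ARI for comparison.

## Asymmetry statistics

AI = 2(R−L)/(R+L); L+R = 0 is missing-coded and removed pairwise, with
the per-unit n reported.

**Sign-flip permutation.** The one-sample t statistic is recomputed under
sign flips of the subject values. Because flipping leaves Σx² unchanged,
the flipped variance follows from the flipped mean, so the null is a
single matrix product. When 2ⁿ ≤ n_perm all flips are enumerated and
p = #{|t*| ≥ |t|}/2ⁿ; otherwise n_perm Monte-Carlo flips are drawn and
the add-one estimator p = (1 + #{|t*| ≥ |t|})/(1 + n_perm) keeps the
identity flip in the null, guaranteeing p ≥ 1/(n_perm+1) and estimator
validity. The observed statistic goes through the same vectorized code
path as the null, and the magnitude comparison uses an ulp-scale relative
tolerance (1e-12) so that mathematically exact ties (identity and mirror
flips) are never lost to summation-order rounding; any genuinely distinct
flip differs by far more. Zero-variance degenerate columns give p = 1,
d = 0 at zero mean and ±∞ t otherwise. The test operates on AIs by
default; `vertex_value="diff"` switches to plain R−L differences.

**Wilcoxon signed-rank.** Differences R−L; zeros discarded (count
reported; Pratt handling via config routes to the normal approximation).
For up to 12 non-zero differences the exact null of W⁺ is built by
subset-sum convolution over doubled mid-ranks (doubling makes tied ranks
integer), and the two-sided p is the null probability of a deviation from
n(n+1)/4 at least as large as observed — this matches full 2ⁿ
enumeration by construction and is checked against an independent
brute-force oracle in the tests. Larger samples use scipy's normal
approximation with tie and continuity correction.

**Corrections and families.** Vertex-wise maps use BH-FDR across the
analysis mask (per subregion map); volumetric, ROI-wise and tract-wise
tests use Bonferroni with family m = subregions × regions within a
species, multiplied by the species count when
`correction_family="cross_species"`. Cohen's d = mean/SD with the n−1
denominator. Missing-coded units are excluded from correction families.

## Allometry

OLS of ln V on ln G (natural logs; the base cancels in the slope), 95%
slope CI from the t distribution. Reduced-major-axis regression is not
fitted: the estimator is declared as ordinary least squares and the
pooled fits are evaluated as such. Cross-species pooling defaults to one
mean point per species (falling back to individual subjects when fewer
than three species are pooled, since a slope needs three points); fitting
all individuals is available via `use_species_means=False`. Slope
equality is the F-test on the hemisphere × ln G interaction in a stacked
model treating the two hemispheres as independent samples — a plot-level
comparison that ignores the L/R pairing within subjects and is
anticonservative to the extent volumes correlate across hemispheres
(limitation accepted for comparability with the plot-based practice).
Bit-identical hemispheres short-circuit to F = 0, p = 1 with a
degenerate-fit warning, since the fitted interaction is only
floating-point zero.

## Pipeline and reproducibility

Every stage is a pure function of (inputs, config, seed); the config
requires an explicit seed per RNG consumer (`simulate`, `parcellate`,
`stats`) and round-trips through YAML. Artifacts are TSV/JSON with a
fixed float format, so identical configs produce byte-identical files;
a JSONL log records one line per stage with parameters and output
checksums. ROI and tract index sets in the shipped pipeline are
contiguous equal-width target bands (11 and 7 per species, matching the
counts such studies analyze) standing in for anatomical atlas and
tract-protocol definitions, which are out of scope.

## Problem sizes

Default test and acceptance runs use the preset sizes above (M = 80,
N = 120, up to 40 subjects, 5000 permutations), a 400-seed benchmark for
parcellation recovery, 200–500 replicates for calibration simulations,
and full enumeration up to 2¹² states for exactness checks; the whole
suite completes in well under two minutes on one CPU.

## Known limitations

- No spatial statistics (TFCE, cluster-extent) at the vertex level; no
  phylogenetic comparative methods (three species cannot support them).
- Index-identity hemispheric correspondence; no surface registration.
- The ANCOVA independence approximation above.
- Exact Wilcoxon is limited to n ≤ 12 by design; beyond that the
  tie-corrected normal approximation is used.
- Synthetic data realism caveats listed under the generator.
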