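# Methods

This note documents the statistical model behind `caprimorph`, the
numerical choices made where several defensible options existed, what the
synthetic generator does and does not emulate, and the known limitations.

## Landmark scheme and data model

A specimen is an ordered configuration of k = 55 points in 2-D digitized
on the occlusal outline of a third lower molar: 7 fixed anatomical
landmarks at lobe extrema and curve junctions, and 48 sliding
semi-landmarks in 6 curves of 8 points spanning the arcs between them
(the mesial edge, which wear damages most, carries no points). Only the
semi-landmarks' position *along* the outline is arbitrary; their position
*across* it is informative, which is why they are allowed to slide during
superimposition.

Files are read and written in the tpsDig TPS dialect (`LM=`, `ID=`,
`IMAGE=`, `SCALE=`; unknown keys ignored) and as flat CSV tables.
Internal indices are 0-based; file-facing numbering is 1-based. Left
molars are mirrored about their centroid's vertical axis before any
analysis; reflection is never permitted inside the superimposition
itself, so handedness errors cannot be absorbed silently. When metadata
carry no side column, specimens are assumed right-side and this is
logged.

## Superimposition

Generalized Procrustes Analysis with unit-centroid-size scaling (full
Procrustes): every configuration is centered, scaled to CS = 1 and
rotated onto the consensus, the consensus is re-averaged and renormalized,
and the loop repeats until the total Procrustes sum of squares changes by
less than `tol` (default 1e-8, cap 100 iterations). Optimal 2-D rotations
use the closed-form angle atan2(M₁₀ − M₀₁, M₀₀ + M₁₁) of the
cross-product matrix, which cannot produce a reflection. Centroid sizes
are recorded from the raw configurations before normalization, so sliding
never affects size.

**Sliding.** Semi-landmark s with outline neighbors (b, a) moves along
the unit chord direction u = (p_a − p_b)/‖p_a − p_b‖ by t = u ·
(consensus_s − p_s): the orthogonal projection of the consensus landmark
onto the tangent line, i.e. the Procrustes-distance-minimizing position
along the linearized curve. The criterion is Procrustes distance, not
bending energy, and curves are never re-interpolated (the original image
curves are unavailable post hoc). Sliding passes alternate with full
re-superimposition.

**Stopping rule for sliding.** The Procrustes sliding objective on a
closed outline has a nearly flat valley — points can re-parametrize
along the outline with almost no change in fit — along which the total SS
creeps indefinitely (empirically ~1/iteration; thousands of iterations
still exceed an absolute 1e-8 change). The implementation therefore runs
a fixed number of sliding passes (`slide_passes`, default 10), each
followed by a converged classical superimposition, stopping earlier if
the SS change drops below `tol`. After a handful of passes the remaining
displacements are orders of magnitude below digitizing noise; the total
SS is non-increasing across passes by construction, which the test suite
asserts.

**Orientation.** The aligned dataset is finally rotated so the consensus
lies on its principal axes (major axis on x, half-turn resolved by the
sign of the first landmark's x). Aligned coordinates are thus a function
of shape alone: independently rotating, translating or scaling the input
specimens changes the output only at machine precision.

## Identification

The Procrustes residuals of all specimens — reference and unknowns,
superimposed together — enter a PCA (SVD of the centered n × 2k matrix;
components below 1e-12 of the leading eigenvalue dropped). Identification
uses the first 20 scores; computing the basis jointly matches the
protocol of superimposing everything together, and a reference-only basis
is available by flag.

Because the reference is strongly unbalanced (about 70% sheep) and
unbalanced training biases discriminant analysis, each of 100 iterations
draws a without-replacement subsample of the majority species equal to
the minority count and fits a two-class linear discriminant: pooled
within-class covariance, equal priors, Mahalanobis rule. Its leave-one-out
cross-validation percentage (CVP) is computed exactly, using rank-one
downdates of the class sums and scatters so each left-out case costs one
p × p solve. LOO is used because the analysis sample is modest and LOO is
the common morphometrics default.

The third quartile of the 100 CVPs is computed with linear interpolation
(type 7); iterations with CVP **≥** Q3 are retained. The inclusive rule
is the default because with many tied CVPs a strict rule can retain far
fewer than a quarter of the iterations (and can retain none, in which
case the implementation falls back to ≥ and logs it); the strict rule is
available as configuration. Each unknown's label is the majority species
among the retained iterations, reported with its vote percentage. An
exact 50/50 tie is reported as `unresolved` rather than guessed, unless a
force-call flag is set; ties at the single-discriminant decision boundary
go to the first class, a documented arbitrary choice.

Congruence against molecular labels (e.g. ZooMS) is the percentage of
scored unknowns whose morphometric and molecular labels agree, with a
cross-tabulation and the mismatch list; specimens without a molecular
label are excluded and counted.

## Group statistics

Groups are species × cohort (modern/archaeological), with the
archaeological species taken from the molecular labels — mismatched
specimens enter under their molecular species and are flagged in the
report.

- **Procrustes ANOVA**: sequential (type-I) sums of squares from nested
  least-squares fits on the flattened aligned coordinates; pseudo-F per
  term against the full-model residual; significance by residual
  randomization under the reduced model (RRPP), 999 permutations plus the
  observed, seed-deterministic. Permutations are evaluated in chunks with
  precomputed orthonormal design bases, so the full-size two-way model
  runs in seconds.
- **Disparity**: per-group Procrustes variance (mean squared deviation
  from the group mean shape); the pairwise statistic is the absolute
  variance difference, with p from permuting group labels within the pair
  (a pairwise restriction of the usual full-relabeling scheme, chosen so
  each contrast is self-contained).
- **Size**: Fligner–Killeen (chi-square statistic, df = groups − 1) per
  pairwise contrast; two-sided Wilcoxon rank-sum per pair, exact when
  both groups have ≤ 50 untied observations and the tie-corrected normal
  approximation otherwise, Bonferroni-multiplied by the number of pairs
  and capped at 1; and a classical two-way ANOVA with interaction on
  log CS (sequential SS, parametric F).
- **Mahalanobis / NJ**: distances between group means under the pooled
  within-group covariance of the first 20 PC scores (component count
  configurable; the space matches the classifier's), summarized as an
  unrooted neighbor-joining tree serialized to newick. Negative NJ branch
  lengths are clamped to zero and logged. A graphical network layout is
  out of scope; the tree carries the same information.

Permutation p-values lie in [1/(n_perm+1), 1] and are deterministic under
a fixed seed. One global pipeline seed spawns one sub-seed per stochastic
stage, all recorded in the JSON report, so partial reruns reproduce the
full run exactly.

## Synthetic generator

`simulate` draws datasets with the structure of a two-species ×
two-period molar study. The template is a deterministic three-lobed,
elongated closed outline (star-shaped about the origin, hence simple),
centered with CS = 1, carrying the 7 + 48 scheme and its slider map.

Specimen coordinates are

    template + s·species_effect·δ_species + c·cohort_effect·δ_cohort + ε

with s = +1 for sheep, −1 for goat; c = +1 modern, −1 archaeological;
ε isotropic Gaussian per landmark (`noise_sd`). The displacement fields δ
are fixed, unit-norm, low-order trigonometric amplitudes applied along
the outline normal, generated once from package-constant seeds so the
"species difference" is identical across runs and versions. Normal-direction
fields matter: a tangential difference is a re-parametrization of points
along the outline, which sliding removes by design. The cohort field is
orthogonalized against the species field, encoding the observation that
the species contrast is homogeneous across periods (no species × cohort
shape interaction). Configurations are then scaled to a log-normal
centroid size per group and, optionally, arbitrarily rotated and
translated. Molecular labels equal the true species flipped independently
with probability `mismatch_rate`.

Defaults are sized to the reference study design: group sizes
(521, 222, 64, 45); `noise_sd` 0.004 shape units, giving within-group
Procrustes variances of order 2e-3; `species_effect` 0.0075, placing the
retained balanced-LDA CVPs in the low-to-mid 90s — the regime reported
for real caprine M3 discrimination; `cohort_effect` 0.0035, subordinate
to the species effect; log-CS means (3.75, 3.72, 3.66, 3.65) with SD
0.09, reproducing the qualitative size structure (modern > archaeological,
modern sheep largest, archaeological species nearly equal) at effect
sizes consistent with the published pairwise tests; `mismatch_rate` 0.05,
matching the observed few-percent discordance between morphometric and
molecular identifications.

What the generator does **not** emulate: per-group variance differences
(`logcs_sd` is a single scalar, so heterogeneous size variance between
modern sheep and goat is absent and Fligner tests on defaults are null);
correlated or wear-dependent landmark noise; age and sex structure;
asymmetric molecular error (flips are symmetric, so with flip rate m and
classifier accuracy a the expected congruence is a(1−m) + (1−a)m, which
approaches 1 − m only as the classifier approaches perfection); and real
outline anatomy beyond lobe count and elongation. Passing tests
on synthetic data therefore demonstrate the pipeline's statistical
behavior under a known generative model, not field performance on
collection photographs.

## Degenerate inputs and numerical details

- Zero-size (all-coincident) configurations: CS = 0 is flagged; GPA
  refuses them by specimen name.
- Sliders with coincident neighbors keep their position (logged).
- All-identical CVPs make the quartile filter vacuous; all iterations are
  retained (logged).
- Singular pooled covariances raise with the advice to use fewer
  components.
- Constant responses yield zero statistics (F = 0, Fligner = 0) rather
  than 0/0 artifacts.
- Quantiles use type-7 linear interpolation throughout; permutation
  p-values use the add-one rank convention.

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data: the acceptance script at the full reference design
(852 specimens, 100 ensemble iterations, 999 permutations) in well under
a minute; the calibration test of the permutation ANOVA uses 200 null
simulations of 200 permutations each at n = 60.
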