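# Methods

This note records the models implemented in `anchorgm`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Data model

An anchor is an ordered 11-landmark 2D configuration; a specimen carries
four of them (ventral/dorsal × left/right) plus optional body length and
width. Landmarks LM1, LM2, LM3, LM5, LM7, LM8 are Type I (anatomical
points); LM4, LM6, LM9, LM10, LM11 are Type III semi-landmarks constructed
by projecting from Type I landmarks onto the outline. Semi-landmarks are
*not* slid during superimposition; all statistics run on the aligned
coordinates directly. Coordinates are Cartesian with y up; callers
digitizing from image coordinates (y down) must flip before analysis.

Size variables are the 55 pairwise inter-landmark Euclidean distances, in
the fixed lexicographic order (1,2), (1,3), …, (10,11). The order is not
intrinsic to the data; it is fixed so size-PC1 loadings are comparable
across runs. Distances convert from digitizer units to micrometres by the
affine law µm = 0.2·d + 0.9; the constants are the shipped calibration and
`fit_unit_conversion` refits them from paired measurements when a user has
their own calibration set.

## Quality score

For each specimen, M pools the right-minus-left distances over the ventral
and dorsal anchors (110 values for 11-landmark anchors) and A the
corresponding left/right means. The score is
Q = 100·10^(−√(M² + b²_scaled)/10) with M² = ΣMᵢ², b the OLS slope of M on
A (intercept included — left/right agreement plots show nonzero mean
offsets), and b²_scaled = b²·Σ(A−Ā)². Choices worth recording:

- **Scaling of b².** A bare squared slope is dimensionless while M² is an
  area; multiplying by Σ(A−Ā)² turns it into the regression sum of squares
  attributable to the slope, putting both terms on one scale. Other
  rescalings (by n, by a constant) would order specimens almost
  identically but shift absolute Q values; treat cross-package Q
  comparisons with caution.
- **Sign of M.** right − left; the choice is immaterial because M enters
  squared and the slope term is symmetric under swapping sides.
- **Scale sensitivity.** Q is deliberately scale-dependent (a residual of
  1 µm should matter more on a 15 µm anchor than a 150 µm one would not
  hold if Q were normalized). Score distances in micrometres — the
  filtering helpers and CLI apply the unit conversion before scoring — so
  that the Q = 10 retention threshold has a fixed physical meaning.
- Ventral and dorsal residuals share one regression and one Q per
  specimen. The threshold comparison is inclusive (Q = 10 is retained).

Q cannot distinguish true fluctuating asymmetry from mounting artifact;
both depress it.

## Two-stage alignment

GPA here is partial Procrustes superimposition: center, scale to unit
centroid size, and rotate each configuration to the current consensus by
the closed-form 2D orthogonal fit; the consensus is the mean of aligned
forms, rescaled to unit size, iterated to convergence (tolerance 1e-8 on
the consensus, max 100 iterations — far below any biological signal).
Reflections are excluded from the rotation fit because handedness is
normalized explicitly: left forms are reflected (x negated) before
alignment, otherwise averaging left and right would mix handedness.

Stage 1 runs per species and anchor type, averages each specimen's aligned
left/right forms, and rotates the average so LM7 (the curve point) lies on
the x = 0 line with its y-sign preserved (smallest rotation). This puts all
species in one orientation frame — necessary because slide-mounted
microscopic specimens cannot be physically posed before imaging. The
standardization is applied after left/right averaging; the order affects
only the global frame, not any inter-landmark distance. Stage 2 is one GPA
per anchor type over all specimens' stage-1 configurations. Because GPA
determines orientation only up to a global rotation (it depends on the
initial consensus), the final aligned set is rotated once more so the
stage-2 consensus LM7 lies on the positive x = 0 axis; this makes the
44-column shape matrix deterministic and independent of specimen order.
Species mean shapes ("species centroids") are arithmetic means of
shape-matrix rows.

Single-specimen species pass stage 1 with only their own left/right forms
(warning logged); no tangent-space projection is applied anywhere.

## Ordination and discrimination

PCA is computed by SVD of the column-centered matrix, components ordered by
variance with a deterministic sign (largest-magnitude loading positive).
Size PC1 is the first component of the specimens × 55 distance matrix; the
all-loadings-same-sign condition is flagged because only then is PC1
readable as overall size.

Clustering applies Ward's minimum-variance update (Lance–Williams, via
scipy's linkage on a precomputed condensed matrix) to **Manhattan**
distances. Ward formally presumes squared Euclidean input, so this
combination is unconventional; it is retained deliberately as the pairing
used for anchor-shape heat maps, and the merge tree is returned for
heat-map ordering. Misclassification error matches clusters to species by
Hungarian assignment on the contingency table (not majority vote), so the
error stays well-defined when clusters split species. The clade ranking
uses the pooled-variance two-sample t (not Welch); only the ordering is
consumed.

## Brownian-motion comparative methods

All comparative statistics condition on a rooted tree with positive branch
lengths through C, the tips × tips matrix of shared root-to-MRCA path
lengths: under BM each trait's tips are Gaussian with covariance σ²C.

- **Ancestral states** are joint ML estimates: internal values minimize
  Σ_edges Δ²/ℓ, solved exactly as a weighted-Laplacian linear system; for
  Gaussian models the joint mode equals the per-node marginal estimate, and
  the root equals the phylogenetically weighted mean (1ᵀC⁻¹Y)/(1ᵀC⁻¹1).
- **K_mult** = [Σⱼ eⱼᵀeⱼ / Σⱼ eⱼᵀC⁻¹eⱼ] / [(tr C − N/1ᵀC⁻¹1)/(N−1)] with
  eⱼ the trait-j deviations from the weighted mean. It is 1 in expectation
  under BM on the given tree and scale-invariant in the traits. The
  permutation test permutes tip rows; the observed arrangement counts as
  one permutation, so p ∈ (0, 1] and can never be 0.
- **Scalar PGLS**: β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with t-tests on N − p df; reduces
  exactly to OLS when C ∝ I. Used e.g. to screen body size against anchor
  size for collinearity before including both (with interaction) in the
  shape regression.
- **Shape regression (RRPP)**: data and design are premultiplied by the
  symmetric eigendecomposition root C^(−1/2) (chosen over Cholesky so the
  transform is rotation-consistent); sums of squares are sequential
  (type I) in the user-supplied covariate order, interaction columns
  (products of covariate pairs) appended last. For each term the reduced
  model's residuals are permuted, the response rebuilt, and the term's F
  recomputed; p includes the observed statistic, so p ≥ 1/iterations.
- **Phylogenetic two-block PLS**: the evolutionary cross-covariance
  R = AᶜᵀC⁻¹Bᶜ/(N−1) (blocks centered at their phylogenetically weighted
  means) is decomposed by SVD, and r_PLS is the correlation of the first
  singular-pair scores of the C^(−1/2)-transformed centered blocks. Because
  C⁻¹ = PᵀP for the symmetric root, this equals ordinary PLS on the
  transformed blocks, and the permutation null permutes the transformed
  rows of one block — the transformed rows are exchangeable under the null,
  which keeps the test calibrated on non-star trees.

With few species and many trait columns (e.g. 13 species × 22
coordinates), r_PLS is optimistically large in absolute terms even for
independent blocks; the permutation p, not the raw r, carries the
evidence.

## Directional change and the character screen

Species mean configurations are compared landmark-wise with the estimated
root configuration (the root, not each clade's MRCA, so both clades share
one reference). Displacements below 1e-12 have undefined direction and are
flagged. The Rayleigh statistic is R̄ = |Σe^{iθ}|/n with the standard
series approximation for p (clamped to (0, 1]); for the small per-clade
samples typical here (6–7 species) the approximation is rough, and a
Monte-Carlo null option (`method="montecarlo"`) is provided.

The divergence screen measures, within each of exactly two clades, the
minor-arc separation of the mean directions of each landmark pair, and
flags pairs separated by ≥ 90° in one clade and ≤ 45° in the other,
restricted by default to Type I landmarks (the measurable ones), ranked by
the between-clade separation contrast. The 90°/45° defaults are package
choices exposed as parameters; the underlying criterion is qualitative.
One structural fact uncovered while testing: because the estimated root is
an affine combination of the tip values, *clade-mean* displacement vectors
at any landmark are exactly antiparallel between two clades that partition
the tips — so the screen's signal necessarily comes from within-clade
weight and coherence structure (which species dominate the root estimate,
and how concentrated each clade's directions are), not from clade means
alone. The constructed-recovery test plants its contrast accordingly.

## Characters and parsimony

Length characters use fixed cut-offs on per-species median distances in
µm: LM1–LM3 (ventral and dorsal) 0 ≤ 15 < 1; ventral LM1–LM5 0 < 15 ≤ 1 ≤
25 < 2; dorsal LM1–LM5 0 for [15, 25], 1 above. Interval bounds are closed
("15–25" includes both ends; ties at 25 take the interval state);
"less/greater than" are strict. Dorsal LM1–LM5 below 15 µm is outside the
declared state space and raises an explicit error rather than silently
extending the rule. Qualitative shaft/root shape characters are accepted
as user-supplied states; `suggest_shape_states` offers a clearly-labelled
PC1-sign heuristic only.

NEXUS export writes standard data with single-digit symbols and quotes
labels containing whitespace; a small reader parses the files back, and a
test cross-checks the format against dendropy's nexus parser. Fitch
scoring resolves polytomies into an arbitrary binary caterpillar (the
bottom-up set algorithm's fold over children); the length is invariant to
rerooting, so scores apply to unrooted topologies. Tree *search* is out of
scope — only user-supplied topologies are scored.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
species mean shapes = a fixed hook-like 11-landmark template (satisfying
the semi-landmark construction identities) plus BM deviations along the
tree, applied to raw template coordinates (not Procrustes tangent
coordinates) and kept small relative to template size; ventral and dorsal
deviations share a tunable fraction (`integration_rho`) of their BM
increments; specimens scatter isotropically around their species mean;
left anchors are mirrored rights plus independent noise; and the mounting
artifact is a uniaxial compression of the left form by 1 − δ along a
random axis — the orthographic projection of a plane tilted by
arccos(1 − δ), a one-parameter, provably distance-shrinking distortion.

Default study conditions (chosen once, with their rationale):

| parameter | default | why |
| --- | --- | --- |
| tree | 13-tip pure-birth, depth 1 | a 13-species collection on a time-scaled tree |
| `n_per_species` | 35 | ≈ the per-species yield of a ~450-specimen collection |
| `bm_rate` | 9 units² | species-mean landmark SD ≈ 3 units, a few % of the ~140-unit template span |
| `within_sd` | 1.5 units | ≈ 0.3 µm digitization/biological scatter at the 0.2 µm/unit calibration |
| `tilt_delta` | 0.02 | mild mounting artifact; most specimens clear the Q ≥ 10 filter |
| `size_range` | (0.8, 1.3) | spans both states of the 15 µm LM1–LM3 cut-off after unit conversion |
| `integration_rho` | 0.5 | intermediate ventral/dorsal integration |

What the generator does **not** emulate: realistic anchor outlines,
qualitative character evolution (fenestration, shaft shape as a process),
non-BM evolutionary models, allometric (non-isometric) size–shape
coupling, digitization landmark-ordering errors, and correlated
within-species shape structure. Tests passing on this generator therefore
demonstrate correctness of the algorithms under their stated assumptions,
not robustness to every artifact of real slide material.

## Numerical choices and degenerate inputs

- GPA convergence: 1e-8 / 100 iterations; degenerate (zero centroid size)
  configurations are rejected by name.
- C must be symmetric positive definite; duplicate tips or non-positive
  branch lengths are rejected.
- Permutation p-values always include the observed statistic (no p = 0).
- Zero-variance traits/blocks/columns raise errors (K_mult, PLS, PCA) or
  produce flagged ±∞ statistics with warnings (clade t ranking).
- Orientation standardization is undefined for LM7 at the origin (error).
- The seeds of all stochastic procedures are explicit arguments and are
  recorded in result objects; no global random state is used.

## Problem sizes in tests

The test suite and acceptance script run entirely on synthetic data at
desk scale: trees of 4–13 tips, 2–200 specimens per species, 100–999
permutations per test, 200 replicates for the K_mult calibration, 500
simulations for its type-I error check, and 100,000 draws for the
Rayleigh Monte-Carlo null. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

- Q values are comparable only within one scaling convention for b²; see
  above.
- K_mult computed from estimated (noisy) species means is biased downward
  relative to the BM expectation of 1; the permutation test remains valid.
- Ward-on-Manhattan lacks the variance-decomposition optimality Ward has
  under squared Euclidean input.
- The Rayleigh series approximation is rough for n < ~10 (use the
  Monte-Carlo option).
- The divergence screen compares mean directions only; it ignores
  magnitude information beyond the undefined-direction cutoff.
- 2D landmarks only; no thin-plate-spline or bending-energy decomposition.
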