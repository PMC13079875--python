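# Methods

This note documents the models, conventions and numerical choices behind
`matperc`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where a genuinely open design choice was
made.

## 1. Synthetic stimuli

Real experiments of this kind render physics simulations (soft bodies,
fluids, smoke, cloth, fracture) and show them as line drawings, dot
displays or fully textured video. `matperc` replaces the renderer with
minimal parametric point-cloud dynamics. These are **not** physical
simulations; they are stand-ins chosen so that each material class has a
distinct, analytically checkable kinematic signature:

| class | dynamic | checkable signature |
|---|---|---|
| jelly | disc with damped angular standing wave `r(θ,t) = r₀(1 + A e^{−λt} sin(kθ) cos(ωt))` | `A = 0` ⇒ every frame identical; oscillatory, near-zero mean divergence |
| liquid | downward advection with horizontal shear + lateral diffusion | persistent downward flow, spatial speed gradient |
| smoke | isotropic expansion about the centroid + upward drift + Brownian jitter | positive mean flow divergence, growing dispersion |
| fabric | transverse travelling wave `Δy = A sin(κx − ωt)` on a point sheet | spatially varying speed (large speed SD) |
| rigid-breakable | rigid translation until `t_break`, then fragments as independent rigid bodies | pre-break: all pairwise distances constant, speed SD = 0 |

Defaults: 48 frames at 24 fps (2 s), 400 points per video; 18 exemplars
in the class layout 4/3/3/4/4 (jelly/liquid/smoke/fabric/rigid).
Exemplars within a class are seeded ±15 % parameter jitters; camera
views of an exemplar are in-plane rotations with a mild (±8 %)
foreshortening-like scale change. The view split — 8 views for the three
smoke exemplars, 6 for the other fifteen, totalling 114 videos — is one
concrete instance of a "six or eight angles" design and is plain config,
not hard-coded.

Coordinates are scene units with x right and y **down**, matching raster
indexing (row = y, column = x); "falling" is +y, smoke drifts toward −y.

### Masks, contours, dots

Masks are unions of pixel discs (default radius 2–3 px) stamped at
point locations, followed by a morphological closing (disc, radius 2) to
bridge gaps between neighbouring points; grids default to 128² and are
fitted to the video's bounding box, which makes all downstream shape and
motion statistics invariant to global translation.

Contours are marching-squares iso-lines at level 0.5 on a zero-padded
frame, then smoothed by a circular 5-point moving average. The smoothing
matters: the staircase polygons of binary marching squares overestimate
the perimeter of smooth shapes by ~7 %, and the moving average brings a
rasterized disc's perimeter within ~0.5 % of `2πr`. Outer contours carry
positive shoelace area in (x, y)-with-y-down ("counter-clockwise" by
the package convention); holes are negative.

The dot-count rule follows the area-based prescription exactly: the
per-frame area fraction is the ratio of on-pixels to **off**-pixels (not
to total pixels — the two diverge at large coverage), the series is
summarized by its 75th percentile using linear interpolation between
order statistics (numpy default, R type 7), multiplied by 2000, and
rounded half away from zero. Dot subsets keep one uniformly sampled
index set across all frames.

## 2. Motion statistics (20 per frame pair)

Scattered point displacements are rasterized to a regular grid (default
32²) by Gaussian-weighted averaging (bandwidth two cell widths, support
truncated at 3σ, cells with total weight < 0.25 invalid). Five scalar
fields follow: speed `|v|`; divergence `∂u/∂x + ∂v/∂y` and curl
`∂v/∂x − ∂u/∂y` by central differences; the speed-gradient magnitude;
and the 5-point-stencil Laplacian of the speed field. Validity
propagates through every stencil: a derivative cell is valid only if its
whole stencil is. Each field is summarized by mean, SD (n−1), skewness
`g₁ = m₃/m₂^{1.5}` and **excess** kurtosis `g₂ = m₄/m₂² − 3` over valid
cells; zero-variance samples map skewness and kurtosis to 0. Frame pairs
with fewer than 8 valid cells for a field yield missing values that are
excluded from downstream z-scoring.

Two readings were genuinely open and are isolated behind named
functions so alternates can be swapped: "gradient" is taken as the
magnitude of the spatial gradient *of the speed field*, and "discrete
Laplacian" as the Laplacian *of the speed field*. Likewise the
scattered-to-grid conversion (the source experiments used projected mesh
vertices without describing a field construction) is one function,
`rasterize_flow`.

A caution for interpretation: curl is a pseudoscalar. Its statistics are
invariant under proper rotations of the scene and negate (odd moments)
only under reflections; the test suite asserts exactly that.

## 3. Shape statistics (20 per frame)

The fixed, versioned descriptor list: (1–4) signed-curvature
mean/SD/skew/excess-kurtosis of the largest outer contour after uniform
arc-length resampling (curvature = turning angle / local arc length,
positive for convex turns of a CCW contour); (5) moment orientation in
(−π/2, π/2]; (6) eccentricity; (7) circular variance of boundary-normal
directions; (8) inertia-eigenvalue anisotropy (minor/major, in [0,1]);
(9–10) normalized centroid x, y; (11–12) normalized bounding-box width
and height; (13) area fraction (on/total here — a *shape* feature,
distinct from the dot rule's on/off series); (14) perimeter / grid
diagonal; (15) compactness `4πA/P²`; (16) convexity = hull perimeter /
perimeter; (17) solidity = area / hull area; (18) 8-connected component
count; (19) hole count (complement components not touching the border);
(20) bounding-box aspect ratio.

Perimeter, enclosed area and convex hull for (14–17) are all measured on
the traced sub-pixel boundary so their ratios are mutually consistent; a
rasterized disc scores compactness and solidity within a few percent of
1. Convexity can exceed 1 for *disconnected* masks (the hull spans the
gap); that is geometry, not a bug. Curvature features use the largest
component; (9–20) use the global mask. Empty frames return zeros with a
`valid=False` flag that downstream standardization respects.

## 4. Synthetic observers

Each class carries an archetype 5-vector over (dense, flexible, wobbly,
fluid, airy) — e.g. rigid-breakable is high-dense/low-everything-else,
smoke is airy and un-wobbly. An exemplar's latent vector is archetype +
seeded jitter (SD 0.05), shared across its views. A rating is
`extremity(clip(latent + observer bias + noise, 0, 1))` with bias SD
0.05 and noise SD 0.08. The extremity transform is a logistic push
`v ↦ (σ(g(v−½)) − σ(−g/2)) / (σ(g/2) − σ(−g/2))` — identity at `g = 0`,
a step as `g → ∞`. The default gain `g = 8` was set so pooled ratings
show the strongly bimodal, endpoints-heavy histogram characteristic of
categorical material impressions (with defaults, ~58 % of ratings fall
in the extreme tenths of the scale).

Triplet trials enumerate all exemplar triples spanning three distinct
classes (each member in turn as reference), then subsample a per-observer
budget (default 300). The choice between tests x and y given reference r
is `P(x) = σ((d_ry − d_rx)/T)` on latent Euclidean distances with
temperature `T = 0.15`, a lapse rate of 0.02 (uniform guess), randomized
side assignment, and log-normal RTs (median 1.5 s, log-SD 0.4).

What the generator does **not** emulate: optical material cues (color,
gloss, translucency), semantic associations, attention drift, or
inter-individual strategy differences beyond scalar bias/noise. Passing
tests therefore certify the *pipeline* — that planted structure of known
strength is recovered and that nulls are calibrated — not any claim
about human vision.

## 5. Perceptual battery

- **Inter-observer consistency**: Spearman correlation between
  participants' flattened (video × attribute) rating vectors, average
  ranks for ties, mean over the off-diagonal upper triangle.
- **Rating RDMs**: item vectors concatenate each participant's five
  attribute ratings in a fixed participant order (the stricter reading;
  a participant-averaging switch exists). Dissimilarity `1 − ρ_s`,
  range [0, 2]; exemplar-level RDMs average over an exemplar's views
  first. Constant item vectors (undefined rank correlation) fall back to
  dissimilarity 1 with a warning.
- **Triplet RDMs**: similarity(i, j) = the fraction, over trials where
  one of i, j was the reference and the other a test, of trials where
  that test was chosen; dissimilarity = 1 − similarity, range [0, 1].
  Pairs that never qualify (notably same-class pairs, since every
  triplet spans three classes) are flagged missing and excluded
  pairwise from Mantel correlations.
- **Mantel test**: Spearman over lower triangles; the null jointly
  permutes row/column labels of one matrix; `p = (count + 1)/(n_perm+1)`
  with 999 permutations by default, one-sided "greater" for directional
  hypotheses; exact enumeration over all `n!` relabelings is available
  and is used to validate the sampler against a brute-force oracle.
- **Mantel-difference test**: observed `Δr = r(RDM_A, ref) − r(RDM_B,
  ref)`; the null reassigns participants between the two groups (sizes
  preserved), rebuilds both RDMs and recomputes Δr; two-sided p. Holm
  correction across the family of comparisons.
- **EFA**: rows are participant × stimulus records over the five
  z-scored attributes. ML extraction by profile likelihood: for fixed
  uniquenesses Ψ the conditional loadings come from the eigensystem of
  `Ψ^{-1/2} S Ψ^{-1/2}`, and `F(Ψ) = Σ_{j>k}(θ_j − ln θ_j − 1)` is
  minimized over log-uniquenesses (L-BFGS-B, Heywood floor 0.005 with a
  warning; the optimizer trace is exposed so likelihood monotonicity is
  testable). Varimax is the Kaiser pairwise-rotation sweep with a
  non-decreasing criterion; factor scores are Thomson regression scores
  `Z S⁻¹ Λ`; exemplar scores are means of row scores. The default
  synthetic conditions put ~81 % of rating variance in the first two
  eigenvalues, hence the two-factor solutions used throughout.
- **Clustering**: Ward linkage on Euclidean distances between exemplar
  factor scores (scipy's implementation, equivalent to the Ward.D2
  update), cut at k = 5; agreement with the planted classes by adjusted
  Rand index.
- **Screening**: a participant is flagged when a same-side choice run
  exceeds 14 trials, or when *every* RT inside a sliding window of 10
  consecutive trials is below 350 ms ("consistently fast" is
  operationalized as a complete window; window length configurable).

## 6. Feature space

Frame-level tables (47 rows per video for motion, 48 for shape) are
analyzed separately but identically: feature columns are z-scored pooled
over all videos' frames (per-condition standardization was rejected to
keep embeddings comparable); PCA retains the minimal number of
components reaching 80 % cumulative variance; each video is summarized
by its mean retained-component scores. For each attribute, the reference
video is the one with the lowest participant-mean rating (ties broken
lexicographically by video id), the predictor is Euclidean distance to
that reference in retained space, and participant-mean ratings are
regressed on it by OLS with `adjR² = 1 − (1−R²)(n−1)/(n−2)` and BH
adjustment across the five attributes. The predicted-attribute vectors
feed the same 1 − Spearman RDM construction as the perceptual data, so
feature-derived and perceptual geometries are compared by the same
Mantel machinery. Because projected statistics depend on the camera
angle, the whole chain can be rerun over random one-view-per-exemplar
selections (`camera_angle_resample`); the analysis driver uses 100 seeds
as its problem size and reports quantiles across seeds.

## 7. Problem sizes and determinism

Every stochastic stage takes a seed; pipeline stages derive theirs from
one master seed by hashing `"<master>:<stage>"` (stable across runs and
platforms, always < 2³¹). The test suite and the acceptance script use
the default study conditions — 18 exemplars, 114 videos, 20 observers
per task, 999 Mantel permutations — with feature extraction on one view
per exemplar, 48 frames and 400 points per video, 32² flow grids and
128² masks; the Mantel-difference power check runs 50 replicates at 199
permutations, and the null-calibration check 200 replicates at 199
permutations on 10-item RDMs.

## 8. Known limitations

- The point dynamics are caricatures: no collision, no volume
  conservation, no optical cues; cross-class kinematic confusability is
  much lower than for rendered footage, so recovery statistics here are
  upper bounds on what identical analyses achieve on real data.
- Internal creases of line drawings are not reconstructable from binary
  silhouettes; only occluding-contour geometry is modelled.
- The ML factor model is fit on 5 variables; with strongly bimodal
  ratings the normality assumption is heuristic (as in the experimental
  literature), and Heywood cases are floored rather than re-specified.
- Triplet aggregation counts reference–test pairings only; test–test
  co-occurrences carry information a full choice model would use.
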