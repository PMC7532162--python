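# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `hippoparc`, at the level of detail a user
needs to judge what a passing test suite does and does not establish.

## Graph model and objective

The ROI's voxels form a fully connected undirected graph. Time series
are z-scored row-wise with the population convention (divide by T), so
the Pearson correlation is the scaled inner product `r_uv = ⟨z_u, z_v⟩/T`
and the similarity `a_uv = r_uv + 1` lies in [0, 2] with `a_uu = 2`.
Dense N×N algebra is used throughout: at the intended ROI sizes
(10²–10³ voxels) dense matrices are faster and simpler than sparse
approximations, and the graph is complete anyway.

The combined objective is `J = Nassoc_k + α·S_k + λ·R_k`:

* `Nassoc_k = Σ_c links(V_c,V_c)/degree(V_c)` with
  `links(X,Y) = Σ_{u∈X,v∈Y} a_uv` over ordered pairs and
  `degree(X) = Σ_{u∈X} d_u`, `d_u = Σ_v a_uv`. `Nassoc_k ≤ k`, with
  equality exactly when no similarity mass crosses cluster boundaries.
* `S_k` rewards, per cluster and degree-normalized, ordered voxel pairs
  sharing a prior set (+1 each) and penalizes unordered cross-prior
  pairs (−1 each). The supervision matrix S has zero diagonal: a voxel
  is not a pair with itself, and the "fully violating" partition should
  contribute only penalty terms.
* `R_k` rewards co-clustered spatial neighbor pairs (both directions),
  degree-normalized. The neighborhood system is 26-connectivity by
  default (6 and 18 are available).

A deliberate asymmetry is worth knowing about: the solver's kernel
`K = D⁻¹(A + αS + λR)D⁻¹` weights all ordered pairs of S equally, so the
trace objective it ascends counts each cross-prior pair twice (once per
direction), whereas the reported `S_k` counts it once. Both conventions
are kept as-is — the reported breakdown follows the printed definition of
the supervision term, the kernel follows the printed kernel — and the
solver selects among restarts by the trace objective it actually
optimizes. In practice the two orderings agree about which partitions
are good; they differ only in the absolute value of the supervision part.

## Solver

Weighted kernel k-means with node weights `W = D`. Two pseudo-distance
variants:

* `paper_eq4`: `d(u,V_c) = k_uu − 2·Σ_{v∈V_c} w_v k_uv / Σ_{v∈V_c} w_v`
  (no cluster self-term). Cheap, and a faithful transcription of the
  update rule as printed, but not guaranteed to ascend J.
* `full_wkkm` (default): adds the cluster self-similarity term
  `+ Σ_{v,z∈V_c} w_v w_z k_vz/(Σ w)²`. Because S contributes −1 entries,
  K can be indefinite, and even the full distance does not guarantee
  ascent on an indefinite kernel (the weighted-mean-minimizes-distance
  argument needs positive semidefiniteness). The solver therefore
  shifts the kernel by `σW⁻¹`, `σ = max(0, −λ_min(W^{1/2}KW^{1/2}))`,
  before iterating. The shift adds the constant `σ·k` to the trace
  objective, so which partitions are optimal is unchanged and the
  reported J is computed on the unshifted matrices; what the shift buys
  is a guaranteed monotone, finitely terminating iteration. It can be
  disabled (`psd_shift=False`).

The shift has a side effect worth stating: it acts as a stay-put inertia
(each node's distance to foreign clusters grows by `σ/Σw_c`-type terms),
so trajectories started far from a good partition move less. For
fitting with the prior-seeded initialization this is harmless; for
random-restart exploration of unstructured graphs the shift-free
distance explores markedly better, and the hyperparameter-sweep analyses
in the test suite use `psd_shift=False` for exactly this reason.

Initialization: the default `prior_seeded` start assigns labeled voxels
their prior set and every unlabeled voxel the label of its geodesically
nearest labeled voxel (hop distance on the ROI lattice, ties to the
lowest label). Additional random restarts alternate uniform random
labelings with a k-means++-flavoured start (k random seed voxels,
everyone assigned to the nearest seed in kernel distance); uniform
random labelings alone place all initial centroids near the global mean
and explore poorly. Ties in the assignment step go to the lowest
cluster id; an emptied cluster is repaired by donating the node farthest
from its own centroid; convergence is an exact label fixed point, with
`max_iter = 100` as a safety cap.

Cluster ids are relabeled deterministically by centroid position along
the ROI's longest principal axis (sign fixed toward the dominant
coordinate), so "head/body/tail" ordering is stable across runs,
sessions and subjects.

The unsupervised baseline (`kmeans_baseline`) is plain Euclidean k-means
on the rows of A (scikit-learn, 10 inits, fixed seed).

## Prior extraction

The functional-consistency value at voxel u pools all neighbor and
timepoint squared differences before the root:
`sqrt(Σ_{v∈N_u} Σ_t (z_u(t)−z_v(t))² / (|N_u|·T))`, which for z-scored
rows equals `sqrt(mean_v 2(1−r_uv))`; the alternative
(average-after-root) reading would not satisfy this identity, which the
tests exploit as a cross-check. Watershed flooding uses marker-based
scikit-image watershed with markers = 26-connected regional minima of
the consistency map restricted to each structural subregion; a fully
constant subregion is one plateau minimum and yields one region per
connected component. Candidate regions smaller than `min_size = 5`
voxels are excluded before the exhaustive Mcut search — a single-voxel
prior makes `links(P,P)` a lone diagonal entry and the Mcut ratio
unstable. Ties in the Mcut minimum break to the lexicographically
smallest region-index tuple. For subregions with very many watershed
regions, an optional `max_candidates` pre-filter keeps the most
internally homogeneous regions (`links(P,P)/|P|²`); the default is the
full exhaustive search.

## Hyperparameter selection

The bi-level criterion is operationalized as: solve at every grid point
of α, λ ∈ {0, 0.25, 0.5, 1, 2, 4} (configurable; no canonical published
grid exists for this method); discard points whose partition fails any
per-parcel feasibility flag; keep feasible points with
`Nassoc ≥ (1−ε_N)·max`, ε_N = 0.01 relative (strict lexicographic
comparison of floats would make the outer smoothness objective vacuous —
ε_N = 0 restores it); among those return the maximal-smoothness point,
ties to smaller α then smaller λ.

Feasibility (`gsc_check`) tests, per parcel: single 26-connected
component, and — in the default strict mode — that every member is
reachable from the parcel's geodesic center (the node minimizing the
maximal within-parcel hop distance) by a path that is simultaneously a
shortest within-ROI path and entirely inside the parcel (checked as
equality of parcel-restricted and ROI-wide BFS distances). This is a
practical star-convexity surrogate; plain connectivity is available with
`strict_geodesic=False`.

Smoothness `Sm = (N − Σ_u Σ_{v∈N_u} χ(u,v))/N` counts split neighbor
pairs in both directions and is therefore often negative under
26-connectivity (up to 26 split pairs per boundary voxel against a
budget of N). Only differences between candidate parcellations matter.

## Evaluation metrics

Dice between two parcellations defaults to maximum-total-overlap label
matching (Hungarian assignment on the k×k intersection-count matrix);
identity matching is available because the principal-axis relabeling
usually aligns labels already, and matched Dice ≥ identity Dice always.
Fisher z clips |r| at 1−1e−12. The group connectivity test converts the
one-sample t statistic to a standard normal z through its two-sided tail
probability (sign preserved) and applies Benjamini–Hochberg FDR across
all parcel×region pairs; pairs with zero variance across subjects are
excluded rather than reported with an undefined p. Regions with fewer
than 5 voxels are skipped in the connectivity tables.

The aging model is OLS of `FC` on `[1, Age, Sex]` (sex dropped with a
warning if constant). The sex-adjusted connectivity defaults to
`FC* = FC − β₂·Sex`. The fully literal alternative that also subtracts
the residuals (`subtract_residuals=True`) reduces FC* to `β₀ + β₁·Age`,
whose correlation with age is ±1 by construction whenever β₁ ≠ 0 — a
degenerate diagnostic — so the default keeps the residuals; the reported
correlation of FC* with age and its p-value then behave as ordinary
partial-correlation diagnostics.

## Synthetic studies

The generator produces an axis-aligned ellipsoid ROI (default diameters
12×8×6 voxels ≈ 300 voxels on a 3 mm grid; the end-to-end analyses use
19×9×7 ≈ 645 voxels), k = 3 ground-truth parcels as slabs along the long
axis with boundary planes placed to hit cumulative volume fractions
(0.395, 0.690), and a "structural" prior equal to the truth with both
planes shifted by `prior_offset` voxels (default 1) to emulate a
structural/functional mismatch.

Signals follow a one-factor-per-parcel Gaussian mixing model, sufficient
because the method consumes only pairwise correlations: parcel latents
share a global component with weight `g = ρ_out/ρ_in`, and each voxel is
`√w·L_c + √(1−w)·η_u` with `w = ρ_in` (defaults ρ_in = 0.4,
ρ_out = 0.1, T = 175; cohort presets `newyork_like` — 20 subjects,
T = 192, ages 18–46 — and `retest_like` — 24 subjects, 3 sessions,
T = 197, ages 21–49). Voxel series are scaled to a 10⁴ baseline so the
pipeline's z-scoring step is exercised. Sessions redraw all noise under
per-(subject, session) derived seeds; everything is bit-reproducible
from one seed. `plant_age_effect` mixes a per-subject reference series
into one parcel with weight `clip(0.4 + slope·(age − mean age), 0.02,
0.98)`, default slope −0.015/year, planting a connectivity–age effect of
known sign between that parcel and the pseudo-region carrying the
reference.

What the generator does **not** emulate: hemodynamic autocorrelation,
physiological noise, motion, scanner drift, spatial smoothness of noise,
or anatomically realistic hippocampal geometry. Passing tests therefore
demonstrate that the algorithmic machinery is correct and recovers
planted structure under controlled correlation levels — not that the
method attains any particular accuracy on real fMRI.

## Problem sizes in the test suite

The suite runs the solver-vs-enumeration check on 100 graphs of up to
10 nodes (exhaustive enumeration of all k-partitions), monotone-ascent
checks on 100 random indefinite-kernel instances, the formula oracles on
50 random toys, the end-to-end recovery on ten ~645-voxel studies with
the full 36-point grid, the test-retest harness on 10 subjects × 3
sessions (~304 voxels), 200 null simulations for the FDR check and 100
cohorts of 24 subjects for the aging check. These sizes were chosen so
the whole suite completes in a few minutes on one CPU while keeping
Monte-Carlo error small relative to the asserted margins.

## Known limitations

* The bi-level selector re-solves at every grid point; no warm starts.
* Exhaustive Mcut search is exponential in the number of subregions
  (fine for the intended k = 3).
* The strict geodesic feasibility test checks paths from the geodesic
  center only, not from every voxel (the full star-convexity family).
* Dense algebra caps practical ROI sizes at a few thousand voxels.
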