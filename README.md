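# hippoparc

Semi-supervised, spatially regularized graph partitioning for functional
parcellation of a brain region of interest (ROI) from resting-state fMRI.

Functional parcellation asks: given the BOLD time series of every voxel in
a structure such as the hippocampus, split the structure into k disjoint,
spatially contiguous parcels whose voxels have homogeneous functional
signals (e.g. head / body / tail along the hippocampal long axis).
`hippoparc` implements this as a graph-partitioning problem with partial
supervision from a structural parcellation, together with the machinery
needed to tune and validate it: prior-label extraction, bi-level
hyperparameter selection, and homogeneity / reproducibility / functional
connectivity evaluation. Because real test-retest fMRI cohorts are large
downloads, the package ships a first-class synthetic-study generator that
emulates the relevant data properties, so the entire pipeline runs and is
tested offline.

## The model

Every ROI voxel is a node of a fully connected graph with edge weights
`a_uv = r_uv + 1`, where `r_uv` is the Pearson correlation of the z-scored
voxel time series (so `a_uv ∈ [0, 2]`). A partition {V_1..V_k} is scored
by

    J = Nassoc_k + α·S_k + λ·R_k

* `Nassoc_k = Σ_c links(V_c,V_c)/degree(V_c)` — normalized association,
  the within-parcel similarity data term;
* `S_k` — a supervision term rewarding co-clustered voxels that share a
  prior label (must-link) and penalizing co-clustered voxels with
  different prior labels (cannot-link), degree-normalized;
* `R_k` — a spatial term rewarding co-clustered 26-neighbor voxel pairs,
  degree-normalized.

J is maximized by iterative **weighted kernel k-means** with kernel
`K = D⁻¹(A + αS + λR)D⁻¹` and node weights `W = D`; with α = λ = 0 the
method reduces to unsupervised normalized-association clustering.

The partial prior labels are extracted from a structural parcellation:
each structural subregion is subdivided by marker-based watershed on a
functional-consistency map (RMS signal difference to 26-neighbors), and
the jointly most homogeneous tuple of regions — one per subregion,
minimizing the min-maxcut score `Mcut = Σ_i inter_i/intra_i` — becomes
the supervision.

The weights (α, λ) are chosen by a constrained bi-level grid search:
feasible grid points must yield parcels passing a geodesic-star-convexity
contiguity test (`GSC_c = 1` for all c); among feasible points, those
within a tolerance band of the maximal `Nassoc` are kept, and the point
with maximal boundary smoothness `Sm = (N − Σ split neighbor pairs)/N`
wins.

Validation metrics include a similarity-based silhouette `SI_k`,
multi-cluster Dice with optimal label matching, group frequency /
maximum-probability maps, parcel-to-region functional connectivity with
Fisher z transform, one-sample t-tests under Benjamini–Hochberg FDR, and
an aging analysis `FC = β₀ + β₁·Age + β₂·Sex + ε` with sex-adjusted
connectivity.

## Worked example

```python
import hippoparc as hp

# synthetic study: ellipsoid ROI, 3 planted parcels, shifted structural prior
study = hp.generate(hp.SyntheticSpec(seed=42))

model = hp.ParcellationModel(
    study.timeseries[(0, 0)],          # raw N x T voxel time series
    study.mask,                        # ROI mask (node ordering)
    structural_labels=study.structural_labels,
)
res = model.fit(optimize=True)         # bi-level (alpha, lambda) search
print(res.summary())
print("Dice vs ground truth:", round(res.dice(study.truth_labels), 3))
```

prints

```
Semi-supervised graph parcellation
============================================
ROI voxels (N)               304
parcels (k)                    3
alpha                      0.000
lambda                     0.000
Nassoc                    1.1419
supervision term          0.0031
spatial term              0.1250
objective J               1.1419
smoothness Sm            -2.2895
silhouette SI             0.1853
GSC flags                    111
parcel volume shares  38.2%, 35.5%, 26.3%
solver iterations              2
grid points feasible      35 / 36
Dice vs ground truth: 1.0
```

Reading the output: the bi-level search found 35 of 36 grid points whose
parcellations pass every contiguity flag and, within the top-`Nassoc`
band, settled on (α*, λ*) = (0, 0) — at this noise level the data term
alone recovers the planted parcels exactly (Dice 1.0), so no extra
regularization is needed. `Nassoc = 1.14` of a possible 3.0 reflects the
realistic overlap between parcel signals (within-parcel correlation 0.4,
between 0.1); the negative `Sm` simply counts many split 26-neighbor
pairs relative to N on a small ROI and is only compared across candidate
parcellations, never in absolute terms. The three parcels occupy
38.2/35.5/26.3 percent of the ROI — exactly the planted head/body/tail
slabs of this discretized ellipsoid (the generator places boundary planes
as close to its target 39.5/29.5/31 split as the voxel grid allows).

The same pipeline is scriptable from the shell:

```sh
hippoparc simulate --seed 42 --out study/
hippoparc parcellate --bold study/bold_sub00_ses0.nii.gz \
    --mask study/mask.nii.gz --structural study/structural.nii.gz \
    --optimize --out parcels.nii.gz
hippoparc evaluate dice parcels.nii.gz study/truth.nii.gz
```

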