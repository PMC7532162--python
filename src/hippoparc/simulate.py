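"""Synthetic studies: ROI geometry, ground-truth parcels, correlated BOLD
series, shifted structural priors, and multi-subject / multi-session cohorts.

The signal model is a one-factor-per-parcel Gaussian mixing model, which
is sufficient because the parcellation method consumes only pairwise
Pearson correlations.  Parcel c has a latent series L_c; latents share a
global component so that cross-parcel latent correlation is
g = rho_out / rho_in, and each voxel mixes its parcel latent with iid
noise,

    X_u = sqrt(w) * L_c + sqrt(1 - w) * eta_u,   w = rho_in,

giving expected voxel-voxel correlation rho_in within parcels and rho_out
between.  The ROI is an axis-aligned ellipsoid elongated along x (a
hippocampus-like shape); ground-truth parcels are slabs along the long
axis, and the "structural" prior is the truth with its boundary planes
deliberately shifted to emulate a structural/functional mismatch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import Bold4D, LabelMap, RoiMask, VolumeGrid

__all__ = [
    "SyntheticSpec",
    "SyntheticStudy",
    "generate",
    "make_structural_prior",
    "planes_from_labels",
    "plant_age_effect",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic parcellation experiment."""

    axes: tuple[int, int, int] = (12, 8, 6)  # ellipsoid diameters, voxels
    geometry: str = "ellipsoid"  # or "box"
    k: int = 3
    # cumulative voxel-count fractions of the parcel boundaries along x
    boundary_fractions: tuple[float, ...] = (0.395, 0.690)
    n_timepoints: int = 175
    rho_in: float = 0.4
    rho_out: float = 0.1
    prior_offset: int = 1
    n_subjects: int = 1
    n_sessions: int = 1
    seed: int = 0
    age_range: tuple[int, int] = (18, 46)
    male_fraction: float = 0.5
    baseline: float = 10000.0
    scale: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_out <= self.rho_in <= 1.0):
            raise ValueError("need 0 <= rho_out <= rho_in <= 1")
        if self.rho_in > 0 and self.rho_out == self.rho_in and self.rho_in < 1:
            pass  # equal correlations are allowed but make parcels unidentifiable
        fr = self.boundary_fractions
        if len(fr) != self.k - 1 or any(
            not (0 < a < 1) for a in fr
        ) or any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("boundary fractions must be strictly increasing in (0,1)")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")

    @classmethod
    def newyork_like(cls, **overrides) -> "SyntheticSpec":
        """Single-session cohort sized like a 20-subject adult dataset."""
        base = dict(n_subjects=20, n_sessions=1, n_timepoints=192, age_range=(18, 46))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def retest_like(cls, **overrides) -> "SyntheticSpec":
        """Three-session test-retest cohort of 24 adults."""
        base = dict(n_subjects=24, n_sessions=3, n_timepoints=197, age_range=(21, 49))
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticStudy:
    """Ground truth plus generated data for one synthetic experiment."""

    spec: SyntheticSpec
    mask: RoiMask
    truth_labels: np.ndarray  # per node, 1..k
    structural_labels: np.ndarray  # per node, 1..k (boundary-shifted)
    timeseries: dict  # (subject, session) -> raw N x T matrix
    covariates: pd.DataFrame
    reference_series: dict = field(default_factory=dict)  # subject -> T vector

    @property
    def n_nodes(self) -> int:
        return self.mask.n_nodes

    def truth_map(self) -> LabelMap:
        return LabelMap(self.mask.grid, self.mask.volume_from_nodes(self.truth_labels))

    def structural_map(self) -> LabelMap:
        return LabelMap(
            self.mask.grid, self.mask.volume_from_nodes(self.structural_labels)
        )

    def bold(self, subject: int = 0, session: int = 0) -> Bold4D:
        ts = self.timeseries[(subject, session)]
        data = np.zeros(self.mask.grid.shape + (ts.shape[1],))
        data[tuple(self.mask.coords.T)] = ts
        return Bold4D(self.mask.grid, data)


def _roi_mask(spec: SyntheticSpec) -> RoiMask:
    ax, ay, az = spec.axes
    shape = (ax + 2, ay + 2, az + 2)
    grid = VolumeGrid(shape, np.diag([3.0, 3.0, 3.0, 1.0]))  # 3 mm isotropic
    idx = np.indices(shape)
    center = (np.array(shape) - 1) / 2.0
    if spec.geometry == "ellipsoid":
        rx, ry, rz = ax / 2.0, ay / 2.0, az / 2.0
        d2 = (
            ((idx[0] - center[0]) / rx) ** 2
            + ((idx[1] - center[1]) / ry) ** 2
            + ((idx[2] - center[2]) / rz) ** 2
        )
        in_roi = d2 <= 1.0
    elif spec.geometry == "box":
        in_roi = (
            (np.abs(idx[0] - center[0]) <= ax / 2.0)
            & (np.abs(idx[1] - center[1]) <= ay / 2.0)
            & (np.abs(idx[2] - center[2]) <= az / 2.0)
        )
    else:
        raise ValueError("geometry must be 'ellipsoid' or 'box'")
    return RoiMask(grid, in_roi)


def _boundary_planes(mask: RoiMask, fractions: tuple[float, ...]) -> list[float]:
    """x-coordinates of the parcel boundary planes hitting the target
    cumulative voxel-count fractions as closely as possible."""
    xs = mask.coords[:, 0]
    n = len(xs)
    planes = []
    candidates = np.arange(xs.min(), xs.max() + 1) + 0.5
    for f in fractions:
        shares = [(xs < b).sum() / n for b in candidates]
        b = candidates[int(np.argmin(np.abs(np.array(shares) - f)))]
        planes.append(float(b))
    if any(b2 <= b1 for b1, b2 in zip(planes, planes[1:])):
        raise ValueError("boundary planes collapsed; ROI too small for k parcels")
    return planes


def _labels_from_planes(mask: RoiMask, planes: list[float]) -> np.ndarray:
    xs = mask.coords[:, 0]
    labels = np.ones(mask.n_nodes, dtype=int)
    for b in planes:
        labels += xs >= b
    return labels


def planes_from_labels(labels: np.ndarray, mask: RoiMask) -> list[float]:
    """Recover slab boundary planes from a plane-parcellated label vector."""
    xs = mask.coords[:, 0]
    k = int(labels.max())
    planes = []
    for c in range(1, k):
        left = xs[labels == c].max()
        right = xs[labels == c + 1].min()
        if right <= left:
            raise ValueError("labels are not slabs along the long axis")
        planes.append((left + right) / 2.0)
    return planes


def make_structural_prior(
    truth_planes: list[float], mask: RoiMask, offset: int
) -> np.ndarray:
    """Truth boundary planes translated by ``offset`` voxels along the long
    axis; errors if any subregion would be emptied."""
    shifted = [b + offset for b in truth_planes]
    labels = _labels_from_planes(mask, shifted)
    k = len(truth_planes) + 1
    if len(np.unique(labels)) != k:
        raise ValueError(f"offset {offset} empties a structural subregion")
    return labels


def _draw_series(
    rng: np.random.Generator, labels: np.ndarray, spec: SyntheticSpec
) -> np.ndarray:
    """Raw N x T matrix under the one-factor-per-parcel mixing model."""
    n = len(labels)
    t = spec.n_timepoints
    w = spec.rho_in
    g = 0.0 if spec.rho_in == 0 else spec.rho_out / spec.rho_in

    def standardize(v):
        v = v - v.mean()
        sd = np.sqrt((v**2).mean())
        return v / sd if sd > 0 else v

    global_comp = standardize(rng.standard_normal(t))
    latents = {}
    for c in np.unique(labels):
        own = standardize(rng.standard_normal(t))
        latents[c] = standardize(np.sqrt(g) * global_comp + np.sqrt(1 - g) * own)
    noise = rng.standard_normal((n, t))
    signal = np.empty((n, t))
    for c, lat in latents.items():
        members = labels == c
        signal[members] = np.sqrt(w) * lat + np.sqrt(1 - w) * noise[members]
    return spec.baseline + spec.scale * signal


def generate(spec: SyntheticSpec) -> SyntheticStudy:
    """Build the full synthetic study deterministically from ``spec.seed``."""
    mask = _roi_mask(spec)
    planes = _boundary_planes(mask, spec.boundary_fractions)
    truth = _labels_from_planes(mask, planes)
    structural = make_structural_prior(planes, mask, spec.prior_offset)

    cov_rng = np.random.default_rng([spec.seed, 997])
    ages = cov_rng.integers(spec.age_range[0], spec.age_range[1] + 1, spec.n_subjects)
    sexes = (cov_rng.random(spec.n_subjects) < spec.male_fraction).astype(int)
    covariates = pd.DataFrame(
        {"subject_id": np.arange(spec.n_subjects), "age": ages, "sex": sexes}
    )

    timeseries = {}
    for s in range(spec.n_subjects):
        for r in range(spec.n_sessions):
            rng = np.random.default_rng([spec.seed, s, r])
            timeseries[(s, r)] = _draw_series(rng, truth, spec)
    return SyntheticStudy(
        spec=spec,
        mask=mask,
        truth_labels=truth,
        structural_labels=structural,
        timeseries=timeseries,
        covariates=covariates,
    )


def plant_age_effect(
    study: SyntheticStudy,
    parcel: int = 2,
    slope: float = -0.015,
    base_weight: float = 0.4,
) -> SyntheticStudy:
    """Mix a per-subject reference series into one parcel's voxels with a
    mixing weight linear in age, planting a connectivity-age effect of the
    sign of ``slope`` between that parcel and the pseudo-region carrying
    the reference series.

    The weight is clip(base_weight + slope * (age - mean age), 0.02, 0.98)
    and each voxel series becomes sqrt(1 - weight^2)*X + weight*ref, so
    the expected parcel-to-reference correlation scales with the weight.
    """
    if study.covariates is None or study.covariates.empty:
        raise ValueError("study has no covariates")
    out = copy.deepcopy(study)
    ages = study.covariates["age"].to_numpy(dtype=float)
    mean_age = ages.mean()
    members = study.truth_labels == parcel
    if not members.any():
        raise ValueError(f"no voxels in parcel {parcel}")
    for s in range(study.spec.n_subjects):
        rng = np.random.default_rng([study.spec.seed, 7919, s])
        ref = rng.standard_normal(study.spec.n_timepoints)
        ref = (ref - ref.mean()) / np.sqrt(((ref - ref.mean()) ** 2).mean())
        out.reference_series[s] = ref
        weight = float(np.clip(base_weight + slope * (ages[s] - mean_age), 0.02, 0.98))
        for r in range(study.spec.n_sessions):
            ts = out.timeseries[(s, r)].copy()
            sig = (ts[members] - study.spec.baseline) / study.spec.scale
            mixed = np.sqrt(1 - weight**2) * sig + weight * ref[None, :]
            ts[members] = study.spec.baseline + study.spec.scale * mixed
            out.timeseries[(s, r)] = ts
    return out
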