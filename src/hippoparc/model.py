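"""Model / results interface for the full parcellation pipeline.

``ParcellationModel`` holds the data (ROI time series, mask, structural
prior or explicit supervision labels) and the modelling choices (k,
connectivity, solver configuration).  ``fit`` runs prior extraction, the
semi-supervised graph partition, and — when requested — the bi-level
(alpha, lambda) search, returning a ``ParcellationResults`` that carries
the partition, the objective breakdown, homogeneity and smoothness
diagnostics, and the hyperparameter audit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .clustering import Partition, SolveResult, SolverConfig, solve
from .graph import (
    PriorLabels,
    RoiGraph,
    build_kernel,
    build_spatial,
    build_supervision,
    pearson_similarity,
    zscore,
)
from .hyperopt import ParameterGrid, bilevel_select, gsc_check, smoothness
from .priors import extract_prior
from .volumes import Bold4D, LabelMap, RoiMask, extract_timeseries, write_labels

__all__ = ["ParcellationModel", "ParcellationResults"]


class ParcellationModel:
    """Semi-supervised functional parcellation of an ROI.

    Parameters
    ----------
    timeseries : (N, T) array
        Raw BOLD series per ROI node (node order fixed by ``mask``).
    mask : RoiMask
        ROI geometry; defines the node ordering and spatial lattice.
    structural_labels : (N,) int array, optional
        Per-node structural subregion labels 1..k; prior supervision is
        extracted from them by watershed + min-maxcut selection.
    prior : PriorLabels, optional
        Explicit supervision labels; overrides structural extraction.
    k : int
        Number of parcels.
    connectivity : {6, 18, 26}
        Spatial neighborhood system.
    """

    def __init__(
        self,
        timeseries: np.ndarray,
        mask: RoiMask,
        structural_labels: np.ndarray | None = None,
        prior: PriorLabels | None = None,
        k: int = 3,
        connectivity: int = 26,
        min_prior_size: int = 5,
    ):
        self.mask = mask
        self.k = int(k)
        self.connectivity = int(connectivity)
        self.min_prior_size = int(min_prior_size)
        self.raw = np.asarray(timeseries, dtype=float)
        if self.raw.shape[0] != mask.n_nodes:
            raise ValueError("time series rows must match ROI nodes")
        self.ts = zscore(self.raw)
        self.graph: RoiGraph = pearson_similarity(self.ts)
        self.spatial = build_spatial(mask, connectivity)
        self.structural_labels = (
            None if structural_labels is None else np.asarray(structural_labels, int)
        )
        self._prior = prior
        self.prior_report: dict | None = None

    @classmethod
    def from_nifti(cls, bold_path, mask_path, structural_path=None, **kwargs):
        from .volumes import read_bold, read_label_map, read_mask

        mask = read_mask(mask_path)
        bold = read_bold(bold_path)
        ts = extract_timeseries(bold, mask)
        structural = None
        if structural_path is not None:
            structural = read_label_map(structural_path).node_labels(mask)
        return cls(ts, mask, structural_labels=structural, **kwargs)

    @property
    def prior(self) -> PriorLabels:
        if self._prior is None:
            if self.structural_labels is None:
                raise ValueError("no prior: provide structural labels or PriorLabels")
            self._prior, self.prior_report = extract_prior(
                self.ts,
                self.mask,
                self.spatial,
                self.structural_labels,
                self.graph,
                min_size=self.min_prior_size,
            )
        return self._prior

    def fit(
        self,
        alpha: float = 1.0,
        lam: float = 1.0,
        optimize: bool = False,
        grid: ParameterGrid | None = None,
        epsilon_nassoc: float = 0.01,
        config: SolverConfig | None = None,
        seed: int | None = None,
    ) -> "ParcellationResults":
        """Fit the parcellation; with ``optimize`` run the bi-level search."""
        config = config or SolverConfig()
        if seed is not None:
            config.rng_seed = seed
        S = build_supervision(self.prior, self.mask.n_nodes)
        coords = self.mask.coords
        audit = None
        if optimize:
            sel = bilevel_select(
                self.graph,
                S,
                self.spatial,
                self.prior,
                self.k,
                grid=grid,
                config=config,
                epsilon_nassoc=epsilon_nassoc,
                coords=coords,
            )
            alpha, lam, res, audit = sel.alpha, sel.lam, sel.result, sel.audit
        else:
            kern = build_kernel(self.graph, S, self.spatial, alpha=alpha, lam=lam)
            res = solve(
                kern,
                self.k,
                self.graph,
                S=S,
                R=self.spatial,
                prior=self.prior,
                config=config,
                spatial_adj=self.spatial,
                coords=coords,
            )
        return ParcellationResults(self, res, alpha, lam, audit)


@dataclass
class ParcellationResults:
    """Fitted parcellation with diagnostics."""

    model: ParcellationModel
    solve_result: SolveResult
    alpha: float
    lam: float
    audit: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def partition(self) -> Partition:
        return self.solve_result.partition

    @property
    def labels(self) -> np.ndarray:
        return self.partition.labels

    @property
    def objective(self):
        return self.solve_result.objective

    def silhouette(self) -> float:
        return _metrics.silhouette(self.partition, self.model.graph)

    def smoothness(self) -> float:
        return smoothness(self.partition, self.model.spatial)

    def gsc_flags(self) -> np.ndarray:
        return gsc_check(self.partition, self.model.spatial)

    def parcel_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.model.k + 1)[1:]

    def volume_shares(self) -> np.ndarray:
        sizes = self.parcel_sizes()
        return sizes / sizes.sum()

    def dice(self, other_labels: np.ndarray, matching: str = "optimal_overlap") -> float:
        return _metrics.dice(self.labels, other_labels, self.model.k, matching)

    def label_map(self) -> LabelMap:
        return LabelMap(
            self.model.mask.grid, self.model.mask.volume_from_nodes(self.labels)
        )

    def save_labels(self, path) -> None:
        write_labels(self.labels, self.model.mask, path)

    def summary(self) -> str:
        obj = self.objective
        shares = ", ".join(f"{s:.1%}" for s in self.volume_shares())
        lines = [
            "Semi-supervised graph parcellation",
            "=" * 44,
            f"ROI voxels (N)        {self.model.mask.n_nodes:>10d}",
            f"parcels (k)           {self.model.k:>10d}",
            f"alpha                 {self.alpha:>10.3f}",
            f"lambda                {self.lam:>10.3f}",
            f"Nassoc                {obj.nassoc:>10.4f}",
            f"supervision term      {obj.supervision:>10.4f}",
            f"spatial term          {obj.spatial:>10.4f}",
            f"objective J           {obj.total:>10.4f}",
            f"smoothness Sm         {self.smoothness():>10.4f}",
            f"silhouette SI         {self.silhouette():>10.4f}",
            f"GSC flags             {''.join(map(str, self.gsc_flags())):>10s}",
            f"parcel volume shares  {shares:>10s}",
            f"solver iterations     {self.solve_result.n_iter:>10d}",
        ]
        if self.audit is not None:
            n_feas = int(self.audit["feasible"].sum())
            lines.append(
                f"grid points feasible  {n_feas:>6d} / {len(self.audit):<4d}"
            )
        return "\n".join(lines)
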