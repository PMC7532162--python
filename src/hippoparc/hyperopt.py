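"""Bi-level selection of the supervision and spatial weights (alpha, lambda).

Feasibility is a topological constraint: every parcel must be a single
26-connected component whose voxels are reachable from the parcel's
geodesic center by a within-ROI shortest path lying entirely inside the
parcel (a geodesic-star-convexity style test).  Among feasible grid
points, the inner objective keeps those within a relative tolerance band
of the maximal normalized association; the outer objective then picks the
one with maximal boundary smoothness

    Sm = (N - sum_u sum_{v in N_u} chi(u, v)) / N,

chi(u, v) = 0 for same-parcel neighbor pairs and 1 otherwise (both
directions counted).  Ties break to the smallest (alpha, lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .clustering import Partition, SolveResult, SolverConfig, solve
from .graph import PriorLabels, RoiGraph, build_kernel

__all__ = ["gsc_check", "smoothness", "ParameterGrid", "bilevel_select", "SelectedParams"]

DEFAULT_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)


def gsc_check(
    partition: Partition, spatial_adj: np.ndarray, strict_geodesic: bool = True
) -> np.ndarray:
    """Per-parcel feasibility flags.

    A parcel passes when it forms one connected component of the spatial
    adjacency graph and (with ``strict_geodesic``) every member is linked
    to the parcel's geodesic center — the node minimizing the maximal
    within-parcel hop distance — by a path that is simultaneously a
    shortest within-ROI path and fully contained in the parcel.
    """
    adj = csr_matrix(spatial_adj)
    flags = np.zeros(partition.k, dtype=int)
    for c in range(1, partition.k + 1):
        nodes = partition.cluster(c)
        if len(nodes) == 1:
            flags[c - 1] = 1
            continue
        sub = adj[np.ix_(nodes, nodes)]
        d_sub = dijkstra(sub, directed=False, unweighted=True)
        ecc = d_sub.max(axis=1)
        if np.isinf(ecc).any():
            continue  # disconnected parcel
        if not strict_geodesic:
            flags[c - 1] = 1
            continue
        center_local = int(np.argmin(ecc))
        d_roi = dijkstra(adj, directed=False, unweighted=True, indices=nodes[center_local])
        # a shortest within-ROI path inside the parcel exists iff the
        # parcel-restricted distance equals the ROI-wide distance
        flags[c - 1] = int(np.allclose(d_sub[center_local], d_roi[nodes]))
    return flags


def smoothness(partition: Partition, spatial_adj: np.ndarray) -> float:
    """Boundary smoothness Sm; 1 for a single parcel, lower (possibly
    negative) as more neighbor pairs are split across parcels."""
    n = partition.n_nodes
    same = partition.labels[:, None] == partition.labels[None, :]
    split_pairs = float((spatial_adj * (~same)).sum())  # both directions
    return (n - split_pairs) / n


@dataclass
class ParameterGrid:
    alphas: tuple = DEFAULT_GRID
    lambdas: tuple = DEFAULT_GRID

    def __post_init__(self) -> None:
        self.alphas = tuple(float(a) for a in self.alphas)
        self.lambdas = tuple(float(l) for l in self.lambdas)
        if not self.alphas or not self.lambdas:
            raise ValueError("parameter grid must be non-empty")
        if min(self.alphas) < 0 or min(self.lambdas) < 0:
            raise ValueError("alpha and lambda must be non-negative")

    def points(self):
        for a in self.alphas:
            for l in self.lambdas:
                yield a, l


@dataclass
class SelectedParams:
    alpha: float
    lam: float
    result: SolveResult
    audit: pd.DataFrame = field(repr=False)


def bilevel_select(
    graph: RoiGraph,
    S: np.ndarray,
    spatial_adj: np.ndarray,
    prior: PriorLabels,
    k: int,
    grid: ParameterGrid | None = None,
    config: SolverConfig | None = None,
    epsilon_nassoc: float = 0.01,
    strict_geodesic: bool = True,
    coords: np.ndarray | None = None,
) -> SelectedParams:
    """Grid-search (alpha, lambda) under the bi-level criterion.

    Solves the partition problem at every grid point, drops points whose
    partition fails any per-parcel feasibility flag, keeps feasible points
    with Nassoc >= (1 - epsilon_nassoc) * best feasible Nassoc, and among
    those returns the point with maximal smoothness (ties: smaller alpha,
    then smaller lambda).  Raises if no grid point is feasible, attaching
    the per-point audit table.
    """
    grid = grid or ParameterGrid()
    config = config or SolverConfig()
    rows = []
    results = {}
    for a, l in grid.points():
        kern = build_kernel(graph, S, spatial_adj, alpha=a, lam=l)
        res = solve(
            kern, k, graph, S=S, R=spatial_adj, prior=prior,
            config=config, spatial_adj=spatial_adj, coords=coords,
        )
        flags = gsc_check(res.partition, spatial_adj, strict_geodesic=strict_geodesic)
        results[(a, l)] = res
        rows.append(
            {
                "alpha": a,
                "lambda": l,
                "feasible": bool(flags.all()),
                "gsc_flags": "".join(map(str, flags)),
                "nassoc": res.objective.nassoc,
                "smoothness": smoothness(res.partition, spatial_adj),
                "J": res.objective.total,
            }
        )
    audit = pd.DataFrame(rows)
    feas = audit[audit["feasible"]]
    if feas.empty:
        raise RuntimeError(
            "no feasible (alpha, lambda) grid point; per-point diagnostics:\n"
            + audit.to_string(index=False)
        )
    best_nassoc = feas["nassoc"].max()
    band = feas[feas["nassoc"] >= (1.0 - epsilon_nassoc) * best_nassoc]
    # maximal smoothness; ties -> smaller alpha, then smaller lambda
    band = band.sort_values(
        ["smoothness", "alpha", "lambda"], ascending=[False, True, True], kind="stable"
    )
    win = band.iloc[0]
    a_star, l_star = float(win["alpha"]), float(win["lambda"])
    return SelectedParams(a_star, l_star, results[(a_star, l_star)], audit)
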