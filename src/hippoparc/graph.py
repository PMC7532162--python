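"""Similarity graph, supervision and spatial matrices, and the solver kernel.

Every ROI voxel is a node of a fully connected undirected graph.  Edge
weights are ``a_uv = r_uv + 1`` where r is the Pearson correlation of the
two voxels' time series, so a_uv lies in [0, 2] with a_uu = 2.  Partial
prior labels induce a supervision matrix S (+1 same prior set, -1
different, 0 if either node is unlabeled), and the voxel lattice induces a
binary spatial adjacency R.  The solver consumes the combined kernel
K = D^-1 (A + alpha*S + lambda*R) D^-1 with node weights W = D, where D is
the diagonal degree matrix of A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import RoiMask

__all__ = [
    "zscore",
    "RoiGraph",
    "pearson_similarity",
    "PriorLabels",
    "build_supervision",
    "build_spatial",
    "KernelSystem",
    "build_kernel",
    "CONNECTIVITY_STENCILS",
]


def zscore(raw: np.ndarray) -> np.ndarray:
    """Row-wise z-scoring with the population (1/T) variance convention.

    Returns an N x T matrix whose rows have mean 0 and standard deviation 1
    exactly (up to float rounding).  A constant row has no direction and is
    rejected; callers may drop such voxels from the ROI beforehand.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise ValueError("need an N x T matrix with T >= 2")
    mean = raw.mean(axis=1, keepdims=True)
    centered = raw - mean
    sd = np.sqrt((centered**2).mean(axis=1, keepdims=True))
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"constant time series at node(s) {bad.tolist()}: cannot z-score"
        )
    return centered / sd


@dataclass
class RoiGraph:
    """Dense similarity graph: A with entries in [0, 2], degrees d = A @ 1."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        if A.min() < -1e-9 or A.max() > 2 + 1e-9:
            raise ValueError("similarity entries must lie in [0, 2]")
        self.A = A
        self.degrees = A.sum(axis=1)
        if (self.degrees <= 0).any():
            raise ValueError("every node must have positive degree")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def links(self, x: np.ndarray, y: np.ndarray) -> float:
        """links(X, Y) = sum of a_uv over u in X, v in Y (ordered pairs)."""
        x = np.asarray(x, dtype=int)
        y = np.asarray(y, dtype=int)
        return float(self.A[np.ix_(x, y)].sum())

    def degree(self, x: np.ndarray) -> float:
        """degree(X) = sum of node degrees over X."""
        return float(self.degrees[np.asarray(x, dtype=int)].sum())


def pearson_similarity(ts: np.ndarray) -> RoiGraph:
    """Similarity graph a_uv = r_uv + 1 from z-scored series.

    For rows with mean 0 and population SD 1, the Pearson correlation is
    r_uv = (1/T) <row_u, row_v>; the diagonal is exactly 2.
    """
    ts = np.asarray(ts, dtype=float)
    n, t = ts.shape
    r = ts @ ts.T / t
    if np.abs(r).max() > 1 + 1e-9:
        raise ValueError("correlation outside [-1, 1]: input rows not z-scored?")
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    a = r + 1.0
    a = (a + a.T) / 2.0
    return RoiGraph(a)


class PriorLabels:
    """Partial supervision: disjoint, non-empty node sets P_1..P_k."""

    def __init__(self, sets: list[np.ndarray], n_nodes: int):
        self.k = len(sets)
        if self.k < 2:
            raise ValueError("need at least 2 prior sets")
        self.n_nodes = int(n_nodes)
        clean = []
        seen = np.zeros(n_nodes, dtype=bool)
        for i, s in enumerate(sets):
            s = np.unique(np.asarray(s, dtype=int))
            if s.size == 0:
                raise ValueError(f"prior set {i + 1} is empty")
            if s.min() < 0 or s.max() >= n_nodes:
                raise ValueError(f"prior set {i + 1} has node ids out of range")
            if seen[s].any():
                raise ValueError("prior sets must be pairwise disjoint")
            seen[s] = True
            clean.append(s)
        self.sets = clean

    @classmethod
    def from_node_labels(cls, labels: np.ndarray, k: int | None = None) -> "PriorLabels":
        """Build from a per-node vector with 0 = unlabeled, 1..k = prior set."""
        labels = np.asarray(labels, dtype=int)
        if k is None:
            k = int(labels.max())
        return cls([np.flatnonzero(labels == i) for i in range(1, k + 1)], len(labels))

    def node_labels(self) -> np.ndarray:
        """Per-node prior label vector (0 = unlabeled)."""
        out = np.zeros(self.n_nodes, dtype=int)
        for i, s in enumerate(self.sets, start=1):
            out[s] = i
        return out


def build_supervision(prior: PriorLabels, n_nodes: int | None = None) -> np.ndarray:
    """Pairwise supervision matrix: s_uv = +1 same prior set (must-link),
    -1 different prior sets (cannot-link), 0 if either node is unlabeled.
    Symmetric with zero diagonal (a node is not a pair with itself)."""
    n = prior.n_nodes if n_nodes is None else int(n_nodes)
    if n < prior.n_nodes:
        raise ValueError("n_nodes smaller than the prior's node range")
    lab = np.zeros(n, dtype=int)
    for i, s in enumerate(prior.sets, start=1):
        lab[s] = i
    labeled = lab > 0
    same = (lab[:, None] == lab[None, :]) & labeled[:, None] & labeled[None, :]
    both = labeled[:, None] & labeled[None, :]
    s_mat = np.where(same, 1, np.where(both, -1, 0)).astype(float)
    np.fill_diagonal(s_mat, 0.0)
    return s_mat


CONNECTIVITY_STENCILS = {6: 1, 18: 2, 26: 3}


def build_spatial(mask: RoiMask, connectivity: int = 26) -> np.ndarray:
    """Binary spatial adjacency over ROI nodes.

    e_uv = 1 iff both voxels are in the ROI and within the 6/18/26
    neighborhood stencil of each other; symmetric with zero diagonal.
    """
    if connectivity not in CONNECTIVITY_STENCILS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    max_manhattan = {6: 1, 18: 2, 26: 3}[connectivity]
    coords = mask.coords
    n = mask.n_nodes
    diff = np.abs(coords[:, None, :] - coords[None, :, :])
    cheb = diff.max(axis=2)
    manh = diff.sum(axis=2)
    adj = (cheb == 1) & (manh <= max_manhattan)
    return adj.astype(float)


@dataclass
class KernelSystem:
    """The solver's kernel K = D^-1 (A + alpha*S + lambda*R) D^-1, W = D."""

    K: np.ndarray
    weights: np.ndarray
    alpha: float
    lam: float


def build_kernel(
    graph: RoiGraph,
    S: np.ndarray | None,
    R: np.ndarray | None,
    alpha: float = 0.0,
    lam: float = 0.0,
) -> KernelSystem:
    if alpha < 0 or lam < 0:
        raise ValueError("alpha and lambda must be non-negative")
    n = graph.n_nodes
    M = graph.A.copy()
    if alpha and S is not None:
        if S.shape != (n, n):
            raise ValueError("supervision matrix dimension mismatch")
        M += alpha * S
    if lam and R is not None:
        if R.shape != (n, n):
            raise ValueError("spatial matrix dimension mismatch")
        M += lam * R
    d_inv = 1.0 / graph.degrees
    K = M * d_inv[:, None] * d_inv[None, :]
    return KernelSystem(K=K, weights=graph.degrees.copy(), alpha=float(alpha), lam=float(lam))
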