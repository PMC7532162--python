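"""Prior-label extraction from a structural parcellation.

A structural parcellation (e.g. head/body/tail subregions of a
hippocampus) is refined into functional supervision labels in three steps:

1. a functional-consistency map — at each voxel, the root-mean-square
   difference between its z-scored signal and those of its in-ROI
   26-connected neighbors (low values = locally homogeneous signal);
2. marker-based watershed flooding of the consistency map inside each
   structural subregion, splitting it into locally homogeneous regions;
3. exhaustive selection of one region per subregion minimizing the
   min-maxcut score

       Mcut_k = sum_i [ sum_{j != i} links(P_i, P_j) ] / links(P_i, P_i),

   the inter- to intra-region similarity ratio (smaller = jointly more
   homogeneous and better separated).

The selected regions P_1..P_k become the partial supervision labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .graph import PriorLabels, RoiGraph
from .volumes import RoiMask

__all__ = [
    "functional_consistency",
    "watershed_subdivide",
    "mcut_score",
    "select_prior",
    "extract_prior",
    "WatershedRegions",
]


def functional_consistency(
    ts: np.ndarray,
    mask: RoiMask,
    spatial_adj: np.ndarray,
    isolated: str = "error",
) -> np.ndarray:
    """Per-node RMS signal difference to in-ROI neighbors.

    value(u) = sqrt( (1 / (|N_u| T)) sum_{v in N_u} sum_t (I_u(t) - I_v(t))^2 )

    pooling all neighbor/timepoint squared differences before the root.
    For z-scored rows this equals sqrt(mean_v 2 (1 - r_uv)).
    """
    ts = np.asarray(ts, dtype=float)
    n, t = ts.shape
    n_nb = spatial_adj.sum(axis=1)
    if (n_nb == 0).any():
        if isolated == "inf":
            pass
        else:
            raise ValueError(
                f"isolated ROI voxel(s) {np.flatnonzero(n_nb == 0).tolist()}: "
                "no in-ROI neighbors"
            )
    # sum_v e_uv ||x_u - x_v||^2 = n_nb*||x_u||^2 - 2 x_u . (E x)_u + (E ||x||^2)_u
    sq = (ts**2).sum(axis=1)
    cross = np.einsum("ut,ut->u", ts, spatial_adj @ ts)
    total = n_nb * sq - 2.0 * cross + spatial_adj @ sq
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(np.maximum(total, 0.0) / (n_nb * t))
    out[n_nb == 0] = np.inf
    return out


@dataclass
class WatershedRegions:
    """Disjoint regions tiling one structural subregion (node-id arrays)."""

    regions: list[np.ndarray]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(r) for r in self.regions])


def watershed_subdivide(
    cmap: np.ndarray, subregion: np.ndarray, mask: RoiMask
) -> WatershedRegions:
    """Split a subregion by marker-based flooding of the consistency map.

    Markers are the regional minima of the map restricted to the subregion
    (26-connectivity); flooding assigns every subregion voxel to exactly
    one marker, so the regions are disjoint, connected, and tile the
    subregion.
    """
    subregion = np.asarray(subregion, dtype=int)
    if subregion.size == 0:
        raise ValueError("empty subregion")
    sub_mask = np.zeros(mask.grid.shape, dtype=bool)
    sub_mask[tuple(mask.coords[subregion].T)] = True

    vol = np.full(mask.grid.shape, np.inf)
    vol[tuple(mask.coords.T)] = cmap
    vol_masked = np.where(sub_mask, vol, np.inf)

    _, n_comp = cc_label(sub_mask, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp > 1:
        warnings.warn(
            f"subregion is not 26-connected ({n_comp} components); "
            "components are flooded separately",
            stacklevel=2,
        )

    minima = local_minima(vol_masked, connectivity=3) & sub_mask
    markers, n_markers = cc_label(minima, structure=np.ones((3, 3, 3), dtype=int))
    if n_markers == 0:
        # a fully constant subregion is one plateau minimum: one region
        # per connected component
        markers, n_markers = cc_label(sub_mask, structure=np.ones((3, 3, 3), dtype=int))
    labels_vol = watershed(vol_masked, markers=markers, mask=sub_mask, connectivity=3)

    node_labels = labels_vol[tuple(mask.coords[subregion].T)]
    if (node_labels == 0).any():  # pragma: no cover - watershed covers the mask
        raise RuntimeError("watershed left subregion voxels unassigned")
    regions = [subregion[node_labels == lab] for lab in range(1, n_markers + 1)]
    regions = [r for r in regions if len(r)]
    return WatershedRegions(regions)


def mcut_score(regions: list[np.ndarray], graph: RoiGraph) -> float:
    """Min-maxcut of a candidate region tuple: inter/intra similarity ratio."""
    k = len(regions)
    intra = np.array([graph.links(r, r) for r in regions])
    if (intra <= 0).any():
        return np.inf
    score = 0.0
    for i in range(k):
        inter = sum(graph.links(regions[i], regions[j]) for j in range(k) if j != i)
        score += inter / intra[i]
    return float(score)


def select_prior(
    regions_by_subregion: list[WatershedRegions],
    graph: RoiGraph,
    min_size: int = 5,
    max_candidates: int | None = None,
) -> tuple[PriorLabels, float, tuple[int, ...]]:
    """Pick one region per subregion minimizing the joint Mcut score.

    All combinations of admissible regions (size >= ``min_size``) are
    evaluated exhaustively; ties break to the lexicographically smallest
    region-index tuple.  ``max_candidates`` optionally pre-filters each
    subregion to its most internally homogeneous regions
    (links(P,P)/|P|^2) to bound the search.

    Returns the prior labels, the winning Mcut value, and the winning
    region-index tuple.
    """
    candidate_lists: list[list[tuple[int, np.ndarray]]] = []
    for si, ws in enumerate(regions_by_subregion):
        cands = [(i, r) for i, r in enumerate(ws.regions) if len(r) >= min_size]
        if not cands:
            raise ValueError(
                f"subregion {si} has no watershed region with >= {min_size} voxels"
            )
        if max_candidates is not None and len(cands) > max_candidates:
            homog = [graph.links(r, r) / len(r) ** 2 for _, r in cands]
            order = np.argsort(homog, kind="stable")[::-1][:max_candidates]
            cands = [cands[i] for i in sorted(order)]
        candidate_lists.append(cands)

    # precompute pairwise link sums between all candidate regions
    best_score = np.inf
    best_combo: tuple[int, ...] | None = None
    best_regions: list[np.ndarray] | None = None
    for combo in itertools.product(*candidate_lists):
        ids = tuple(i for i, _ in combo)
        regions = [r for _, r in combo]
        score = mcut_score(regions, graph)
        if score < best_score - 1e-15 or (
            abs(score - best_score) <= 1e-15 and (best_combo is None or ids < best_combo)
        ):
            best_score = score
            best_combo = ids
            best_regions = regions
    if best_regions is None:
        raise ValueError("no admissible region combination")
    prior = PriorLabels(best_regions, graph.n_nodes)
    return prior, best_score, best_combo


def extract_prior(
    ts: np.ndarray,
    mask: RoiMask,
    spatial_adj: np.ndarray,
    structural_labels: np.ndarray,
    graph: RoiGraph,
    min_size: int = 5,
    max_candidates: int | None = None,
) -> tuple[PriorLabels, dict]:
    """Full prior-extraction pipeline on per-node structural labels 1..k.

    Returns the prior plus a report dict (Mcut value, candidate counts).
    """
    structural_labels = np.asarray(structural_labels, dtype=int)
    subregion_ids = np.unique(structural_labels[structural_labels > 0])
    if len(subregion_ids) < 2:
        raise ValueError("need at least 2 structural subregions")
    cmap = functional_consistency(ts, mask, spatial_adj)
    regions_by_sub = []
    for sid in subregion_ids:
        nodes = np.flatnonzero(structural_labels == sid)
        regions_by_sub.append(watershed_subdivide(cmap, nodes, mask))
    prior, score, combo = select_prior(
        regions_by_sub, graph, min_size=min_size, max_candidates=max_candidates
    )
    report = {
        "mcut": score,
        "selected_regions": list(combo),
        "n_candidates": [len(ws.regions) for ws in regions_by_sub],
        "prior_sizes": [int(len(s)) for s in prior.sets],
    }
    return prior, report
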