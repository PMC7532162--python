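"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use explicit Python double loops over node pairs
so they share no code path with the vectorized implementations they
check.
"""

import numpy as np
import pytest

from hippoparc import SyntheticSpec, generate
from hippoparc.volumes import RoiMask, VolumeGrid


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_study():
    """Default synthetic study (ellipsoid ROI, ~300 voxels, k=3)."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture()
def box_mask():
    """Solid 4 x 3 x 2 box ROI (24 voxels)."""
    grid = VolumeGrid((4, 3, 2))
    return RoiMask(grid, np.ones((4, 3, 2), dtype=bool))


def random_similarity(rng, n):
    """Random symmetric similarity matrix with entries in [0,2], diag 2."""
    a = rng.uniform(0, 2, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 2.0)
    return a


def random_partition_labels(rng, n, k):
    """Random labels 1..k with every cluster non-empty."""
    labels = rng.integers(1, k + 1, size=n)
    labels[rng.choice(n, size=k, replace=False)] = np.arange(1, k + 1)
    return labels


# ------------------------------------------------------- brute-force oracles


def nassoc_oracle(labels, A):
    k = labels.max()
    deg = A.sum(axis=1)
    total = 0.0
    for c in range(1, k + 1):
        links = 0.0
        degree = 0.0
        for u in range(len(labels)):
            if labels[u] != c:
                continue
            degree += deg[u]
            for v in range(len(labels)):
                if labels[v] == c:
                    links += A[u, v]
        total += links / degree
    return total


def supervision_oracle(labels, prior_sets, A):
    """Literal double summation of the supervision term: per cluster,
    ordered same-prior pairs (u != v) at +1 plus unordered cross-prior
    pairs at -1, over the cluster degree."""
    deg = A.sum(axis=1)
    k = labels.max()
    n_prior = len(prior_sets)
    total = 0.0
    for c in range(1, k + 1):
        members = {u for u in range(len(labels)) if labels[u] == c}
        degree = sum(deg[u] for u in members)
        same = 0.0
        for i in range(n_prior):
            in_c = [u for u in prior_sets[i] if u in members]
            for u in in_c:
                for v in in_c:
                    if u != v:
                        same += 1.0
        cross = 0.0
        for i in range(n_prior):
            for j in range(i + 1, n_prior):
                for u in prior_sets[i]:
                    if u not in members:
                        continue
                    for v in prior_sets[j]:
                        if v in members:
                            cross += -1.0
        total += (same + cross) / degree
    return total


def spatial_oracle(labels, R, A):
    deg = A.sum(axis=1)
    k = labels.max()
    total = 0.0
    for c in range(1, k + 1):
        within = 0.0
        degree = 0.0
        for u in range(len(labels)):
            if labels[u] != c:
                continue
            degree += deg[u]
            for v in range(len(labels)):
                if labels[v] == c:
                    within += R[u, v]
        total += within / degree
    return total


def smoothness_oracle(labels, R):
    n = len(labels)
    split = 0.0
    for u in range(n):
        for v in range(n):
            if R[u, v] and labels[u] != labels[v]:
                split += 1.0
    return (n - split) / n


def mcut_oracle(regions, A):
    total = 0.0
    for i, ri in enumerate(regions):
        intra = sum(A[u, v] for u in ri for v in ri)
        inter = 0.0
        for j, rj in enumerate(regions):
            if j == i:
                continue
            inter += sum(A[u, v] for u in ri for v in rj)
        total += inter / intra
    return total


def silhouette_oracle(labels, A):
    n = len(labels)
    k = labels.max()
    total = 0.0
    for c in range(1, k + 1):
        members = [u for u in range(n) if labels[u] == c]
        others = [u for u in range(n) if labels[u] != c]
        n_c = len(members)
        a_c = sum(A[u, v] for u in members for v in members if u != v) / (
            n_c * (n_c - 1)
        )
        b_c = sum(A[u, v] for u in members for v in others) / (n_c * (n - n_c))
        total += (a_c - b_c) / max(a_c, b_c)
    return total / k


def dice_oracle(x, y, k):
    """Identity-matching mean Dice by direct set counting."""
    total = 0.0
    for i in range(1, k + 1):
        xi = {u for u in range(len(x)) if x[u] == i}
        yi = {u for u in range(len(y)) if y[u] == i}
        denom = len(xi) + len(yi)
        total += 2 * len(xi & yi) / denom if denom else 0.0
    return total / k


def enumerate_partitions(n, k):
    """All label vectors over n nodes with exactly k non-empty clusters,
    up to cluster relabeling (first occurrences in increasing order)."""
    out = []

    def rec(prefix, used):
        if len(prefix) == n:
            if used == k:
                out.append(np.array(prefix))
            return
        if used + (n - len(prefix)) < k:
            return
        for lab in range(1, min(used + 1, k) + 1):
            rec(prefix + [lab], max(used, lab))

    rec([1], 1)
    return out
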