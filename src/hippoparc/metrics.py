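"""Evaluation metrics: homogeneity, reproducibility, group maps, and
functional-connectivity statistics.

Homogeneity uses a similarity-based silhouette

    SI_k = (1/k) sum_c (a_c - b_c) / max(a_c, b_c)

with a_c the mean within-parcel similarity (self-pairs excluded) and b_c
the mean similarity to all out-of-parcel voxels; higher is better.
Reproducibility is the multi-cluster Dice coefficient, averaged over
parcels after an optional maximum-overlap label matching.  Connectivity
statistics follow the usual resting-state pipeline: parcel-mean to
region-mean Pearson correlation, Fisher z transform, one-sample t-tests
across subjects with Benjamini-Hochberg FDR control, and an age
regression with sex adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .clustering import Partition
from .graph import RoiGraph, zscore

__all__ = [
    "silhouette",
    "dice",
    "match_labels",
    "group_maps",
    "fisher_z",
    "parcel_region_fc",
    "group_fc_test",
    "age_regression",
    "AgeModelFit",
]


def silhouette(partition: Partition, graph: RoiGraph) -> float:
    """Similarity-based silhouette SI_k of a partition."""
    labels = partition.labels
    n = partition.n_nodes
    total = 0.0
    for c in range(1, partition.k + 1):
        members = np.flatnonzero(labels == c)
        n_c = len(members)
        if n_c < 2:
            raise ValueError(f"cluster {c} is a singleton: within-similarity undefined")
        if n_c == n:
            raise ValueError("single cluster covers the ROI: out-similarity undefined")
        others = np.flatnonzero(labels != c)
        block = graph.A[np.ix_(members, members)]
        a_c = (block.sum() - np.trace(block)) / (n_c * (n_c - 1))
        b_c = graph.A[np.ix_(members, others)].sum() / (n_c * (n - n_c))
        total += (a_c - b_c) / max(a_c, b_c)
    return total / partition.k


def match_labels(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Permutation of y's labels maximizing total overlap with x.

    Returns ``perm`` with perm[j] = label in x-space that y's label j+1
    maps to (maximum-total-intersection assignment).
    """
    overlap = np.zeros((k, k))
    for i in range(1, k + 1):
        xi = x == i
        for j in range(1, k + 1):
            overlap[i - 1, j - 1] = np.count_nonzero(xi & (y == j))
    row, col = linear_sum_assignment(-overlap)
    perm = np.empty(k, dtype=int)
    perm[col] = row + 1
    return perm


def dice(
    x: np.ndarray, y: np.ndarray, k: int, matching: str = "optimal_overlap"
) -> float:
    """Mean multi-cluster Dice = (1/k) sum_i 2|X_i ∩ Y_i| / (|X_i| + |Y_i|).

    ``matching='optimal_overlap'`` first permutes y's labels by the
    maximum-total-overlap assignment; ``'identity'`` compares labels as-is.
    Only voxels labeled (> 0) in either map participate through the set
    cardinalities.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError("label vectors must share a voxel domain")
    kx = int(x.max())
    ky = int(y.max())
    if kx != ky:
        raise ValueError(f"partitions have different k: {kx} vs {ky}")
    if matching == "optimal_overlap":
        perm = match_labels(x, y, k)
        y = np.where(y > 0, perm[y - 1], 0)
    elif matching != "identity":
        raise ValueError("matching must be 'optimal_overlap' or 'identity'")
    total = 0.0
    for i in range(1, k + 1):
        xi = x == i
        yi = y == i
        denom = xi.sum() + yi.sum()
        total += 2.0 * np.count_nonzero(xi & yi) / denom if denom else 0.0
    return total / k


def group_maps(label_volumes: list[np.ndarray], k: int):
    """Per-parcel frequency maps and the maximum probability map (MPM).

    Frequencies are each voxel's share of subjects assigning each parcel
    label (denominator = number of subjects).  The MPM assigns each voxel
    its most frequent label, ties to the lower label id; voxels labeled by
    no subject stay background 0.
    """
    if not label_volumes:
        raise ValueError("need at least one label map")
    shape = label_volumes[0].shape
    n_subj = len(label_volumes)
    freq = np.zeros((k,) + shape)
    for vol in label_volumes:
        if vol.shape != shape:
            raise ValueError("inconsistent grids across label maps")
        for i in range(1, k + 1):
            freq[i - 1] += vol == i
    freq /= n_subj
    mpm = np.where(freq.sum(axis=0) > 0, np.argmax(freq, axis=0) + 1, 0)
    return freq, mpm.astype(np.int16)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform z = arctanh(r), with |r| clipped to
    1 - 1e-12 to keep z finite at perfect correlation."""
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def parcel_region_fc(
    roi_ts: np.ndarray,
    parcel_labels: np.ndarray,
    region_ts: dict[str, np.ndarray],
    min_region_voxels: int = 5,
    region_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One subject's parcel-to-region functional connectivity table.

    ``roi_ts`` is the raw node-by-time ROI matrix and ``parcel_labels`` the
    per-node parcel assignment; ``region_ts`` maps region names to raw
    voxel-by-time matrices (or precomputed mean series).  Signals are
    z-scored, averaged within parcel/region, correlated, and Fisher
    z-transformed.  Regions smaller than ``min_region_voxels`` are skipped
    with a warning entry rather than an error.
    """
    z_roi = zscore(roi_ts)
    rows = []
    for name, ts in region_ts.items():
        ts = np.atleast_2d(np.asarray(ts, dtype=float))
        size = region_sizes.get(name, ts.shape[0]) if region_sizes else ts.shape[0]
        if size < min_region_voxels:
            continue
        region_mean = zscore(ts).mean(axis=0)
        for c in np.unique(parcel_labels[parcel_labels > 0]):
            parcel_mean = z_roi[parcel_labels == c].mean(axis=0)
            r = float(np.corrcoef(parcel_mean, region_mean)[0, 1])
            rows.append(
                {"parcel": int(c), "region": name, "r": r, "z": float(fisher_z(r))}
            )
    return pd.DataFrame(rows)


def group_fc_test(tables: list[pd.DataFrame], q: float = 0.05) -> pd.DataFrame:
    """Group-level connectivity significance across subjects.

    For each (parcel, region) pair, a one-sample t-test of the subjects'
    Fisher z values against zero; the t statistic is mapped to a standard
    normal z through its two-sided tail probability (sign preserved), and
    Benjamini-Hochberg FDR is applied across all pairs at level ``q``.
    Pairs with zero variance across subjects are excluded.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 subjects")
    stacked = pd.concat(tables, keys=range(len(tables)), names=["subject"])
    rows = []
    for (parcel, region), grp in stacked.groupby(["parcel", "region"], sort=True):
        z_vals = grp["z"].to_numpy()
        if np.ptp(z_vals) == 0:
            continue  # zero variance across subjects: t undefined or infinite
        t_stat, p = scipy.stats.ttest_1samp(z_vals, 0.0)
        z_group = np.sign(t_stat) * scipy.stats.norm.isf(p / 2.0)
        rows.append(
            {
                "parcel": parcel,
                "region": region,
                "mean_z": z_vals.mean(),
                "t": float(t_stat),
                "p": float(p),
                "z_group": float(z_group),
                "n_subjects": len(z_vals),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    reject, p_adj, _, _ = multipletests(out["p"], alpha=q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


@dataclass
class AgeModelFit:
    """OLS fit of connectivity on age with sex adjustment."""

    beta0: float
    beta1: float  # age slope
    beta2: float  # sex effect (female 0, male 1); NaN if sex dropped
    residuals: np.ndarray
    fc_adjusted: np.ndarray
    r_age: float
    p_age: float
    beta1_se: float


def age_regression(
    fc: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    subtract_residuals: bool = False,
) -> AgeModelFit:
    """Linear aging model  FC = b0 + b1*Age + b2*Sex + eps  (OLS).

    The sex-adjusted connectivity is FC* = FC - b2*Sex by default; with
    ``subtract_residuals`` the residuals are removed as well, leaving the
    pure fitted age component b0 + b1*Age (whose correlation with age is
    +-1 by construction whenever b1 != 0).  Reports the Pearson
    correlation of FC* with age and its p-value.  If all subjects share
    one sex the sex column is dropped.
    """
    fc = np.asarray(fc, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    m = len(fc)
    if m < 4:
        raise ValueError("need at least 4 subjects")
    drop_sex = np.all(sex == sex[0])
    if drop_sex:
        X = np.column_stack([np.ones(m), age])
    else:
        X = np.column_stack([np.ones(m), age, sex])
    beta, _, _, _ = np.linalg.lstsq(X, fc, rcond=None)
    fitted = X @ beta
    resid = fc - fitted
    dof = m - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta2 = np.nan if drop_sex else float(beta[2])
    fc_star = fc - (0.0 if drop_sex else beta2 * sex)
    if subtract_residuals:
        fc_star = fc_star - resid
    r_age, p_age = scipy.stats.pearsonr(fc_star, age)
    return AgeModelFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=beta2,
        residuals=resid,
        fc_adjusted=fc_star,
        r_age=float(r_age),
        p_age=float(p_age),
        beta1_se=float(np.sqrt(cov[1, 1])),
    )
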