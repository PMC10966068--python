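"""Comparing asymmetry patterns: correlations, spin nulls, clustering.

Pairwise Pearson correlations between 65-region coefficient maps are
tested against a spatial null that preserves the maps' spatial
autocorrelation: cortical parcels are reassigned by uniformly random
3-D rotations of their spherical centroids (the mirrored, x-flip
conjugate rotation applies to the right hemisphere), while subcortical
and cerebellar parcels — for which a spherical rotation has no
geometric meaning — are permuted uniformly within tissue class.
Empirical p-values are two-sided with add-one smoothing, so the
smallest attainable p is 1/(n_spin+1).  Pattern sets are summarised by
Ward hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .atlas import CORTICAL, AtlasSpec
from .effects import benjamini_hochberg

fdr_correct = benjamini_hochberg  # one BH routine package-wide


def pattern_correlation(a, b) -> float:
    """Pearson correlation between two equal-length coefficient maps."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance pattern")
    return float(stats.pearsonr(a, b)[0])


def random_rotations(n: int, rng) -> np.ndarray:
    """n uniform SO(3) rotation matrices via normalised quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def mirror_conjugate(R: np.ndarray) -> np.ndarray:
    """The x-flip conjugate M R M (M = diag(-1,1,1)) for the right hemisphere."""
    M = np.diag([-1.0, 1.0, 1.0])
    return M @ R @ M


def _assign_nearest(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """For each original centroid, the index of the nearest rotated one.

    Ties are broken by the lowest region index (argmin convention).
    Duplicates are permitted: several targets may draw from one source.
    """
    # squared distances; (n_orig, n_rot)
    d2 = (
        np.sum(original**2, axis=1)[:, None]
        - 2.0 * original @ rotated.T
        + np.sum(rotated**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def spin_null(
    atlas: AtlasSpec, n_spin: int = 1000, seed: int = 0
) -> np.ndarray:
    """(n_spin, n_regions) integer index maps defining the spatial null.

    Row s permutes a 65-vector as ``values[assignment[s]]``.  Cortical
    entries come from nearest-centroid reassignment under one random
    rotation of the left-hemisphere centroids (the mirrored rotation of
    the mirrored right hemisphere yields the identical assignment in
    this hemisphere-symmetric atlas); subcortical and cerebellar entries
    are uniform within-class permutations.
    """
    if n_spin < 1:
        raise ValueError("n_spin must be >= 1")
    cort = atlas.indices_of(CORTICAL)
    if len(cort) == 0:
        raise ValueError("atlas has no cortical centroids to rotate")
    pts = atlas.centroid_left[cort]
    if not np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-9):
        raise ValueError("cortical centroids must lie on the unit sphere")
    rng = np.random.default_rng(seed)
    R = random_rotations(n_spin, rng)
    rotated = np.einsum("sij,kj->ski", R, pts)  # (n_spin, n_cort, 3)
    table = np.tile(np.arange(atlas.n_regions), (n_spin, 1))
    for s in range(n_spin):
        table[s, cort] = cort[_assign_nearest(pts, rotated[s])]
    for tissue in set(atlas.tissue_class) - {CORTICAL}:
        idx = atlas.indices_of(tissue)
        for s in range(n_spin):
            table[s, idx] = rng.permutation(idx)
    return table


@dataclass
class SpinTestResult:
    label_a: str
    label_b: str
    r_obs: float
    null_r: np.ndarray
    p_empirical: float
    n_spin: int


def spin_test(
    a, b, null_table: np.ndarray, label_a: str = "a", label_b: str = "b"
) -> SpinTestResult:
    """Two-sided empirical p for corr(a, b) against the spin null.

    null_r[s] = corr(a, b[null_table[s]]); p = (1 + #{|null| >= |obs|})
    / (1 + n_spin).  A spin that degenerates b to a constant vector
    contributes r = 0 with a warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_spin = null_table.shape[0]
    if n_spin < 1:
        raise ValueError("empty null table")
    if null_table.shape[1] != len(a) or len(a) != len(b):
        raise ValueError("vector length must match the null table")
    r_obs = pattern_correlation(a, b)
    perms = b[null_table]  # (n_spin, n)
    az = a - a.mean()
    pz = perms - perms.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(az) * np.linalg.norm(pz, axis=1)
    null_r = np.zeros(n_spin)
    ok = denom > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} degenerate spin(s); their r set to 0")
    null_r[ok] = (pz[ok] @ az) / denom[ok]
    p = (1.0 + np.sum(np.abs(null_r) >= np.abs(r_obs))) / (1.0 + n_spin)
    return SpinTestResult(
        label_a=label_a,
        label_b=label_b,
        r_obs=r_obs,
        null_r=null_r,
        p_empirical=float(p),
        n_spin=n_spin,
    )


def pairwise_spin_tests(
    patterns: dict, null_table: np.ndarray, q: float = 0.05
):
    """All-pairs correlation matrix, spin p matrix and BH-adjusted p.

    Returns (r_df, p_df, p_fdr_df); the FDR family is the set of
    distinct pairs.
    """
    labels = list(patterns)
    k = len(labels)
    r = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    p = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            res = spin_test(
                patterns[labels[i]], patterns[labels[j]], null_table,
                labels[i], labels[j],
            )
            r.iloc[i, j] = r.iloc[j, i] = res.r_obs
            p.iloc[i, j] = p.iloc[j, i] = res.p_empirical
            pairs.append((i, j))
            pvals.append(res.p_empirical)
    p_adj_flat, _ = benjamini_hochberg(np.array(pvals), q=q)
    p_adj = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for (i, j), padj in zip(pairs, p_adj_flat):
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = padj
    return r, p, p_adj


@dataclass
class ClusterResult:
    """Ward-linkage dendrogram over a set of coefficient patterns."""

    labels: tuple
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: tuple

    def flat_clusters(self, k: int) -> dict:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "labels": list(self.labels),
                    "linkage": self.linkage.tolist(),
                    "leaf_order": list(self.leaf_order),
                },
                indent=1,
            )
        )


def ward_cluster(patterns: dict) -> ClusterResult:
    """Agglomerative Ward clustering of patterns on Euclidean distance."""
    labels = list(patterns)
    if len(labels) < 2:
        raise ValueError("need at least two patterns")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate pattern labels")
    X = np.vstack([np.asarray(patterns[l], float) for l in labels])
    Z = hierarchy.linkage(pdist(X), method="ward")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        labels=tuple(labels),
        linkage=Z,
        leaf_order=tuple(np.asarray(labels, object)[order].tolist()),
    )
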