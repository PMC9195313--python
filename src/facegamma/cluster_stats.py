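"""Two-group cluster-based permutation statistics on time-frequency maps.

One map per subject (a patient-region face-minus-mosaic dB map); the group
comparison is a pooled-variance two-sample t-test per pixel.  Cluster-level
inference follows the max/min-sum permutation scheme: pixels below the
two-tailed p = 0.05 voxel threshold are removed, 4-connected components are
summed, and the observed cluster sums are compared against the 95th
percentile of permutation maxima (positive clusters) and the 5th percentile
of permutation minima (negative clusters).  Positive t means group O > M.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import ndimage, stats

__all__ = ["pixel_tmap", "cluster_permutation", "ClusterResult", "Cluster"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def pixel_tmap(maps_o: np.ndarray, maps_m: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per pixel; positive = group O > group M."""
    maps_o = np.asarray(maps_o, dtype=float)
    maps_m = np.asarray(maps_m, dtype=float)
    n1, n2 = maps_o.shape[0], maps_m.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subject maps per group")
    m1, m2 = maps_o.mean(axis=0), maps_m.mean(axis=0)
    v1 = maps_o.var(axis=0, ddof=1)
    v2 = maps_m.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


@dataclass(frozen=True)
class Cluster:
    sign: int           # +1 or -1
    t_sum: float
    n_pixels: int
    pixels: np.ndarray  # boolean mask, freqs x time
    freq_idx: tuple     # (min, max) frequency-bin indices
    time_idx: tuple


@dataclass
class ClusterResult:
    tmap: np.ndarray
    voxel_threshold: float
    clusters: list          # surviving clusters only
    all_clusters: list      # every suprathreshold cluster in the real map
    null_max: np.ndarray
    null_min: np.ndarray
    thr_hi: float
    thr_lo: float
    surviving_mask: np.ndarray
    n_perm: int
    seed: object


def _cluster_sums(t: np.ndarray, thr: float):
    """(positive cluster sums with labels, negative cluster sums with labels)."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) >= thr
        labels, n = ndimage.label(mask, structure=_CROSS)
        if n == 0:
            out.append((np.empty(0), labels, n))
            continue
        sums = ndimage.sum_labels(t, labels, index=np.arange(1, n + 1))
        out.append((sums, labels, n))
    return out


def cluster_permutation(maps_o, maps_m, n_perm: int = 3000,
                        voxel_p: float = 0.05, seed=None,
                        rng=None) -> ClusterResult:
    """Full cluster-based permutation test between two groups of subject maps.

    Per permutation the subject maps are randomly reassigned to two groups of
    the original sizes; the maximum positive and minimum negative cluster sum
    of each permuted map (0 when no cluster) build the null distributions.
    """
    maps_o = np.asarray(maps_o, dtype=float)
    maps_m = np.asarray(maps_m, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n1, n2 = maps_o.shape[0], maps_m.shape[0]
    df = n1 + n2 - 2
    thr = stats.t.ppf(1.0 - voxel_p / 2.0, df)

    t_obs = pixel_tmap(maps_o, maps_m)
    (pos_sums, pos_lab, npos), (neg_sums, neg_lab, nneg) = _cluster_sums(t_obs, thr)

    if comb(n1 + n2, n1) < n_perm:
        warnings.warn("fewer distinct group assignments than permutations; "
                      "sampling with replacement")

    stacked = np.concatenate([maps_o, maps_m], axis=0)
    null_max = np.zeros(n_perm)
    null_min = np.zeros(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n1 + n2)
        t_p = pixel_tmap(stacked[perm[:n1]], stacked[perm[n1:]])
        (ps, _, _), (ns, _, _) = _cluster_sums(t_p, thr)
        if ps.size:
            null_max[i] = ps.max()
        if ns.size:
            null_min[i] = ns.min()

    thr_hi = float(np.percentile(null_max, 95.0))
    thr_lo = float(np.percentile(null_min, 5.0))

    all_clusters, surviving = [], []
    surviving_mask = np.zeros_like(t_obs, dtype=bool)
    for sums, labels, n, sign in ((pos_sums, pos_lab, npos, 1),
                                  (neg_sums, neg_lab, nneg, -1)):
        for k in range(n):
            pix = labels == (k + 1)
            fi, ti = np.nonzero(pix)
            cl = Cluster(sign, float(sums[k]), int(pix.sum()), pix,
                         (int(fi.min()), int(fi.max())),
                         (int(ti.min()), int(ti.max())))
            all_clusters.append(cl)
            if (sign > 0 and cl.t_sum >= thr_hi) or \
               (sign < 0 and cl.t_sum <= thr_lo):
                surviving.append(cl)
                surviving_mask |= pix

    return ClusterResult(t_obs, float(thr), surviving, all_clusters,
                         null_max, null_min, thr_hi, thr_lo, surviving_mask,
                         n_perm, seed)
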