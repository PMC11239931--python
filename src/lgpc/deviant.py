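"""Deviant-response contrasts and cluster-based permutation significance.

A deviant response is a significant difference in ERSP between the deviant
and standard sequences of a block, assessed separately for the two
contrasts c1 = xy|xx - xx|xx and c2 = xy|xy - xx|xy. Significance of the
per-bin two-sample t map is corrected for multiple comparisons with a
nonparametric cluster-based permutation test:

1. threshold the t map at the two-sided per-bin alpha quantile of the t
   distribution (cluster-forming threshold),
2. form positive and negative clusters by 4-connectivity on the
   frequency x time grid, with cluster mass = summed t,
3. build the null distribution of the maximum |mass| over seeded trial-label
   permutations (both signs pooled), and
4. keep clusters whose corrected p-value is at most alpha.

Non-significant bins of the difference map are set to 0; negative clusters
are preserved with their sign. An IC with at least one significant cluster
in either contrast is a *significant IC*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import Dataset

__all__ = ["CONTRASTS", "Cluster", "ClusterResult", "DeviantResponse",
           "ersp_contrast", "cluster_permutation", "deviant_responses",
           "select_significant_ics", "cluster_table"]

#: (deviant trial type, standard trial type) per contrast, in tensor order.
CONTRASTS = (("xy|xx", "xx|xx"), ("xy|xy", "xx|xy"))
CONTRAST_NAMES = ("xy|xx - xx|xx", "xy|xy - xx|xy")

# 4-neighborhood (no diagonals) on the freq x time grid
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _t_stats_from_sums(sa, ssa, sb, ssb, na, nb):
    """Two-sample pooled-variance t from per-group sums and sums of squares."""
    ma, mb = sa / na, sb / nb
    va = (ssa - na * ma ** 2) / (na - 1)
    vb = (ssb - nb * mb ** 2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.clip(sp2, 0, None) * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def ersp_contrast(trials_deviant: np.ndarray, trials_standard: np.ndarray):
    """Difference of group means and the per-bin two-sample t statistic.

    Both inputs are (n_trials, n_freqs, n_times) dB stacks; returns
    (difference map, t map) on the (n_freqs, n_times) grid.
    """
    a = np.asarray(trials_deviant, dtype=float)
    b = np.asarray(trials_standard, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("expected matching (n_trials, n_freqs, n_times) stacks")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per group")
    diff = a.mean(axis=0) - b.mean(axis=0)
    t = _t_stats_from_sums(a.sum(0), (a ** 2).sum(0), b.sum(0), (b ** 2).sum(0),
                           len(a), len(b))
    return diff, t


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold cluster of the t map."""

    cluster_id: int
    sign: int                   # +1 or -1
    mass: float                 # summed t statistic (signed)
    p_corrected: float
    bbox: tuple[int, int, int, int]  # (fmin, fmax, tmin, tmax), inclusive bin indices
    n_bins: int


@dataclass
class ClusterResult:
    """Cluster-permutation outcome for one IC x contrast."""

    mask: np.ndarray            # bool, significant bins
    clusters: list[Cluster]
    t_map: np.ndarray
    diff_map: np.ndarray
    threshold: float            # cluster-forming |t| threshold
    n_permutations: int

    @property
    def masked_diff(self) -> np.ndarray:
        """Difference map with non-significant bins set to 0 (sign preserved)."""
        return np.where(self.mask, self.diff_map, 0.0)

    @property
    def significant(self) -> bool:
        return bool(self.mask.any())


def _clusters_and_masses(t_map: np.ndarray, threshold: float):
    """Label positive and negative suprathreshold clusters; return
    (labels array with unique ids, list of (id, sign, mass, n_bins))."""
    out_labels = np.zeros(t_map.shape, dtype=int)
    info = []
    next_id = 1
    for sign in (1, -1):
        supra = (sign * t_map) > threshold
        lab, n = ndimage.label(supra, structure=_STRUCTURE)
        if n == 0:
            continue
        masses = ndimage.sum_labels(t_map, lab, index=np.arange(1, n + 1))
        sizes = ndimage.sum_labels(np.ones_like(t_map), lab, index=np.arange(1, n + 1))
        for j in range(n):
            out_labels[lab == j + 1] = next_id
            info.append((next_id, sign, float(masses[j]), int(sizes[j])))
            next_id += 1
    return out_labels, info


def cluster_permutation(trials_deviant: np.ndarray, trials_standard: np.ndarray,
                        n_permutations: int = 500, alpha: float = 0.05,
                        seed: int | np.random.Generator = 0,
                        batch_size: int = 100) -> ClusterResult:
    """Two-sided cluster-based permutation test of a deviant-vs-standard contrast.

    Trial labels are exchangeable under the null; each permutation fully
    relabels the pooled trials. The null statistic is the maximum absolute
    cluster mass over both signs; corrected p-values use the standard
    (1 + #{null >= observed}) / (n_permutations + 1) estimator.
    """
    a = np.asarray(trials_deviant, dtype=float)
    b = np.asarray(trials_standard, dtype=float)
    diff, t_obs = ersp_contrast(a, b)
    na, nb = len(a), len(b)
    if n_permutations < 1.0 / alpha:
        warnings.warn(
            f"{n_permutations} permutations cannot resolve p <= {alpha}; "
            "increase n_permutations", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    df = na + nb - 2
    threshold = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    grid_shape = t_obs.shape

    labels, info = _clusters_and_masses(t_obs, threshold)
    pooled = np.concatenate([a, b], axis=0).reshape(na + nb, -1)
    pooled_sq = pooled ** 2
    tot = pooled.sum(axis=0)
    tot_sq = pooled_sq.sum(axis=0)

    null_max = np.zeros(n_permutations)
    done = 0
    while done < n_permutations:
        nb_batch = min(batch_size, n_permutations - done)
        # selection matrix for group A in each permutation
        sel = np.zeros((nb_batch, na + nb))
        for i in range(nb_batch):
            sel[i, rng.permutation(na + nb)[:na]] = 1.0
        sa = sel @ pooled
        ssa = sel @ pooled_sq
        t_perm = _t_stats_from_sums(sa, ssa, tot - sa, tot_sq - ssa, na, nb)
        for i in range(nb_batch):
            _, pinfo = _clusters_and_masses(t_perm[i].reshape(grid_shape), threshold)
            if pinfo:
                null_max[done + i] = max(abs(m) for _, _, m, _ in pinfo)
        done += nb_batch

    clusters = []
    mask = np.zeros(grid_shape, dtype=bool)
    for cid, sign, mass, nbins in info:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (n_permutations + 1.0)
        member = labels == cid
        fi, ti = np.nonzero(member)
        c = Cluster(cluster_id=cid, sign=sign, mass=mass, p_corrected=float(p),
                    bbox=(int(fi.min()), int(fi.max()), int(ti.min()), int(ti.max())),
                    n_bins=nbins)
        clusters.append(c)
        if p <= alpha:
            mask |= member

    return ClusterResult(mask=mask, clusters=clusters, t_map=t_obs, diff_map=diff,
                         threshold=threshold, n_permutations=n_permutations)


@dataclass
class DeviantResponse:
    """Masked deviant responses of one IC: one ClusterResult per contrast."""

    ic: int
    results: tuple[ClusterResult, ClusterResult]

    @property
    def significant(self) -> bool:
        return any(r.significant for r in self.results)

    def masked_maps(self) -> np.ndarray:
        """(2, n_freqs, n_times) masked difference maps, contrast-ordered."""
        return np.stack([r.masked_diff for r in self.results])


def deviant_responses(dataset: Dataset, n_permutations: int = 500,
                      alpha: float = 0.05, seed: int = 0) -> list[DeviantResponse]:
    """Per-IC, per-contrast masked deviant responses for a whole dataset."""
    responses = []
    rng = np.random.default_rng(seed)
    for ic in range(dataset.n_ics):
        per_contrast = []
        for dev_type, std_type in CONTRASTS:
            res = cluster_permutation(
                dataset.trials_of(dev_type)[:, ic],
                dataset.trials_of(std_type)[:, ic],
                n_permutations=n_permutations, alpha=alpha, seed=rng)
            per_contrast.append(res)
        responses.append(DeviantResponse(ic=ic, results=tuple(per_contrast)))
    return responses


def select_significant_ics(responses: list[DeviantResponse]) -> list[int]:
    """ICs with at least one significant cluster in either contrast."""
    return [r.ic for r in responses if r.significant]


def cluster_table(responses: list[DeviantResponse]) -> pd.DataFrame:
    """Flat cluster summary (ic, contrast, cluster id, mass, p, bbox)."""
    rows = []
    for r in responses:
        for ci, res in enumerate(r.results):
            for c in res.clusters:
                rows.append({
                    "ic": r.ic, "contrast": CONTRAST_NAMES[ci],
                    "cluster_id": c.cluster_id, "sign": c.sign,
                    "mass": c.mass, "n_bins": c.n_bins,
                    "p_corrected": c.p_corrected,
                    "f_min": c.bbox[0], "f_max": c.bbox[1],
                    "t_min": c.bbox[2], "t_max": c.bbox[3],
                })
    return pd.DataFrame(rows, columns=["ic", "contrast", "cluster_id", "sign", "mass",
                                       "n_bins", "p_corrected", "f_min", "f_max",
                                       "t_min", "t_max"])
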