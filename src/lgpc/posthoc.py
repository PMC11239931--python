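"""Component signatures, single-trial projection variability, and the
consistency-threshold sensitivity sweep.

Signature summaries describe the significant ICs and the fitted PE1/PE2
components: joint topography (per-IC normalized |spatial coefficients|
averaged across significant ICs), regional contribution fractions
(pTC/aTC/aPFC), peak latency after fifth-tone onset, amplitude-weighted
mean frequency, and the min/max contrast values.

Single-trial projections collapse a trial's ERSP onto a component's
spatio-spectro-temporal structure: scalar = S * ERSP * FT, summing the
product of IC loadings S, the trial's per-IC time-frequency maps, and a
spectro-temporal structure FT. FT is the across-dataset average of the
normalized component maps, gated by a high-gamma mask (top 75% of values
above 40 Hz); by default the weighted values inside the mask are used
(a binary-mask variant is available).

The sensitivity sweep repeats best-model selection at consistency
thresholds from 40% to 100% in 1% steps (61 thresholds) and records the
selected (s0, s1, s2) and the signal variability SV — the mean projection
standard deviation across components and trial types — per threshold.
Group comparisons use two-sided Wilcoxon rank-sum / signed-rank tests with
Bonferroni correction over pairwise families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grids import TFGrid, FIFTH_TONE_ONSET_S
from .io import Dataset
from .paradigm import TRIAL_TYPES
from .tensorfit import ScalingGridSearch, select_best

__all__ = ["SignatureSummary", "VariabilityStats",
           "joint_topography", "region_contribution", "peak_latency",
           "mean_frequency", "component_brain_map", "st_mask", "project_trial",
           "project_dataset", "variability_stats", "sensitivity_sweep",
           "rank_sum", "signed_rank", "group_compare"]


# ---------------------------------------------------------------------------
# topography and spectro-temporal signatures
# ---------------------------------------------------------------------------

def normalize_map(spatial: np.ndarray) -> np.ndarray:
    """|coefficients| scaled to [0, 1] by the maximum."""
    m = np.abs(np.asarray(spatial, dtype=float))
    peak = m.max()
    if peak == 0:
        raise ValueError("all-zero spatial map cannot be normalized")
    return m / peak


def joint_topography(sig_ic_maps: np.ndarray) -> np.ndarray:
    """Average of per-IC normalized |spatial coefficients|, (n_electrodes,)."""
    maps = np.atleast_2d(np.asarray(sig_ic_maps, dtype=float))
    if maps.shape[0] < 1:
        raise ValueError("need at least one significant IC")
    return np.mean([normalize_map(m) for m in maps], axis=0)


def region_contribution(topo: np.ndarray, region_labels: np.ndarray,
                        regions=("pTC", "aTC", "aPFC")) -> dict[str, float]:
    """Fraction of the spatial distribution in each named region."""
    topo = np.asarray(topo, dtype=float)
    region_labels = np.asarray(region_labels)
    if len(topo) != len(region_labels):
        raise ValueError("topography and region labels must align per electrode")
    total = topo.sum()
    if total == 0:
        raise ValueError("zero total spatial distribution")
    return {r: float(topo[region_labels == r].sum() / total) for r in regions}


def peak_latency(tf_map: np.ndarray, grid: TFGrid,
                 onset_s: float = FIFTH_TONE_ONSET_S) -> float:
    """Peak latency (ms after fifth-tone onset) of the frequency-averaged |map|.

    Ties break toward the earlier time bin. A flat post-onset profile has
    no defined peak.
    """
    tf_map = np.asarray(tf_map, dtype=float)
    if tf_map.shape != grid.shape:
        raise ValueError(f"map shape {tf_map.shape} does not match grid {grid.shape}")
    profile = np.abs(tf_map).mean(axis=0)
    post = grid.post_onset_mask(onset_s)
    if not post.any():
        raise ValueError("no time bins after onset")
    seg = profile[post]
    if np.allclose(seg, seg[0]):
        raise ValueError("flat temporal profile; peak latency undefined")
    t_peak = grid.times[post][int(np.argmax(seg))]
    return float((t_peak - onset_s) * 1000.0)


def mean_frequency(tf_map: np.ndarray, grid: TFGrid) -> float:
    """Amplitude-weighted mean frequency of the time-averaged |map| (Hz)."""
    tf_map = np.asarray(tf_map, dtype=float)
    if tf_map.shape != grid.shape:
        raise ValueError(f"map shape {tf_map.shape} does not match grid {grid.shape}")
    profile = np.abs(tf_map).mean(axis=1)
    total = profile.sum()
    if total == 0:
        raise ValueError("zero spectral profile; mean frequency undefined")
    return float((profile * grid.freqs).sum() / total)


def contrast_minmax(masked_maps: np.ndarray) -> dict[str, tuple[float, float]]:
    """Min and max dB of the masked deviant responses per contrast.

    ``masked_maps`` is (2, n_ic, n_freqs, n_times).
    """
    m = np.asarray(masked_maps, dtype=float)
    out = {}
    for ci, name in enumerate(("xy|xx - xx|xx", "xy|xy - xx|xy")):
        out[name] = (float(m[ci].min()), float(m[ci].max()))
    return out


def component_brain_map(sig_ic_maps: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-component electrode maps: sum_i |B[i, k]| * normalized_map_i.

    Returns (n_components, n_electrodes).
    """
    maps = np.atleast_2d(np.asarray(sig_ic_maps, dtype=float))
    B = np.asarray(B, dtype=float)
    if B.shape[0] != maps.shape[0]:
        raise ValueError("IC loadings and spatial maps disagree on the IC count")
    norm = np.stack([normalize_map(m) for m in maps])
    return np.abs(B).T @ norm


@dataclass
class SignatureSummary:
    """Univariate signatures of a set of significant ICs."""

    joint_topography: np.ndarray
    region_fractions: dict[str, float]
    joint_tf: np.ndarray
    peak_latency_ms: float
    mean_frequency_hz: float
    contrast_minmax: dict[str, tuple[float, float]]


def signature_summary(sig_ic_maps: np.ndarray, region_labels: np.ndarray,
                      masked_maps: np.ndarray, grid: TFGrid) -> SignatureSummary:
    """Full univariate summary of significant ICs and their deviant responses.

    ``masked_maps`` is (2, n_sig, n_freqs, n_times); the joint TF map is
    the average |masked response| across significant ICs and contrasts.
    """
    topo = joint_topography(sig_ic_maps)
    joint_tf = np.abs(np.asarray(masked_maps, float)).mean(axis=(0, 1))
    return SignatureSummary(
        joint_topography=topo,
        region_fractions=region_contribution(topo, region_labels),
        joint_tf=joint_tf,
        peak_latency_ms=peak_latency(joint_tf, grid),
        mean_frequency_hz=mean_frequency(joint_tf, grid),
        contrast_minmax=contrast_minmax(masked_maps),
    )


# ---------------------------------------------------------------------------
# masks and single-trial projection
# ---------------------------------------------------------------------------

def st_mask(component_tf_maps: np.ndarray, grid: TFGrid,
            fmin: float = 40.0, keep_fraction: float = 0.75):
    """High-gamma spectro-temporal mask and weighted structure.

    ``component_tf_maps`` is a stack (n_datasets, n_freqs, n_times) of one
    component's maps (e.g. across subjects). Each map is normalized to
    [0, 1] by its own extrema, averaged, restricted to frequencies above
    ``fmin``, and thresholded to keep the top ``keep_fraction`` of bin
    values there. Returns (mask, structure): boolean mask and the averaged
    values inside the mask (0 outside).
    """
    maps = np.asarray(component_tf_maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.shape[-2:] != grid.shape:
        raise ValueError("maps do not match the grid")
    normed = []
    for m in np.abs(maps):
        peak = m.max()
        if peak == 0:
            raise ValueError("all-zero component map")
        normed.append(m / peak)
    avg = np.mean(normed, axis=0)
    hg = grid.freqs > fmin
    if not hg.any():
        raise ValueError(f"no frequency bins above {fmin} Hz")
    vals = avg[hg]
    mask = np.zeros(grid.shape, dtype=bool)
    if vals.max() > 0:  # no high-gamma energy at all -> empty mask
        thr = np.quantile(vals, 1.0 - keep_fraction)
        mask[hg] = (vals >= thr) & (vals > 0)
    structure = np.where(mask, avg, 0.0)
    return mask, structure


def project_trial(S: np.ndarray, ersp_trial: np.ndarray, FT: np.ndarray) -> float:
    """Scalar projection S * ERSP * FT = sum_i sum_f sum_t S_i ERSP[i,f,t] FT[f,t]."""
    S = np.asarray(S, dtype=float).ravel()
    E = np.asarray(ersp_trial, dtype=float)
    FT = np.asarray(FT, dtype=float)
    if E.ndim != 3 or E.shape[0] != len(S) or E.shape[1:] != FT.shape:
        raise ValueError(
            f"dimension mismatch: S {S.shape}, ERSP {E.shape}, FT {FT.shape}")
    return float(np.einsum("i,ift,ft->", S, E, FT))


def project_dataset(dataset: Dataset, sig_ics, S_per_component: np.ndarray,
                    structures: np.ndarray) -> pd.DataFrame:
    """Projection records for every trial and component.

    ``S_per_component`` is (n_components, n_sig) — typically |B|.T from the
    fit; ``structures`` is (n_components, n_freqs, n_times). Returns a
    DataFrame with columns (trial_index, trial_type, component, value).
    """
    sig_ics = list(sig_ics)
    S = np.asarray(S_per_component, dtype=float)
    FT = np.asarray(structures, dtype=float)
    if S.shape[0] != FT.shape[0]:
        raise ValueError("one S row and one structure per component required")
    sub = dataset.ersp[:, sig_ics]                       # (J, n_sig, F, T)
    vals = np.einsum("jift,kft,ki->jk", sub, FT, S, optimize=True)
    names = [f"PE{k + 1}" for k in range(S.shape[0])]
    rows = []
    for j in range(dataset.n_trials):
        for k, name in enumerate(names):
            rows.append({"trial_index": j, "trial_type": dataset.labels[j],
                         "component": name, "value": float(vals[j, k])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variability statistics
# ---------------------------------------------------------------------------

@dataclass
class VariabilityStats:
    """Mean/SD/CV summary of projection values.

    ``per_type`` indexes (component, trial type) -> (mean, sd). The
    cross-type aggregates average the per-type means and SDs per component;
    CV = averaged SD / averaged mean (NaN when the mean is 0). SV is the
    mean SD across components and trial types.
    """

    per_type: dict[tuple[str, str], tuple[float, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    cv: dict[str, float]
    sv: float


def variability_stats(records: pd.DataFrame) -> VariabilityStats:
    """Variability summary from projection records (trial_type, component, value)."""
    per_type: dict[tuple[str, str], tuple[float, float]] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    cv: dict[str, float] = {}
    present = [t for t in TRIAL_TYPES if (records["trial_type"] == t).any()]
    if not present:
        raise ValueError("no recognized trial types in the records")
    for comp, g in records.groupby("component"):
        ms, ss = [], []
        for t in present:
            vals = g.loc[g["trial_type"] == t, "value"].to_numpy()
            if len(vals) < 2:
                raise ValueError(f"need at least 2 trials of type {t!r} "
                                 f"for component {comp!r}")
            m, s = float(vals.mean()), float(vals.std(ddof=1))
            per_type[(comp, t)] = (m, s)
            ms.append(m)
            ss.append(s)
        mean[comp] = float(np.mean(ms))
        sd[comp] = float(np.mean(ss))
        cv[comp] = sd[comp] / mean[comp] if mean[comp] != 0 else float("nan")
    sv = float(np.mean([s for _, s in per_type.values()]))
    return VariabilityStats(per_type=per_type, mean=mean, sd=sd, cv=cv, sv=sv)


# ---------------------------------------------------------------------------
# sensitivity sweep
# ---------------------------------------------------------------------------

def sensitivity_sweep(grid: ScalingGridSearch, dataset: Dataset, sig_ics,
                      structures_fn, thresholds: np.ndarray | None = None
                      ) -> pd.DataFrame:
    """Optimal parameters and SV per consistency threshold.

    ``structures_fn(fit_result) -> (S_per_component, structures)`` maps a
    selected model to the projection inputs (this keeps the mask convention
    a caller choice). Default thresholds: 40-100% in 1% steps (61 rows).
    Thresholds with no qualifying model yield NaN rows. Projections are
    cached per selected grid cell, since neighboring thresholds typically
    select the same model.
    """
    if thresholds is None:
        thresholds = np.arange(40.0, 101.0, 1.0)
    cache: dict[int, float] = {}
    rows = []
    for thr in thresholds:
        best = select_best(grid, threshold=float(thr), refit_tensor=grid.tensor_)
        if best is None:
            rows.append({"threshold": float(thr), "s0": np.nan, "s1": np.nan,
                         "s2": np.nan, "sv": np.nan, "found": False})
            continue
        idx, params, result = best
        if idx not in cache:
            S, FT = structures_fn(result)
            recs = project_dataset(dataset, sig_ics, S, FT)
            cache[idx] = variability_stats(recs).sv
        rows.append({"threshold": float(thr), "s0": params.s0, "s1": params.s1,
                     "s2": params.s2, "sv": cache[idx], "found": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value; exact when small.

    Ties are handled by midranks; all-equal pooled input gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(a, b, zero_method="wilcox",
                              alternative="two-sided").pvalue)


def group_compare(groups: dict[str, np.ndarray], paired: bool = False,
                  alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise two-sided rank tests with Bonferroni correction.

    Returns a DataFrame (group_a, group_b, p_raw, p_bonferroni, significant);
    the Bonferroni factor is the number of pairs in the family.
    """
    names = list(groups)
    pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1:]]
    n_pairs = len(pairs)
    rows = []
    for x, y in pairs:
        p = signed_rank(groups[x], groups[y]) if paired else rank_sum(groups[x], groups[y])
        pb = min(p * n_pairs, 1.0)
        rows.append({"group_a": x, "group_b": y, "p_raw": p,
                     "p_bonferroni": pb, "significant": pb <= alpha})
    return pd.DataFrame(rows)
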