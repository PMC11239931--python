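"""Fixed-mode PARAFAC of the deviant-response tensor and the scaling grid search.

The masked deviant responses of all significant ICs are stacked into a
3-way tensor X with dimensions Contrast (2) x IC (n_sig) x Time-Frequency
(frequency-major flattening). X is decomposed into two rank-1 components
(PE1 and PE2)::

    X[i, j, k] ~ sum_r A[i, r] * B[j, r] * C[k, r]

with the *Contrast* factor matrix A fixed to the model-derived 2x2 contrast
design (:func:`lgpc.model.contrast_design`) and only the IC loadings B and
the spectro-temporal loadings C estimated by alternating least squares
(no constraints, convergence when the relative change in fit drops below
``tol``). With A frozen, each component carries one multiplicative
degeneracy between B and C; the convention here normalizes C columns to
unit norm and absorbs the magnitude into B (RSS is invariant to this).

Goodness of fit is measured by the residual sum of squares (RSS) and the
core consistency diagnostic — 100 * (1 - ||G - T||^2 / ||T||^2), where G is
the least-squares Tucker core given the CP loadings (the fixed A included
as an ordinary factor) and T the superdiagonal identity core. Values near
100 indicate appropriate trilinear structure; 80-90 a robust decomposition;
below ~40 a questionable one.

The grid search fits one model per scaling-factor combination — by default
21 x 21 x 21 = 9261 cells over s0 in [0, 1], s1 and s2 in [0, 2] — and the
best model is the minimum-RSS cell among those whose core consistency
exceeds a threshold (default 80%). Cells whose contrast matrix is singular
(e.g. s2 = 0 collapses the two columns) are recorded as invalid rather
than fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grids import TFGrid
from .model import (ContrastDesign, ScalingParams, RegularityStats,
                    DEFAULT_STATS_XX, DEFAULT_STATS_XY, contrast_design_batch)

__all__ = ["DeviantTensor", "FitResult", "FixedModeCP", "ScalingGridSearch",
           "parafac_fixed", "core_consistency", "grid_search", "select_best",
           "default_grid_axes", "tensor_from_maps"]


@dataclass
class DeviantTensor:
    """The Contrast x IC x Time-Frequency tensor of significant deviant responses."""

    values: np.ndarray          # (2, n_sig, n_tf), dB differences
    grid: TFGrid
    ic_indices: tuple[int, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 2:
            raise ValueError("tensor must be (2, n_ic, n_tf)")
        if self.values.shape[2] != self.grid.n_tf:
            raise ValueError(
                f"TF dimension {self.values.shape[2]} does not match grid "
                f"({self.grid.n_tf} = {self.grid.n_freqs} x {self.grid.n_times}, "
                f"{self.grid.flatten_order})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor must be finite")
        self.metadata.setdefault("tf_flatten_order", self.grid.flatten_order)

    @property
    def n_ics(self) -> int:
        return self.values.shape[1]


def tensor_from_maps(maps: np.ndarray, grid: TFGrid,
                     ic_indices=(), metadata=None) -> DeviantTensor:
    """Stack per-IC (2, n_freqs, n_times) contrast maps into a DeviantTensor.

    ``maps`` is (2, n_ic, n_freqs, n_times); the TF axes are flattened
    frequency-major.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4 or maps.shape[0] != 2:
        raise ValueError("maps must be (2, n_ic, n_freqs, n_times)")
    return DeviantTensor(values=grid.flatten_tf(maps), grid=grid,
                         ic_indices=tuple(ic_indices), metadata=metadata or {})


# ---------------------------------------------------------------------------
# batched fixed-mode rank-2 ALS
# ---------------------------------------------------------------------------

def _inv2x2(M: np.ndarray, eps: float = 1e-12):
    """Batched 2x2 inverse; returns (inverse, valid mask)."""
    a, b = M[..., 0, 0], M[..., 0, 1]
    c, d = M[..., 1, 0], M[..., 1, 1]
    det = a * d - b * c
    scale = np.maximum(np.abs(M).max(axis=(-2, -1)) ** 2, eps)
    valid = np.abs(det) > eps * scale
    safe = np.where(valid, det, 1.0)
    inv = np.empty_like(M)
    inv[..., 0, 0] = d / safe
    inv[..., 0, 1] = -b / safe
    inv[..., 1, 0] = -c / safe
    inv[..., 1, 1] = a / safe
    return inv, valid


def _init_deterministic(X: np.ndarray, A: np.ndarray):
    """Direct start: project X onto pinv(A) along the contrast mode, then take
    the dominant rank-1 structure of each component slab."""
    Ap = np.linalg.pinv(A)                               # (G, 2, 2)
    Y = np.einsum("gri,ijk->grjk", Ap, X, optimize=True)  # (G, 2, n, m)
    G_, R, n, m = Y.shape
    # dominant left vector of each (n, m) slab via the small n x n Gram matrix
    S = Y @ np.swapaxes(Y, -1, -2)                       # (G, 2, n, n)
    w, V = np.linalg.eigh(S)
    b = V[..., -1]                                       # (G, 2, n)
    c = np.einsum("grn,grnm->grm", b, Y, optimize=True)  # (G, 2, m)
    B = np.swapaxes(b, -1, -2).copy()                    # (G, n, 2)
    C = np.swapaxes(c, -1, -2).copy()                    # (G, m, 2)
    return B, C


def _als_fixed(X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray,
               tol: float, max_iter: int):
    """Alternating least squares updating only B and C, A fixed per batch cell.

    X: (2, n, m); A: (G, 2, 2); B: (G, n, 2); C: (G, m, 2).
    Returns (B, C, rss, n_iter, converged) with per-cell arrays.
    """
    G = A.shape[0]
    normX2 = float((X ** 2).sum())
    AtA = np.einsum("gir,gis->grs", A, A, optimize=True)

    rss = np.full(G, np.inf)
    n_iter = np.zeros(G, dtype=int)
    converged = np.zeros(G, dtype=bool)
    active = np.arange(G)

    Xf = X  # (2, n, m)
    for it in range(1, max_iter + 1):
        Aa, Ba, Ca = A[active], B[active], C[active]
        AtAa = AtA[active]
        # update B
        CtC = np.einsum("gmr,gms->grs", Ca, Ca, optimize=True)
        T1 = np.einsum("ijm,gmr->gijr", Xf, Ca, optimize=True)   # (g, 2, n, 2)
        M = np.einsum("gijr,gir->gjr", T1, Aa, optimize=True)    # (g, n, 2)
        inv, ok_b = _inv2x2(AtAa * CtC)
        Ba = np.einsum("gjr,grs->gjs", M, inv, optimize=True)
        # update C
        BtB = np.einsum("gjr,gjs->grs", Ba, Ba, optimize=True)
        D = np.einsum("gir,gjr->gijr", Aa, Ba, optimize=True)
        N = np.einsum("ijm,gijr->gmr", Xf, D, optimize=True)     # (g, m, 2)
        inv, ok_c = _inv2x2(AtAa * BtB)
        Ca = np.einsum("gmr,grs->gms", N, inv, optimize=True)
        # RSS via <X, model> computed with the fresh C
        CtC = np.einsum("gmr,gms->grs", Ca, Ca, optimize=True)
        cross = np.einsum("gmr,gmr->g", N, Ca, optimize=True)
        model2 = (AtAa * BtB * CtC).sum(axis=(-2, -1))
        new_rss = np.maximum(normX2 - 2.0 * cross + model2, 0.0)

        B[active], C[active] = Ba, Ca
        prev = rss[active]
        rss[active] = new_rss
        n_iter[active] = it
        rel = np.abs(prev - new_rss) / np.maximum(normX2, 1e-300)
        done = (rel < tol) & np.isfinite(prev)
        bad = ~(ok_b & ok_c)
        converged[active] = converged[active] | done
        still = ~(done | bad)
        active = active[still]
        if active.size == 0:
            break
    return B, C, rss, n_iter, converged


def _fit_batch(X: np.ndarray, A: np.ndarray, tol: float, max_iter: int,
               seed: int = 0, n_random_starts: int = 1):
    """Run the deterministic start plus seeded random starts; keep the best RSS."""
    G = A.shape[0]
    _, n, m = X.shape
    B0, C0 = _init_deterministic(X, A)
    B, C, rss, n_iter, conv = _als_fixed(X, A, B0, C0, tol, max_iter)
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        Br = rng.standard_normal((G, n, 2))
        Cr = rng.standard_normal((G, m, 2))
        B2, C2, rss2, it2, conv2 = _als_fixed(X, A, Br, Cr, tol, max_iter)
        better = rss2 < rss
        B[better], C[better] = B2[better], C2[better]
        n_iter[better], conv[better] = it2[better], conv2[better]
        rss[better] = rss2[better]
    # fix the scale indeterminacy: unit-norm C columns, magnitude into B
    cn = np.linalg.norm(C, axis=1, keepdims=True)        # (G, 1, 2)
    nz = cn[:, 0, :] > 0
    C = np.divide(C, cn, out=C, where=cn > 0)
    B = B * np.where(nz, cn[:, 0, :], 1.0)[:, None, :]
    return B, C, rss, n_iter, conv


def _core_consistency_batch(X: np.ndarray, A: np.ndarray, B: np.ndarray,
                            C: np.ndarray) -> np.ndarray:
    """Core consistency (percent) per batch cell; NaN where loadings degenerate."""
    G = A.shape[0]
    out = np.full(G, np.nan)
    with np.errstate(all="ignore"):
        try:
            Ap = np.linalg.pinv(A)
            Bp = np.linalg.pinv(B)
            Cp = np.linalg.pinv(C)
        except np.linalg.LinAlgError:
            return out
    T = np.einsum("ijm,grm->gijr", X, Cp, optimize=True)     # (G, 2, n, 2)
    U = np.einsum("gijr,gqj->giqr", T, Bp, optimize=True)    # (G, 2, 2, 2)
    core = np.einsum("giqr,gpi->gpqr", U, Ap, optimize=True)  # (G, 2, 2, 2)
    ident = np.zeros((2, 2, 2))
    ident[0, 0, 0] = ident[1, 1, 1] = 1.0
    dev = ((core - ident) ** 2).sum(axis=(1, 2, 3))
    cc = 100.0 * (1.0 - dev / 2.0)
    # degenerate loadings (zero columns) make the pseudo-inverse meaningless
    okB = np.all(np.linalg.norm(B, axis=1) > 1e-12, axis=-1)
    okC = np.all(np.linalg.norm(C, axis=1) > 1e-12, axis=-1)
    ok = okB & okC & np.isfinite(cc)
    out[ok] = cc[ok]
    return out


# ---------------------------------------------------------------------------
# single fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Loadings and diagnostics of one fixed-mode PARAFAC fit."""

    A_fixed: np.ndarray         # (2, 2)
    B: np.ndarray               # (n_sig, 2) IC loadings
    C: np.ndarray               # (n_tf, 2) TF loadings, unit-norm columns
    rss: float
    core_consistency: float     # percent, NaN if undefined
    converged: bool
    n_iter: int

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("A_fixed", data=self.A_fixed)
            f.create_dataset("B", data=self.B)
            f.create_dataset("C", data=self.C)
            f.attrs.update({"rss": self.rss, "core_consistency": self.core_consistency,
                            "converged": self.converged, "n_iter": self.n_iter})


class FixedModeCP(BaseEstimator):
    """Rank-2 CP decomposition with a frozen first (Contrast) factor matrix.

    Parameters
    ----------
    A : (2, 2) array or ContrastDesign — the fixed Contrast-mode loadings.
    tol : relative-fit convergence criterion of the ALS (default 1e-6).
    max_iter : iteration cap per start.
    n_random_starts : seeded random starts run in addition to the
        deterministic start; the best-RSS solution is kept.
    random_state : seed for the random starts.

    Fitted attributes: ``B_``, ``C_`` (unit-norm columns), ``rss_``,
    ``core_consistency_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, A=None, tol: float = 1e-6, max_iter: int = 500,
                 n_random_starts: int = 1, random_state: int = 0):
        self.A = A
        self.tol = tol
        self.max_iter = max_iter
        self.n_random_starts = n_random_starts
        self.random_state = random_state

    def _A(self) -> np.ndarray:
        A = self.A.A if isinstance(self.A, ContrastDesign) else np.asarray(self.A, float)
        if A.shape != (2, 2):
            raise ValueError("A must be a 2x2 matrix")
        return A

    def fit(self, X, y=None):
        X = self._validate_tensor(X)
        A = self._A()
        if np.linalg.matrix_rank(A, tol=1e-10 * max(np.abs(A).max(), 1e-30)) < 2:
            raise ValueError("fixed Contrast matrix is rank-deficient; "
                             "the two components are not distinguishable")
        if not X.any():
            self.B_ = np.zeros((X.shape[1], 2))
            self.C_ = np.zeros((X.shape[2], 2))
            self.rss_, self.core_consistency_ = 0.0, float("nan")
            self.converged_, self.n_iter_ = True, 0
            return self
        B, C, rss, n_iter, conv = _fit_batch(
            X, A[None], self.tol, self.max_iter, seed=self.random_state,
            n_random_starts=self.n_random_starts)
        cc = _core_consistency_batch(X, A[None], B, C)
        self.B_, self.C_ = B[0], C[0]
        self.rss_ = float(rss[0])
        self.core_consistency_ = float(cc[0])
        self.converged_ = bool(conv[0])
        self.n_iter_ = int(n_iter[0])
        return self

    @staticmethod
    def _validate_tensor(X) -> np.ndarray:
        X = X.values if isinstance(X, DeviantTensor) else np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] != 2:
            raise ValueError("expected a (2, n_ic, n_tf) tensor")
        if not np.all(np.isfinite(X)):
            raise ValueError("tensor must be finite")
        return X

    def reconstruct(self) -> np.ndarray:
        """Model tensor from the fitted loadings."""
        return np.einsum("ir,jr,kr->ijk", self._A(), self.B_, self.C_)

    def result(self) -> FitResult:
        return FitResult(A_fixed=self._A(), B=self.B_, C=self.C_, rss=self.rss_,
                         core_consistency=self.core_consistency_,
                         converged=self.converged_, n_iter=self.n_iter_)


def parafac_fixed(tensor, A, tol: float = 1e-6, max_iter: int = 500,
                  random_state: int = 0) -> FitResult:
    """Functional wrapper over :class:`FixedModeCP`."""
    est = FixedModeCP(A=A, tol=tol, max_iter=max_iter, random_state=random_state)
    est.fit(tensor)
    return est.result()


def core_consistency(fit: FitResult, tensor) -> float:
    """Core consistency (percent) of a fit against a tensor."""
    X = FixedModeCP._validate_tensor(tensor)
    return float(_core_consistency_batch(X, fit.A_fixed[None], fit.B[None],
                                         fit.C[None])[0])


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def default_grid_axes(n_s0: int = 21, n_s1: int = 21, n_s2: int = 21):
    """Uniform scaling-factor grids: s0 on [0, 1], s1 and s2 on [0, 2]."""
    return (np.linspace(0.0, 1.0, n_s0),
            np.linspace(0.0, 2.0, n_s1),
            np.linspace(0.0, 2.0, n_s2))


class ScalingGridSearch(BaseEstimator):
    """Exhaustive fixed-mode PARAFAC fit over the scaling-factor grid.

    For every (s0, s1, s2) combination the model contrast matrix is built
    and a fixed-mode rank-2 CP fit of the deviant tensor is run; RSS and
    core consistency are recorded per cell. The default axes give
    21 x 21 x 21 = 9261 models. The best model is the minimum-RSS cell
    among those with consistency above ``threshold`` percent.

    Fitted attributes: ``s0_values_``, ``s1_values_``, ``s2_values_``,
    ``rss_``, ``consistency_`` (flat, C-ordered over the s0 x s1 x s2 grid),
    ``valid_``, ``table_`` (DataFrame), ``best_index_``, ``best_params_``
    (None when no cell qualifies), ``best_result_``.
    """

    def __init__(self, s0_values=None, s1_values=None, s2_values=None,
                 threshold: float = 80.0, tol: float = 1e-6, max_iter: int = 500,
                 n_random_starts: int = 1, random_state: int = 0,
                 stats_xx: RegularityStats = DEFAULT_STATS_XX,
                 stats_xy: RegularityStats = DEFAULT_STATS_XY,
                 batch_size: int = 2048):
        self.s0_values = s0_values
        self.s1_values = s1_values
        self.s2_values = s2_values
        self.threshold = threshold
        self.tol = tol
        self.max_iter = max_iter
        self.n_random_starts = n_random_starts
        self.random_state = random_state
        self.stats_xx = stats_xx
        self.stats_xy = stats_xy
        self.batch_size = batch_size

    def _axes(self):
        d0, d1, d2 = default_grid_axes()
        s0 = d0 if self.s0_values is None else np.asarray(self.s0_values, float)
        s1 = d1 if self.s1_values is None else np.asarray(self.s1_values, float)
        s2 = d2 if self.s2_values is None else np.asarray(self.s2_values, float)
        return s0, s1, s2

    def fit(self, X, y=None):
        X = FixedModeCP._validate_tensor(X)
        s0, s1, s2 = self._axes()
        S0, S1, S2 = np.meshgrid(s0, s1, s2, indexing="ij")
        cells = np.stack([S0.ravel(), S1.ravel(), S2.ravel()], axis=1)  # (G, 3)
        G = len(cells)
        A_all = contrast_design_batch(cells[:, 0], cells[:, 1], cells[:, 2],
                                      self.stats_xx, self.stats_xy)      # (G, 2, 2)
        # singular contrast matrices cannot separate PE1 from PE2
        sv = np.linalg.svd(A_all, compute_uv=False)
        valid = sv[:, -1] > 1e-10 * np.maximum(sv[:, 0], 1e-30)

        rss = np.full(G, np.inf)
        cc = np.full(G, np.nan)
        idx = np.nonzero(valid)[0]
        # cap the batch so per-batch work arrays stay modest for large TF modes
        m = X.shape[2]
        batch = max(1, min(self.batch_size, int(2.5e8 / (8 * 2 * max(m, 1)))))
        for start in range(0, len(idx), batch):
            sel = idx[start:start + batch]
            B, C, r, _, _ = _fit_batch(X, A_all[sel], self.tol, self.max_iter,
                                       seed=self.random_state,
                                       n_random_starts=self.n_random_starts)
            rss[sel] = r
            cc[sel] = _core_consistency_batch(X, A_all[sel], B, C)

        self.s0_values_, self.s1_values_, self.s2_values_ = s0, s1, s2
        self.tensor_ = X
        self.cells_ = cells
        self.rss_ = rss
        self.consistency_ = cc
        self.valid_ = valid
        self.table_ = pd.DataFrame({
            "s0": cells[:, 0], "s1": cells[:, 1], "s2": cells[:, 2],
            "rss": rss, "consistency": cc, "valid": valid,
        })
        self._select(X)
        return self

    def _select(self, X):
        best = select_best(self, threshold=self.threshold, refit_tensor=X)
        if best is None:
            self.best_index_ = None
            self.best_params_ = None
            self.best_result_ = None
        else:
            self.best_index_, self.best_params_, self.best_result_ = best

    @property
    def n_models_(self) -> int:
        return len(self.cells_)


def grid_search(tensor, s0_values=None, s1_values=None, s2_values=None,
                threshold: float = 80.0, **kwargs) -> ScalingGridSearch:
    """Functional wrapper over :class:`ScalingGridSearch`."""
    est = ScalingGridSearch(s0_values=s0_values, s1_values=s1_values,
                            s2_values=s2_values, threshold=threshold, **kwargs)
    return est.fit(tensor)


def select_best(grid: ScalingGridSearch, threshold: float = 80.0,
                refit_tensor=None):
    """Best model at a consistency threshold.

    Among cells with core consistency strictly above ``threshold``, return
    (flat index, ScalingParams, FitResult) of the minimum-RSS cell;
    ``None`` (an explicit empty result) when no cell qualifies.
    """
    ok = grid.valid_ & np.isfinite(grid.rss_) & (grid.consistency_ > threshold)
    if not ok.any():
        return None
    cand = np.nonzero(ok)[0]
    best = cand[np.argmin(grid.rss_[cand])]
    s0, s1, s2 = grid.cells_[best]
    params = ScalingParams(s0=float(s0), s1=float(s1), s2=float(s2))
    result = None
    if refit_tensor is not None:
        A = contrast_design_batch(s0, s1, s2, grid.stats_xx, grid.stats_xy)
        result = parafac_fixed(refit_tensor, A, tol=grid.tol,
                               max_iter=grid.max_iter,
                               random_state=grid.random_state)
    return int(best), params, result


def save_grid_csv(grid: ScalingGridSearch, path: str | Path) -> None:
    grid.table_.to_csv(path, index=False)


def save_best_json(grid: ScalingGridSearch, path: str | Path) -> None:
    if grid.best_params_ is None:
        payload = {"found": False, "threshold": grid.threshold}
    else:
        payload = {"found": True, "threshold": grid.threshold,
                   "params": list(grid.best_params_.as_tuple()),
                   "rss": float(grid.rss_[grid.best_index_]),
                   "consistency": float(grid.consistency_[grid.best_index_])}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
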