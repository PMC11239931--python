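"""Hierarchical predictive-coding model of the local-global paradigm.

The model describes steady-state signaling during the *last* tone of a
sequence, after both temporal regularities have been learned. It has three
levels and two streams (one per tone identity):

* **Level S** receives the sensory input. The input to the x stream (the
  tone repeated four times) is scaled by ``s0`` in [0, 1] to express sensory
  adaptation; the y stream receives a fresh, unadapted input of 1 when tone
  y occurs.
* **Level 1** encodes the local regularity — the tone-to-tone transition
  probability ``q`` — and sends predictions ``P1_x``, ``P1_y`` to Level S,
  scaled by ``s1``. The residuals are the level-1 prediction errors
  ``PE1_x``, ``PE1_y``.
* **Level 2** encodes the global regularity — the sequence probability —
  and predicts the level-1 error signal it expects given the block's
  standard/deviant sequence mix, scaled by ``s2``. The residuals are the
  level-2 errors ``PE2_x``, ``PE2_y``.

``s1 = s2 = 1`` are the MSE-optimal (conditional-expectation) predictions;
values below 1 are hypo-prediction, above 1 hyper-prediction. Prediction
errors propagate *signed* between levels; the observable component
magnitudes are PE1 = |PE1_x| + |PE1_y| and PE2 = |PE2_x| + |PE2_y|, since
spectral-power contrasts are magnitudes.

These formulas are deliberately isolated in this module (see
:func:`trial_state`) so that an alternative formulation can be swapped in
at a single point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import TRIAL_TYPES, RegularityStats

__all__ = [
    "ScalingParams",
    "StreamState",
    "PEValues",
    "ContrastDesign",
    "trial_state",
    "pe_values",
    "contrast_design",
    "DEFAULT_STATS_XX",
    "DEFAULT_STATS_XY",
]

#: Default block statistics for the standard design (q from the four
#: within-trial transitions of the 64/16 mixture; d fixed at the design
#: value 0.2 in both contexts).
DEFAULT_STATS_XX = RegularityStats(q_local=0.05, d_global=0.2)
DEFAULT_STATS_XY = RegularityStats(q_local=0.20, d_global=0.2)


@dataclass(frozen=True)
class ScalingParams:
    """Model scaling factors (s0, s1, s2).

    s0 in [0, 1]: sensory gain of the repeated tone (1 = no adaptation).
    s1, s2 in [0, 2]: strength of the level-1 / level-2 predictions
    (1 = optimal; <1 hypo-, >1 hyper-prediction).
    """

    s0: float = 1.0
    s1: float = 1.0
    s2: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.s0 <= 1.0):
            raise ValueError(f"s0 must be in [0, 1], got {self.s0}")
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 2.0):
                raise ValueError(f"{name} must be in [0, 2], got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s0, self.s1, self.s2)


@dataclass(frozen=True)
class StreamState:
    """Per-stream signals during the fifth tone of one trial type."""

    I_x: float
    I_y: float
    P1_x: float
    P1_y: float
    P2_x: float
    P2_y: float
    e1_x: float
    e1_y: float
    e2_x: float
    e2_y: float


@dataclass(frozen=True)
class PEValues:
    """Observable prediction-error magnitudes for one trial type."""

    PE1: float
    PE2: float

    def __post_init__(self):
        if self.PE1 < 0 or self.PE2 < 0:
            raise ValueError("PE magnitudes must be nonnegative")


def _level1_errors(params: ScalingParams, q: float, fifth_is_deviant_tone: bool,
                   adapt_before_predict: bool = True) -> tuple[float, float]:
    """Signed level-1 errors (e1_x, e1_y) for a sequence ending in x or y.

    ``fifth_is_deviant_tone`` is True when the fifth tone is y (differs from
    the first four). With ``adapt_before_predict`` (default) the level-1
    prediction of the x stream targets the *adapted* input (1-q)*s0;
    otherwise it targets the raw expectation (1-q).
    """
    I_x = 0.0 if fifth_is_deviant_tone else params.s0
    I_y = 1.0 if fifth_is_deviant_tone else 0.0
    x_target = (1.0 - q) * (params.s0 if adapt_before_predict else 1.0)
    P1_x = params.s1 * x_target
    P1_y = params.s1 * q
    return I_x - P1_x, I_y - P1_y


def trial_state(params: ScalingParams, stats: RegularityStats, trial_type: str,
                adapt_before_predict: bool = True) -> StreamState:
    """Full stream state for ``trial_type`` given its block's statistics.

    The level-2 prediction targets the level-1 error signal expected under
    the block's sequence mix: P2_s = s2 * [(1-d) e1_s(standard sequence)
    + d e1_s(deviant sequence)], where d is the deviant-sequence
    probability.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}; expected one of {TRIAL_TYPES}")
    seq, block = trial_type.split("|")
    q, d = stats.q_local, stats.d_global

    # fifth tone is y iff the sequence is xy
    fifth_dev = seq == "xy"
    e1_x, e1_y = _level1_errors(params, q, fifth_dev, adapt_before_predict)

    # block's standard / deviant sequences: xx block -> standard xx, deviant xy
    std_dev_tone = block == "xy"  # standard sequence ends in y in an xy block
    e1_std = _level1_errors(params, q, std_dev_tone, adapt_before_predict)
    e1_dev = _level1_errors(params, q, not std_dev_tone, adapt_before_predict)

    P2_x = params.s2 * ((1.0 - d) * e1_std[0] + d * e1_dev[0])
    P2_y = params.s2 * ((1.0 - d) * e1_std[1] + d * e1_dev[1])

    I_x = 0.0 if fifth_dev else params.s0
    I_y = 1.0 if fifth_dev else 0.0
    x_target = (1.0 - q) * (params.s0 if adapt_before_predict else 1.0)
    return StreamState(
        I_x=I_x, I_y=I_y,
        P1_x=params.s1 * x_target, P1_y=params.s1 * q,
        P2_x=P2_x, P2_y=P2_y,
        e1_x=e1_x, e1_y=e1_y,
        e2_x=e1_x - P2_x, e2_y=e1_y - P2_y,
    )


def pe_values(state: StreamState) -> PEValues:
    """Observable magnitudes: PE1 = |e1_x| + |e1_y|, PE2 = |e2_x| + |e2_y|."""
    return PEValues(
        PE1=abs(state.e1_x) + abs(state.e1_y),
        PE2=abs(state.e2_x) + abs(state.e2_y),
    )


def trial_pe(params: ScalingParams, stats: RegularityStats, trial_type: str,
             adapt_before_predict: bool = True) -> PEValues:
    """PE magnitudes for one trial type (``trial_state`` then ``pe_values``)."""
    return pe_values(trial_state(params, stats, trial_type, adapt_before_predict))


@dataclass(frozen=True)
class ContrastDesign:
    """Model-derived 2x2 contrast matrix.

    Rows are the two ERSP contrasts (c1 = xy|xx - xx|xx, c2 = xy|xy - xx|xy);
    columns are the (PE1, PE2) component contributions. This matrix fixes
    the Contrast mode of the PARAFAC decomposition.
    """

    A: np.ndarray  # (2, 2) rows: contrasts, cols: (PE1, PE2)

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.shape != (2, 2):
            raise ValueError(f"contrast matrix must be 2x2, got {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("contrast matrix must be finite")
        object.__setattr__(self, "A", A)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"A": self.A.tolist(),
                       "rows": ["xy|xx - xx|xx", "xy|xy - xx|xy"],
                       "cols": ["PE1", "PE2"]}, fh, indent=2)


def contrast_design(params: ScalingParams,
                    stats_xx: RegularityStats = DEFAULT_STATS_XX,
                    stats_xy: RegularityStats = DEFAULT_STATS_XY,
                    adapt_before_predict: bool = True) -> ContrastDesign:
    """Model contrast matrix from the two block contexts' statistics."""
    pe = {
        t: trial_pe(params, stats_xx if t.endswith("|xx") else stats_xy, t,
                    adapt_before_predict)
        for t in TRIAL_TYPES
    }
    A = np.array([
        [pe["xy|xx"].PE1 - pe["xx|xx"].PE1, pe["xy|xx"].PE2 - pe["xx|xx"].PE2],
        [pe["xy|xy"].PE1 - pe["xx|xy"].PE1, pe["xy|xy"].PE2 - pe["xx|xy"].PE2],
    ])
    return ContrastDesign(A=A)


def pe_table(params: ScalingParams,
             stats_xx: RegularityStats = DEFAULT_STATS_XX,
             stats_xy: RegularityStats = DEFAULT_STATS_XY) -> pd.DataFrame:
    """Per-trial-type PE magnitudes as a DataFrame (CSV-ready)."""
    rows = []
    for t in TRIAL_TYPES:
        v = trial_pe(params, stats_xx if t.endswith("|xx") else stats_xy, t)
        rows.append({"trial_type": t, "PE1": v.PE1, "PE2": v.PE2})
    return pd.DataFrame(rows)


def params_to_json(params: ScalingParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2)


def contrast_design_batch(s0: np.ndarray, s1: np.ndarray, s2: np.ndarray,
                          stats_xx: RegularityStats = DEFAULT_STATS_XX,
                          stats_xy: RegularityStats = DEFAULT_STATS_XY) -> np.ndarray:
    """Vectorized contrast matrices for arrays of scaling factors.

    Broadcast-compatible ``s0, s1, s2`` map to an output of shape
    ``broadcast_shape + (2, 2)``. Identical to :func:`contrast_design`
    evaluated elementwise (adaptation-precedes-prediction convention); kept
    in sync by a dedicated equivalence test.
    """
    s0, s1, s2 = np.broadcast_arrays(np.asarray(s0, float), np.asarray(s1, float),
                                     np.asarray(s2, float))
    out = np.empty(s0.shape + (2, 2))
    for row, (q, d, block_std_is_dev_tone) in enumerate(
            [(stats_xx.q_local, stats_xx.d_global, False),
             (stats_xy.q_local, stats_xy.d_global, True)]):
        # signed level-1 errors for sequences ending in x / y
        e1x_x5 = s0 - s1 * (1 - q) * s0          # fifth tone x
        e1y_x5 = -s1 * q
        e1x_y5 = -s1 * (1 - q) * s0              # fifth tone y
        e1y_y5 = 1.0 - s1 * q
        if block_std_is_dev_tone:   # xy block: standard sequence ends in y
            P2x = s2 * ((1 - d) * e1x_y5 + d * e1x_x5)
            P2y = s2 * ((1 - d) * e1y_y5 + d * e1y_x5)
        else:                       # xx block
            P2x = s2 * ((1 - d) * e1x_x5 + d * e1x_y5)
            P2y = s2 * ((1 - d) * e1y_x5 + d * e1y_y5)
        pe1_dev = np.abs(e1x_y5) + np.abs(e1y_y5)    # xy sequence
        pe1_std = np.abs(e1x_x5) + np.abs(e1y_x5)    # xx sequence
        pe2_dev = np.abs(e1x_y5 - P2x) + np.abs(e1y_y5 - P2y)
        pe2_std = np.abs(e1x_x5 - P2x) + np.abs(e1y_x5 - P2y)
        out[..., row, 0] = pe1_dev - pe1_std
        out[..., row, 1] = pe2_dev - pe2_std
    return out
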