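"""Local-global auditory oddball paradigm: block generation and regularity statistics.

The paradigm delivers 5-tone sequences in blocks. Within a trial, the first four
tones are identical (the standard tone ``x``); the fifth either repeats it
(an ``xx`` sequence) or deviates (``xy``). A block habituates the subject to one
sequence type (the *global standard*) and then delivers a random mixture in
which the other type is rare. Crossing the within-trial (local) and
across-trial (global) regularities yields four trial types::

    xx|xx  local standard, global standard   (xx sequence in an xx block)
    xy|xx  local deviant,  global deviant    (xy sequence in an xx block)
    xy|xy  local deviant,  global standard   (xy sequence in an xy block)
    xx|xy  local standard, global deviant    (xx sequence in an xy block)

Two regularity statistics summarize a block and feed the predictive-coding
model (:mod:`lgpc.model`):

* the local transition probability ``q`` — the probability of an x->y
  transition, counted over all four within-sequence tone transitions, and
* the global deviant probability ``d`` — the probability that a whole
  sequence is the block's rare (deviant) sequence.

For the default design (64 standard + 16 deviant mixture trials) these are
q = 0.05 in an xx block, q = 0.20 in an xy block, and d = 0.2 in both.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TRIAL_TYPES",
    "ToneSequence",
    "BlockDesign",
    "RegularityStats",
    "generate_block",
    "estimate_local_regularity",
    "estimate_global_regularity",
    "block_to_csv",
    "design_to_json",
    "design_from_json",
]

#: Canonical trial-type labels, "sequence|block".
TRIAL_TYPES = ("xx|xx", "xy|xx", "xy|xy", "xx|xy")

_BLOCK_CONTEXTS = ("XX", "XY")


def trial_label(fifth_is_deviant: bool, block_context: str) -> str:
    """Trial label as a pure function of (5th tone identity, block context)."""
    if block_context not in _BLOCK_CONTEXTS:
        raise ValueError(f"unknown block context {block_context!r}")
    seq = "xy" if fifth_is_deviant else "xx"
    return f"{seq}|{block_context.lower()}"


@dataclass(frozen=True)
class ToneSequence:
    """A single 5-tone trial.

    ``tones`` are the physical tone identities (symbols ``A``/``B``); the
    first four must be identical. ``label`` is the trial type and must be
    consistent with the fifth tone and the block context.
    """

    tones: tuple[str, ...]
    label: str
    block_context: str
    onset_ms: float = 0.0

    def __post_init__(self):
        if len(self.tones) != 5:
            raise ValueError("a trial consists of exactly 5 tones")
        if any(t not in ("A", "B") for t in self.tones):
            raise ValueError("tones must be 'A' or 'B'")
        if len(set(self.tones[:4])) != 1:
            raise ValueError("the first four tones must be identical")
        deviant = self.tones[4] != self.tones[3]
        if self.label != trial_label(deviant, self.block_context):
            raise ValueError(
                f"label {self.label!r} inconsistent with tones {self.tones} "
                f"in block context {self.block_context!r}"
            )

    @property
    def is_local_deviant(self) -> bool:
        """True if the fifth tone differs from the first four (an xy sequence)."""
        return self.tones[4] != self.tones[3]


@dataclass(frozen=True)
class BlockDesign:
    """Design of one stimulus block.

    Defaults follow the standard protocol: 20 habituation trials of the
    block's standard sequence, then a shuffled mixture of 64 standard and
    16 deviant sequences; 50 ms tones with 150 ms inter-tone interval and a
    950-1150 ms gap between sequences.
    """

    block_context: str = "XX"
    standard_identity: str = "A"
    n_habituation: int = 20
    n_standard: int = 64
    n_deviant: int = 16
    tone_duration_ms: float = 50.0
    inter_tone_interval_ms: float = 150.0
    inter_sequence_gap_ms: tuple[float, float] = (950.0, 1150.0)
    seed: int = 0

    def __post_init__(self):
        if self.block_context not in _BLOCK_CONTEXTS:
            raise ValueError(f"block_context must be one of {_BLOCK_CONTEXTS}")
        if self.standard_identity not in ("A", "B"):
            raise ValueError("standard_identity must be 'A' or 'B'")
        for name in ("n_habituation", "n_standard", "n_deviant"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        lo, hi = self.inter_sequence_gap_ms
        if not (0 <= lo <= hi):
            raise ValueError("inter_sequence_gap_ms must be an ordered nonnegative range")

    @property
    def n_trials(self) -> int:
        return self.n_habituation + self.n_standard + self.n_deviant

    def _tones_for(self, deviant: bool) -> tuple[str, ...]:
        x = self.standard_identity
        y = "B" if x == "A" else "A"
        if self.block_context == "XX":
            fifth = y if deviant else x
        else:  # XY block: standard sequence ends in y, deviant repeats x
            fifth = x if deviant else y
        return (x, x, x, x, fifth)


@dataclass(frozen=True)
class RegularityStats:
    """Temporal-regularity statistics of a block.

    ``q_local`` is the tone-to-tone x->y transition probability (TP);
    ``d_global`` is the probability of the block's rare sequence (SP of the
    deviant).
    """

    q_local: float
    d_global: float

    def __post_init__(self):
        if not (0.0 <= self.q_local <= 1.0):
            raise ValueError(f"q_local must be in [0, 1], got {self.q_local}")
        if not (0.0 <= self.d_global <= 1.0):
            raise ValueError(f"d_global must be in [0, 1], got {self.d_global}")


def generate_block(design: BlockDesign) -> list[ToneSequence]:
    """Generate the ordered trials of one block.

    The first ``n_habituation`` trials are the block's standard sequence;
    the remaining ``n_standard + n_deviant`` are a seeded random permutation
    of the standard/deviant mixture. Onsets accumulate tone timing plus a
    uniformly drawn inter-sequence gap.
    """
    rng = np.random.default_rng(design.seed)
    deviant_flags = [False] * design.n_habituation
    mixture = [False] * design.n_standard + [True] * design.n_deviant
    deviant_flags += list(rng.permutation(np.asarray(mixture, dtype=bool)))

    seq_duration = 5 * design.tone_duration_ms + 4 * design.inter_tone_interval_ms
    lo, hi = design.inter_sequence_gap_ms
    gaps = rng.uniform(lo, hi, size=max(design.n_trials - 1, 0))

    trials: list[ToneSequence] = []
    onset = 0.0
    for i, dev in enumerate(deviant_flags):
        tones = design._tones_for(dev)
        trials.append(
            ToneSequence(
                tones=tones,
                label=trial_label(tones[4] != tones[0], design.block_context),
                block_context=design.block_context,
                onset_ms=onset,
            )
        )
        if i < design.n_trials - 1:
            onset += seq_duration + gaps[i]
    return trials


def _counted(block: Sequence[ToneSequence], include_habituation: bool,
             n_habituation: int | None) -> Sequence[ToneSequence]:
    if not block:
        raise ValueError("block is empty")
    if include_habituation:
        return block
    if n_habituation is None:
        # habituation = leading run of the block's first label
        first = block[0].label
        k = 0
        while k < len(block) and block[k].label == first:
            k += 1
        # only strip if the leading run is followed by a mixture; otherwise
        # (uniform block) count everything
        n_habituation = k if k < len(block) else 0
    counted = block[n_habituation:]
    if not counted:
        raise ValueError("no trials left after excluding habituation")
    return counted


def estimate_local_regularity(block: Sequence[ToneSequence],
                              include_habituation: bool = False,
                              n_habituation: int | None = 20) -> float:
    """Estimate the tone-to-tone transition probability q (TP).

    Counts x->y transitions over the four within-sequence transitions of
    every counted trial, divided by the number of transitions out of x.
    Habituation trials are excluded by default.
    """
    counted = _counted(block, include_habituation, n_habituation)
    out_of_x = 0
    x_to_y = 0
    for trial in counted:
        for a, b in zip(trial.tones[:-1], trial.tones[1:]):
            if a == trial.tones[0]:  # transition out of the standard tone x
                out_of_x += 1
                if b != a:
                    x_to_y += 1
    if out_of_x == 0:
        raise ValueError("no transitions out of x; q_local is undefined")
    return x_to_y / out_of_x


def estimate_global_regularity(block: Sequence[ToneSequence],
                               include_habituation: bool = False,
                               n_habituation: int | None = 20) -> float:
    """Estimate the deviant-sequence probability d (SP of the rare sequence)."""
    counted = _counted(block, include_habituation, n_habituation)
    n_dev = sum(t.label in ("xy|xx", "xx|xy") for t in counted)
    return n_dev / len(counted)


def block_stats(block: Sequence[ToneSequence],
                include_habituation: bool = False,
                n_habituation: int | None = 20) -> RegularityStats:
    """Convenience: both regularity statistics of a block."""
    return RegularityStats(
        q_local=estimate_local_regularity(block, include_habituation, n_habituation),
        d_global=estimate_global_regularity(block, include_habituation, n_habituation),
    )


def block_to_csv(block: Iterable[ToneSequence], path: str | Path) -> None:
    """Write a block to CSV (trial_index, block_context, label, tones, onset_ms)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_index", "block_context", "label", "tones", "onset_ms"])
        for i, t in enumerate(block):
            w.writerow([i, t.block_context, t.label, "".join(t.tones), f"{t.onset_ms:.3f}"])


def design_to_json(design: BlockDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(design), fh, indent=2)


def design_from_json(path: str | Path) -> BlockDesign:
    with open(path) as fh:
        d = json.load(fh)
    if "inter_sequence_gap_ms" in d:
        d["inter_sequence_gap_ms"] = tuple(d["inter_sequence_gap_ms"])
    return BlockDesign(**d)
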