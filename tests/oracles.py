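"""Independent brute-force oracles used to freeze expected values.

These deliberately re-derive quantities from first principles in a style
independent of the package implementation (explicit per-stream
dictionaries, full enumeration), so that agreement is informative.
"""

from __future__ import annotations

import numpy as np

STREAMS = ("x", "y")


def brute_force_contrasts(s0, s1, s2, q_xx=0.05, q_xy=0.20, d=0.2):
    """Enumerate all four trial types independently and tabulate the 2x2
    contrast matrix [[c1_PE1, c1_PE2], [c2_PE1, c2_PE2]]."""

    def level1_error(q, fifth):
        sensory = {"x": s0 if fifth == "x" else 0.0,
                   "y": 1.0 if fifth == "y" else 0.0}
        prediction = {"x": s1 * (1.0 - q) * s0, "y": s1 * q}
        return {s: sensory[s] - prediction[s] for s in STREAMS}

    def pe_pair(q, fifth, standard_fifth, deviant_fifth):
        e1 = level1_error(q, fifth)
        expected_e1 = {
            s: (1.0 - d) * level1_error(q, standard_fifth)[s]
            + d * level1_error(q, deviant_fifth)[s]
            for s in STREAMS
        }
        e2 = {s: e1[s] - s2 * expected_e1[s] for s in STREAMS}
        return (sum(abs(e1[s]) for s in STREAMS),
                sum(abs(e2[s]) for s in STREAMS))

    # xx block: standard sequence ends in x, deviant in y; xy block reversed
    table = {}
    for trial in ("xx|xx", "xy|xx", "xy|xy", "xx|xy"):
        seq, block = trial.split("|")
        q = q_xx if block == "xx" else q_xy
        std_fifth = "x" if block == "xx" else "y"
        dev_fifth = "y" if block == "xx" else "x"
        fifth = "y" if seq == "xy" else "x"
        table[trial] = pe_pair(q, fifth, std_fifth, dev_fifth)

    return np.array([
        [table["xy|xx"][0] - table["xx|xx"][0], table["xy|xx"][1] - table["xx|xx"][1]],
        [table["xy|xy"][0] - table["xx|xy"][0], table["xy|xy"][1] - table["xx|xy"][1]],
    ])


def rank1_tensor(a, b, c):
    """Outer product tensor of three vectors."""
    return np.einsum("i,j,k->ijk", a, b, c)


def cp_tensor(A, B, C):
    """Sum of rank-1 terms from factor-matrix columns."""
    return sum(rank1_tensor(A[:, r], B[:, r], C[:, r]) for r in range(A.shape[1]))
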