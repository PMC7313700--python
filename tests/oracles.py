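"""Independent brute-force oracles used by the tests.

These are literal double-summation transcriptions of the descriptor
definitions (no streaming, no vectorization) plus an exact-rational
fixed-point oracle.  They deliberately share no code with the package's
implementation paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_force_pass_one(img, mask):
    """Double-loop transcription: count, centroid, extents, channel sums."""
    n, m = mask.shape
    L = 0
    si = sj = 0
    sums = [0, 0, 0]
    z1 = z2 = z3 = z4 = None
    for i in range(n):
        for j in range(m):
            if mask[i, j]:
                L += 1
                si += i
                sj += j
                for c in range(3):
                    sums[c] += int(img[i, j, c])
                z1 = i if z1 is None else z1
                z2 = i
                z3 = j if z3 is None or j < z3 else z3
                z4 = j if z4 is None or j > z4 else z4
    return {
        "nr": L,
        "cx": si / L,
        "cy": sj / L,
        "z1": z1,
        "z2": z2,
        "z3": z3,
        "z4": z4,
        "sums": sums,
        "means": [s / L for s in sums],
    }


def brute_force_raw_descriptors(img, mask) -> np.ndarray:
    """The nine raw descriptors computed as literal double sums."""
    p1 = brute_force_pass_one(img, mask)
    n, m = mask.shape
    L, cx, cy = p1["nr"], p1["cx"], p1["cy"]

    first_rows = sum(
        1 for i in range(n) for j in range(m) if mask[i, j] and i < cx
    )
    first_cols = sum(
        1 for i in range(n) for j in range(m) if mask[i, j] and j < cy
    )
    d0 = abs(first_rows - (L - first_rows))
    d1 = abs(first_cols - (L - first_cols))
    d2 = max(p1["z2"] - p1["z1"], p1["z4"] - p1["z3"])

    out = [d0, d1, d2]
    for c in range(3):
        mean = p1["means"][c]
        terms = [
            (int(img[i, j, c]) - mean) ** 2
            for i in range(n)
            for j in range(m)
            if mask[i, j]
        ]
        out.extend([mean, math.fsum(terms) / L])
    # reorder color block: currently mean,var per channel already in order
    return np.array(out, dtype=float)


def exact_q_raw(x: Fraction, signed: bool, int_bits: int, frac_bits: int) -> int:
    """Exact-rational quantization oracle: floor then saturate, on raws."""
    raw = math.floor(x * (1 << frac_bits))
    lo = -(1 << (int_bits + frac_bits)) if signed else 0
    hi = (1 << (int_bits + frac_bits)) - 1
    return min(max(raw, lo), hi)
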