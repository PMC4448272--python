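"""Independent oracles for the banded stem-arm alignment DP.

Two implementations of the optimal in-band path score, neither sharing
code with the package engine:

* :func:`enumerate_paths_best` — literal DFS over every monotone in-band
  path, scoring each step-by-step (exponential; small arms only).
* :func:`memo_best` — pure-Python memoized prefix recursion over
  (i, j, last-symbol-class) states (arms up to ~10 nt).

Both use the same incremental rule as the engine is specified to use:
a match following a match credits the negated stacking increment, the
first match is free, mismatch steps score minus half the 2-nt internal
loop initiation, gap steps minus the 1-nt bulge initiation.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Tuple

from hairpinscan.thermo import NNParameterSet, PAIR_INDEX

NEG = -1.0e30


def _pair(x: str, y: str) -> str | None:
    key = x + y
    return key if key in PAIR_INDEX else None


def _incs(params: NNParameterSet):
    s_inc = -(params.internal_init[2] / 2.0)
    g_inc = -params.bulge_init[1]
    return s_inc, g_inc


def enumerate_paths_best(
    st1: str, st2: str, dw: int, params: NNParameterSet
) -> Tuple[float, int]:
    """Max path score and number of enumerated in-band paths (DFS)."""
    l = len(st1)
    assert len(st2) == l
    s_inc, g_inc = _incs(params)
    best = [NEG]
    n_paths = [0]

    def rec(i: int, j: int, last_m: bool, score: float) -> None:
        if i == l and j == l:
            n_paths[0] += 1
            if score > best[0]:
                best[0] = score
            return
        # diagonal
        if i < l and j < l:
            p = _pair(st1[i], st2[j])
            if p is not None:
                inc = 0.0
                if last_m:
                    q = _pair(st1[i - 1], st2[j - 1])
                    inc = -params.stacking[(q, p)]
                rec(i + 1, j + 1, True, score + inc)
            else:
                rec(i + 1, j + 1, False, score + s_inc)
        # D consumes arm 1
        if i < l and abs((i + 1) - j) <= dw:
            rec(i + 1, j, False, score + g_inc)
        # I consumes arm 2
        if j < l and abs(i - (j + 1)) <= dw:
            rec(i, j + 1, False, score + g_inc)

    rec(0, 0, False, 0.0)
    return best[0], n_paths[0]


def memo_best(st1: str, st2: str, dw: int, params: NNParameterSet) -> float:
    """Max in-band path score via memoized prefix recursion."""
    l = len(st1)
    s_inc, g_inc = _incs(params)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state_m: bool) -> float:
        if abs(i - j) > dw or i < 0 or j < 0:
            return NEG
        if i == 0 and j == 0:
            return NEG if state_m else 0.0
        if state_m:
            if i == 0 or j == 0:
                return NEG
            p = _pair(st1[i - 1], st2[j - 1])
            if p is None:
                return NEG
            from_m = best(i - 1, j - 1, True)
            if from_m > NEG / 2:
                q = _pair(st1[i - 2], st2[j - 2]) if i >= 2 and j >= 2 else None
                from_m = from_m + (-params.stacking[(q, p)]) if q else from_m
            return max(from_m, best(i - 1, j - 1, False))
        cands = []
        if i >= 1 and j >= 1 and _pair(st1[i - 1], st2[j - 1]) is None:
            cands.append(best(i - 1, j - 1, True) + s_inc)
            cands.append(best(i - 1, j - 1, False) + s_inc)
        if i >= 1:
            cands.append(best(i - 1, j, True) + g_inc)
            cands.append(best(i - 1, j, False) + g_inc)
        if j >= 1:
            cands.append(best(i, j - 1, True) + g_inc)
            cands.append(best(i, j - 1, False) + g_inc)
        return max(cands) if cands else NEG

    return max(best(l, l, True), best(l, l, False))


def window_count_formula(N: int, l: int, n_min: int, n_max: int) -> int:
    """Closed form for the number of (i, n) scan windows."""
    return sum(max(0, N - 2 * l - n + 1) for n in range(n_min, n_max + 1))
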