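"""Banded Needleman-Wunsch alignment of the two candidate stem-arms.

The two arms of a putative hairpin are globally aligned with a dynamic
programme whose incremental scores are negated NN energy contributions, so
that maximising the DP score approximately minimises the duplex free energy.
The alignment is constrained to a diagonal band of half-width ``dw`` (the
maximum bulge length); ``dw`` equal to the arm length recovers the full
matrix.  The energy that is *reported* for a candidate is never the DP
score: the alignment is decomposed into motifs (helices, bulges, internal
loops, dangling ends) and re-scored exactly with the NN model.

Incremental surrogate driving the DP (see docs/methods.md): a match (M)
following another match credits the true stacking increment of the pair
step; the first pair of a helix is free; a mismatch step (S) charges half
the 2-nt internal-loop initiation; every gap step (I/D) charges the 1-nt
bulge initiation.  Ties prefer diagonal moves (M/S) over deletions over
insertions, and a match-predecessor over a non-match one, which keeps the
traceback deterministic and the stems compact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .thermo import (
    AMBIGUOUS_CODE,
    BASES,
    BASE_CODE,
    PAIR_CODE_TABLE,
    CANONICAL_PAIRS,
    Motif,
    MotifKind,
    NNParameterSet,
    is_canonical,
    encode_sequence,
    total_energy,
)

__all__ = [
    "AlignmentSymbol",
    "AlignmentVector",
    "StemArmPair",
    "BandConfig",
    "AlignmentStats",
    "align_arms",
    "align_arm_batch",
    "decompose_motifs",
    "score_alignment",
    "to_dot_bracket",
]

GAP = "-"

# pointer codes (per DP state; -1 = unset)
_P_M_FROM_M = 0
_P_M_FROM_O = 1
_P_S_FROM_M = 2
_P_S_FROM_O = 3
_P_D_FROM_M = 4
_P_D_FROM_O = 5
_P_I_FROM_M = 6
_P_I_FROM_O = 7

_NEG = -1.0e30


@dataclass(frozen=True)
class AlignmentSymbol:
    """One column of a stem-arm alignment.

    ``op`` is M (canonical pair), S (mismatch), I (insertion: base on arm 2
    only) or D (deletion: base on arm 1 only); ``x``/``y`` are the arm-1 and
    arm-2 bases or '-'.
    """

    op: str
    x: str
    y: str

    def __post_init__(self):
        if self.op == "M":
            if not is_canonical(self.x, self.y):
                raise ValueError(f"M symbol requires a canonical pair, got {self.x}{self.y}")
        elif self.op == "S":
            if GAP in (self.x, self.y) or is_canonical(self.x, self.y):
                raise ValueError("S symbol requires two non-pairing bases")
        elif self.op == "I":
            if self.x != GAP or self.y == GAP:
                raise ValueError("I symbol requires x='-' and a base on y")
        elif self.op == "D":
            if self.y != GAP or self.x == GAP:
                raise ValueError("D symbol requires y='-' and a base on x")
        else:
            raise ValueError(f"unknown op {self.op!r}")


@dataclass
class AlignmentVector:
    """Ordered alignment symbols plus the (orientation-normalized) arms."""

    symbols: List[AlignmentSymbol]
    arm1_sequence: str
    arm2_sequence: str  # stored 3'->5' so column pairs are antiparallel

    def __post_init__(self):
        if "".join(s.x for s in self.symbols if s.x != GAP) != self.arm1_sequence:
            raise ValueError("alignment does not project onto arm 1")
        if "".join(s.y for s in self.symbols if s.y != GAP) != self.arm2_sequence:
            raise ValueError("alignment does not project onto arm 2")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def ops(self) -> str:
        return "".join(s.op for s in self.symbols)

    def alignment_string(self) -> str:
        """Three-row text rendering (arm1 / ops / arm2-as-stored)."""
        return "|".join(
            ("".join(s.x for s in self.symbols), self.ops, "".join(s.y for s in self.symbols))
        )


@dataclass
class StemArmPair:
    """A 5' arm, a terminal loop and a 3' arm (stored 3'->5').

    ``st2`` must already be orientation-normalized: its first base is the
    one pairing with the first base of ``st1``.
    """

    st1: str
    st2: str
    loop_seq: str = ""
    sequence_id: Optional[str] = None
    start: Optional[int] = None  # genomic start of the whole window
    strand: str = "+"

    def __post_init__(self):
        if len(self.st1) != len(self.st2):
            raise ValueError("stem arms must have equal length")
        if not self.st1:
            raise ValueError("stem arms must be non-empty")

    @property
    def l(self) -> int:
        return len(self.st1)

    @property
    def n(self) -> int:
        return len(self.loop_seq)


@dataclass(frozen=True)
class BandConfig:
    """Diagonal band of the DP matrix: cells with |row - col| > dw are pruned."""

    dw: int = 5
    full_matrix: bool = False

    def __post_init__(self):
        if not self.full_matrix and self.dw < 1:
            raise ValueError("dw must be >= 1 unless full_matrix")

    def effective_dw(self, l: int) -> int:
        return l if self.full_matrix else min(self.dw, l)

    @classmethod
    def full(cls) -> "BandConfig":
        return cls(dw=1, full_matrix=True)


@dataclass
class AlignmentStats:
    """Instrumentation of one DP run (per aligned pair)."""

    dp_cells: int
    score: float


# --------------------------------------------------------------------------
# Batched banded DP engine
# --------------------------------------------------------------------------


def _dp_increments(params: NNParameterSet) -> Tuple[np.ndarray, float, float]:
    stack = params.stacking_matrix()
    s_inc = -(params.internal_init[2] / 2.0)
    g_inc = -params.bulge_init[1]
    return stack, s_inc, g_inc


def align_arm_batch(
    A1: np.ndarray, A2: np.ndarray, dw: int, params: NNParameterSet
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Run the banded DP on a batch of encoded arm pairs.

    Parameters
    ----------
    A1, A2 : int8 arrays of shape (B, l)
        Arm 1 (5'->3') and arm 2 (3'->5') base codes.
    dw : int
        Band half-width (1..l).

    Returns
    -------
    scores : (B,) best DP score per pair.
    ptr_m, ptr_o : (B, l+1, 2*dw+1) int8 traceback pointers per state.
    final_state : (B,) 0 if the optimum ends in the M state, 1 otherwise.
    cells : number of in-band DP cells per pair.
    """
    B, l = A1.shape
    dw = min(max(dw, 1), l)
    W = 2 * dw + 1
    stack, s_inc, g_inc = _dp_increments(params)

    prev_m = np.full((B, W), _NEG)
    prev_o = np.full((B, W), _NEG)
    ptr_m = np.full((B, l + 1, W), -1, dtype=np.int8)
    ptr_o = np.full((B, l + 1, W), -1, dtype=np.int8)
    cells = 0

    # row 0: only I steps along j
    prev_o[:, dw] = 0.0
    cells += 1
    for d in range(dw + 1, min(2 * dw, dw + l) + 1):
        prev_o[:, d] = prev_o[:, d - 1] + g_inc
        ptr_o[:, 0, d] = _P_I_FROM_O
        cells += 1

    for i in range(1, l + 1):
        cur_m = np.full((B, W), _NEG)
        cur_o = np.full((B, W), _NEG)
        for d in range(W):
            j = i + d - dw
            if j < 0 or j > l:
                continue
            cells += 1
            if j >= 1:
                p = PAIR_CODE_TABLE[A1[:, i - 1], A2[:, j - 1]]
                canon = p >= 0
                if i >= 2 and j >= 2:
                    q = PAIR_CODE_TABLE[A1[:, i - 2], A2[:, j - 2]]
                else:
                    q = np.full(B, -1, dtype=np.int8)
                gain = np.where(
                    (q >= 0) & canon,
                    -stack[np.maximum(q, 0), np.maximum(p, 0)],
                    0.0,
                )
                # M state (prefer M-predecessor on ties)
                cand_mm = prev_m[:, d] + gain
                cand_mo = prev_o[:, d]
                m_val = np.where(cand_mm >= cand_mo, cand_mm, cand_mo)
                m_ptr = np.where(cand_mm >= cand_mo, _P_M_FROM_M, _P_M_FROM_O)
                cur_m[:, d] = np.where(canon, m_val, _NEG)
                ptr_m[:, i, d] = np.where(canon, m_ptr, -1)
                # S candidates (non-canonical diagonal)
                s_m = np.where(~canon, prev_m[:, d] + s_inc, _NEG)
                s_o = np.where(~canon, prev_o[:, d] + s_inc, _NEG)
            else:
                s_m = np.full(B, _NEG)
                s_o = np.full(B, _NEG)
            # D: from (i-1, j) = offset d+1 in previous row
            if d + 1 < W:
                d_m = prev_m[:, d + 1] + g_inc
                d_o = prev_o[:, d + 1] + g_inc
            else:
                d_m = np.full(B, _NEG)
                d_o = np.full(B, _NEG)
            # I: from (i, j-1) = offset d-1 in current row
            if d - 1 >= 0 and j >= 1:
                i_m = cur_m[:, d - 1] + g_inc
                i_o = cur_o[:, d - 1] + g_inc
            else:
                i_m = np.full(B, _NEG)
                i_o = np.full(B, _NEG)
            cand = np.stack([s_m, s_o, d_m, d_o, i_m, i_o])
            best = np.argmax(cand, axis=0)  # first max wins: S > D > I, M-pred first
            cur_o[:, d] = cand[best, np.arange(B)]
            ptr_o[:, i, d] = best + _P_S_FROM_M
        prev_m, prev_o = cur_m, cur_o

    end_m = prev_m[:, dw]
    end_o = prev_o[:, dw]
    final_state = np.where(end_m >= end_o, 0, 1).astype(np.int8)
    scores = np.where(final_state == 0, end_m, end_o)
    return scores, ptr_m, ptr_o, final_state, cells


def _traceback(
    b: int,
    l: int,
    dw: int,
    ptr_m: np.ndarray,
    ptr_o: np.ndarray,
    final_state: int,
    st1: str,
    st2: str,
) -> List[AlignmentSymbol]:
    i, j, state = l, l, int(final_state)
    out: List[AlignmentSymbol] = []
    while i > 0 or j > 0:
        d = j - i + dw
        ptr = int(ptr_m[b, i, d]) if state == 0 else int(ptr_o[b, i, d])
        if ptr < 0:
            raise RuntimeError("broken traceback pointer")
        if ptr in (_P_M_FROM_M, _P_M_FROM_O):
            out.append(AlignmentSymbol("M", st1[i - 1], st2[j - 1]))
            state = 0 if ptr == _P_M_FROM_M else 1
            i, j = i - 1, j - 1
        elif ptr in (_P_S_FROM_M, _P_S_FROM_O):
            out.append(AlignmentSymbol("S", st1[i - 1], st2[j - 1]))
            state = 0 if ptr == _P_S_FROM_M else 1
            i, j = i - 1, j - 1
        elif ptr in (_P_D_FROM_M, _P_D_FROM_O):
            out.append(AlignmentSymbol("D", st1[i - 1], GAP))
            state = 0 if ptr == _P_D_FROM_M else 1
            i = i - 1
        else:
            out.append(AlignmentSymbol("I", GAP, st2[j - 1]))
            state = 0 if ptr == _P_I_FROM_M else 1
            j = j - 1
    out.reverse()
    return out


def _normalize_arm(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    for ch in seq:
        if ch not in BASES and ch != "N":
            raise ValueError(f"invalid arm symbol {ch!r}")
    return seq


def align_arms(
    pair: StemArmPair,
    params: NNParameterSet,
    band: BandConfig = BandConfig(),
    with_stats: bool = False,
):
    """Align one stem-arm pair; returns the optimal :class:`AlignmentVector`.

    With ``with_stats=True`` returns ``(vector, AlignmentStats)``.
    """
    st1 = _normalize_arm(pair.st1)
    st2 = _normalize_arm(pair.st2)
    l = len(st1)
    dw = band.effective_dw(l)
    A1 = encode_sequence(st1)[None, :]
    A2 = encode_sequence(st2)[None, :]
    scores, ptr_m, ptr_o, fstate, cells = align_arm_batch(A1, A2, dw, params)
    symbols = _traceback(0, l, dw, ptr_m, ptr_o, int(fstate[0]), st1, st2)
    v = AlignmentVector(symbols, st1, st2)
    if with_stats:
        return v, AlignmentStats(dp_cells=cells, score=float(scores[0]))
    return v


# --------------------------------------------------------------------------
# Motif decomposition and exact scoring
# --------------------------------------------------------------------------


def decompose_motifs(v: AlignmentVector) -> List[Motif]:
    """Partition an alignment into motifs for exact NN scoring.

    Maximal M runs become helices; interior non-M runs become internal
    loops (bases on both strands) or bulges (one strand); a single unpaired
    base at either stem end is scored as a dangling end, longer terminal
    runs are dropped with a warning.
    """
    runs: List[Tuple[bool, List[AlignmentSymbol]]] = []
    for s in v.symbols:
        is_m = s.op == "M"
        if runs and runs[-1][0] == is_m:
            runs[-1][1].append(s)
        else:
            runs.append((is_m, [s]))

    motifs: List[Motif] = []
    helices = [idx for idx, (is_m, _) in enumerate(runs) if is_m]
    if not helices:
        warnings.warn("alignment contains no canonical pair; no motifs", stacklevel=2)
        return []

    def closing(run_idx: int, first: bool) -> Tuple[str, str]:
        syms = runs[run_idx][1]
        s = syms[0] if first else syms[-1]
        return (s.x, s.y)

    for idx, (is_m, syms) in enumerate(runs):
        if is_m:
            motifs.append(Motif.helix([(s.x, s.y) for s in syms]))
            continue
        left = closing(idx - 1, first=False) if idx > 0 else None
        right = closing(idx + 1, first=True) if idx < len(runs) - 1 else None
        u1 = "".join(s.x for s in syms if s.x != GAP)
        u2 = "".join(s.y for s in syms if s.y != GAP)
        if left is None or right is None:
            # terminal unpaired run
            if len(u1) + len(u2) == 1:
                base = u1 or u2
                anchor = right if left is None else left
                on_arm1 = bool(u1)
                if left is None:  # 5' end of arm1 / 3' end of arm2
                    side = "5" if on_arm1 else "3"
                else:
                    side = "3" if on_arm1 else "5"
                motifs.append(Motif.dangling_end(anchor, base, side))
            else:
                warnings.warn(
                    f"unscored terminal unpaired run of {len(u1) + len(u2)} bases",
                    stacklevel=2,
                )
            continue
        if u1 and u2:
            motifs.append(Motif.internal_loop(u1, u2, left, right))
        else:
            unpaired = u1 or u2
            strand = 1 if u1 else 2
            t = 1
            if len(unpaired) == 1:
                b = unpaired[0]
                flank_idx = 0 if strand == 1 else 1
                t += int(left[flank_idx] == b) + int(right[flank_idx] == b)
            motifs.append(Motif.bulge(unpaired, strand, left, right, t_conformations=t))
    return motifs


def score_alignment(v: AlignmentVector, params: NNParameterSet) -> float:
    """Exact NN free energy of an alignment (motif re-scoring, kcal/mol)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        motifs = decompose_motifs(v)
        return total_energy(params, motifs) if motifs else 0.0


def to_dot_bracket(pair: StemArmPair, v: AlignmentVector) -> str:
    """Dot-bracket string of length 2l + n for the whole candidate window."""
    arm1 = "".join(("(" if s.op == "M" else ".") for s in v.symbols if s.x != GAP)
    # arm 2 symbols run 3'->5'; genomic order is the reverse
    arm2 = "".join((")" if s.op == "M" else ".") for s in v.symbols if s.y != GAP)[::-1]
    return arm1 + "." * pair.n + arm2
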