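"""Sliding-window genome screen for candidate pre-miRNA hairpins.

Every start position i and every terminal-loop length n in [n_min, n_max]
defines one window: a 5' arm of l bases, a loop of n bases and a 3' arm of
l bases immediately after it (0-based half-open coordinates throughout).
Each window's arms are aligned with the banded DP and re-scored exactly
with the NN model; windows whose exact energy is at or below the threshold
(default -20.6 kcal/mol) are emitted as candidates.

For speed the per-window DPs are run in vectorized batches, and windows
whose DP incremental energy is far above the threshold (by more than
``prescreen_margin``) are discarded without the exact re-scoring; the
margin is generous because the incremental surrogate over-penalizes bulges
(see docs/methods.md).  ``prescreen_margin=None`` re-scores every window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .align import (
    AlignmentVector,
    BandConfig,
    StemArmPair,
    _traceback,
    align_arm_batch,
    score_alignment,
    to_dot_bracket,
)
from .thermo import BASES, NNParameterSet, encode_sequence

__all__ = [
    "ScanConfig",
    "HairpinCandidate",
    "enumerate_windows",
    "scan_sequence",
    "resolve_overlaps",
    "apply_mask",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase, DNA->RNA; non-IUPAC symbols become N with a warning."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set(BASES) - set("NRYSWKMBDHV")
    if bad:
        warnings.warn(f"non-IUPAC symbols {sorted(bad)} masked to N", stacklevel=2)
    out = []
    for ch in seq:
        out.append(ch if ch in BASES else "N")
    return "".join(out)


@dataclass(frozen=True)
class ScanConfig:
    """Geometry and filtering parameters of a genome scan."""

    l: int = 25
    n_min: int = 5
    n_max: int = 20
    energy_threshold: float = -20.6
    band: BandConfig = field(default_factory=BandConfig)
    scan_both_strands: bool = True
    prescreen_margin: Optional[float] = 15.0

    def __post_init__(self):
        if self.l < 1:
            raise ValueError("arm length l must be >= 1")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= n_min <= n_max")
        if not np.isfinite(self.energy_threshold):
            raise ValueError("energy threshold must be finite")


@dataclass
class HairpinCandidate:
    """A scored stem-loop locus (coordinates 0-based half-open, forward frame)."""

    sequence_id: str
    start: int
    end: int
    strand: str
    l: int
    n: int
    alignment: AlignmentVector
    energy: float
    structure: str

    @property
    def arm_intervals(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """Genomic intervals of the two stem-arms."""
        return ((self.start, self.start + self.l), (self.end - self.l, self.end))

    def overlaps(self, other: "HairpinCandidate") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def enumerate_windows(W: str, config: ScanConfig) -> Iterator[StemArmPair]:
    """Yield every candidate stem-arm pair of the sliding-window geometry.

    st1 = W[i, i+l); loop = W[i+l, i+l+n); st2 = the l bases after the loop,
    reversed so that it is stored 3'->5'.
    """
    N = len(W)
    l, n_min, n_max = config.l, config.n_min, config.n_max
    if N < 2 * l + n_min:
        warnings.warn("sequence shorter than the minimal window; nothing to scan", stacklevel=2)
        return
    for i in range(0, N - 2 * l - n_min + 1):
        for n in range(n_min, n_max + 1):
            if i + 2 * l + n > N:
                break
            yield StemArmPair(
                st1=W[i : i + l],
                st2=W[i + l + n : i + 2 * l + n][::-1],
                loop_seq=W[i + l : i + l + n],
                start=i,
            )


def _scan_one_strand(
    seq: str,
    seq_id: str,
    strand: str,
    N_forward: int,
    config: ScanConfig,
    params: NNParameterSet,
) -> List[HairpinCandidate]:
    N = len(seq)
    l = config.l
    dw = config.band.effective_dw(l)
    codes = encode_sequence(seq)
    out: List[HairpinCandidate] = []
    if N < 2 * l + config.n_min:
        return out
    win = np.lib.stride_tricks.sliding_window_view(codes, l)
    for n in range(config.n_min, config.n_max + 1):
        n_windows = N - 2 * l - n + 1
        if n_windows <= 0:
            continue
        starts = np.arange(n_windows)
        A1 = np.ascontiguousarray(win[starts])
        A2 = np.ascontiguousarray(win[starts + l + n][:, ::-1])
        scores, ptr_m, ptr_o, fstate, _ = align_arm_batch(A1, A2, dw, params)
        heuristic_energy = -scores
        if config.prescreen_margin is None:
            keep = np.arange(n_windows)
        else:
            keep = np.nonzero(
                heuristic_energy <= config.energy_threshold + config.prescreen_margin
            )[0]
        for b in keep:
            i = int(starts[b])
            st1 = seq[i : i + l]
            st2 = seq[i + l + n : i + 2 * l + n][::-1]
            symbols = _traceback(b, l, dw, ptr_m, ptr_o, int(fstate[b]), st1, st2)
            v = AlignmentVector(symbols, st1, st2)
            energy = score_alignment(v, params)
            if energy > config.energy_threshold:
                continue
            pair = StemArmPair(
                st1=st1, st2=st2, loop_seq=seq[i + l : i + l + n],
                sequence_id=seq_id, start=i, strand=strand,
            )
            if strand == "+":
                start, end = i, i + 2 * l + n
            else:
                start, end = N_forward - (i + 2 * l + n), N_forward - i
            out.append(
                HairpinCandidate(
                    sequence_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    l=l,
                    n=n,
                    alignment=v,
                    energy=energy,
                    structure=to_dot_bracket(pair, v),
                )
            )
    return out


def scan_sequence(
    W: str,
    config: ScanConfig,
    params: NNParameterSet,
    sequence_id: str = "seq",
) -> List[HairpinCandidate]:
    """Scan a sequence (and by default its reverse complement) for stable
    hairpins; returns candidates with exact energy <= the threshold."""
    seq = normalize_sequence(W)
    N = len(seq)
    candidates = _scan_one_strand(seq, sequence_id, "+", N, config, params)
    if config.scan_both_strands:
        candidates += _scan_one_strand(
            reverse_complement(seq), sequence_id, "-", N, config, params
        )
    candidates.sort(key=lambda c: (c.start, c.n, c.strand))
    logger.info(
        "scan of %s (%d nt): %d candidate(s) at threshold %.2f kcal/mol",
        sequence_id, N, len(candidates), config.energy_threshold,
    )
    return candidates


def resolve_overlaps(candidates: Sequence[HairpinCandidate]) -> List[HairpinCandidate]:
    """Greedy per-locus selection: best (lowest) energy first, keep a
    candidate only if it does not overlap an already-kept one on the same
    sequence and strand.  Deterministic: ties broken by (start, n)."""
    ranked = sorted(candidates, key=lambda c: (c.energy, c.start, c.n))
    kept: List[HairpinCandidate] = []
    for cand in ranked:
        if not any(cand.overlaps(k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.sequence_id, c.start, c.strand))
    return kept


def apply_mask(W: str, mask_intervals: Iterable[Tuple[int, int]]) -> str:
    """Replace masked [start, end) positions by N so they cannot pair."""
    chars = list(W)
    for start, end in mask_intervals:
        if start < 0 or end > len(W) or start > end:
            raise ValueError(f"mask interval ({start}, {end}) out of range")
        for k in range(start, end):
            chars[k] = "N"
    return "".join(chars)
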