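"""A-posteriori Dicer-signature check of predicted hairpins.

Dicer processing of a genuine pre-miRNA leaves reads stacked on the mature
and star arms, with few fragments crossing into the terminal loop.  Each
read over a predicted hairpin is assigned to the region (5'-arm "mature",
terminal loop, 3'-arm "star") containing most of its bases; the fraction of
its bases falling outside that region is its overlap percentage.  Two
tunables control tolerance: a per-read overlap ceiling defining an
"overlapping" read, and a ceiling on the percentage of reads allowed to be
overlapping.  Setting the first to zero is the strict-processing mode.

The check is advisory: it filters nothing in the scan pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

from .procin import MappedRead
from .screen import HairpinCandidate

__all__ = ["DicerConfig", "HairpinRegion", "HairpinReadPartition", "DicerVerdict",
           "partition_reads", "check_dicer"]


class HairpinRegion(Enum):
    MATURE = "mature"   # 5' arm
    LOOP = "loop"
    STAR = "star"       # 3' arm


@dataclass(frozen=True)
class DicerConfig:
    """Tolerances, both percentages in [0, 100]."""

    max_read_overlap_pct: float = 0.0
    max_overlapping_reads_pct: float = 0.0

    def __post_init__(self):
        for v in (self.max_read_overlap_pct, self.max_overlapping_reads_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must be in [0, 100]")


@dataclass
class HairpinReadPartition:
    """Reads of one hairpin keyed by their primary region, plus per-read
    boundary-overlap percentages."""

    candidate: HairpinCandidate
    assignments: List[Tuple[MappedRead, HairpinRegion, float]] = field(default_factory=list)

    def counts(self) -> Dict[HairpinRegion, int]:
        out = {r: 0 for r in HairpinRegion}
        for _, region, _ in self.assignments:
            out[region] += 1
        return out

    def crossing_reads(self, max_read_overlap_pct: float) -> List[Tuple[MappedRead, float]]:
        return [(r, pct) for r, _, pct in self.assignments if pct > max_read_overlap_pct]


@dataclass
class DicerVerdict:
    passed: bool
    n_reads: int
    n_overlapping: int
    no_evidence: bool
    offending: List[Tuple[MappedRead, float]]


def _regions(candidate: HairpinCandidate) -> Dict[HairpinRegion, Tuple[int, int]]:
    s, e, l, n = candidate.start, candidate.end, candidate.l, candidate.n
    if candidate.strand == "+":
        return {
            HairpinRegion.MATURE: (s, s + l),
            HairpinRegion.LOOP: (s + l, s + l + n),
            HairpinRegion.STAR: (e - l, e),
        }
    return {  # 5' arm of a minus-strand hairpin sits at the genomic right
        HairpinRegion.MATURE: (e - l, e),
        HairpinRegion.LOOP: (s + l, s + l + n),
        HairpinRegion.STAR: (s, s + l),
    }


def partition_reads(
    candidate: HairpinCandidate, reads: Sequence[MappedRead]
) -> HairpinReadPartition:
    """Assign each overlapping read to its majority region (ties favour the
    arms, never the loop) and record its boundary-overlap percentage."""
    regions = _regions(candidate)
    part = HairpinReadPartition(candidate=candidate)
    # tie order: mature beats star beats loop
    order = [HairpinRegion.MATURE, HairpinRegion.STAR, HairpinRegion.LOOP]
    for read in reads:
        if read.sequence_id != candidate.sequence_id:
            continue
        if read.end <= candidate.start or read.start >= candidate.end:
            continue  # not overlapping: ignored
        best_region, best_inside = None, -1
        for region in order:
            rs, re = regions[region]
            inside = max(0, min(read.end, re) - max(read.start, rs))
            if inside > best_inside:
                best_region, best_inside = region, inside
        pct = 100.0 * (len(read) - best_inside) / len(read)
        part.assignments.append((read, best_region, pct))
    return part


def check_dicer(partition: HairpinReadPartition, config: DicerConfig) -> DicerVerdict:
    """Pass unless the fraction of reads whose overlap percentage exceeds
    the per-read ceiling itself exceeds the population ceiling."""
    n = len(partition.assignments)
    if n == 0:
        return DicerVerdict(passed=True, n_reads=0, n_overlapping=0,
                            no_evidence=True, offending=[])
    offending = partition.crossing_reads(config.max_read_overlap_pct)
    frac_pct = 100.0 * len(offending) / n
    return DicerVerdict(
        passed=frac_pct <= config.max_overlapping_reads_pct,
        n_reads=n,
        n_overlapping=len(offending),
        no_evidence=False,
        offending=offending,
    )
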