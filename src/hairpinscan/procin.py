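"""sRNA-seq pre-processing: expressed regions and arm/loop length inference.

Mapped small-RNA reads delimit the transcribed loci worth scanning and,
through the geometry of their pile-ups ("stacks"), suggest the stem-arm
length l and the maximum terminal-loop length t of the precursor:

* the highest read stack on the 5' half ends at region-local position i
  (0-based, inclusive)  ->  l = i + 1;
* the highest stack on the 3' half starts at region-local position j
  (1-based) of a region of length p  ->  l = p - j + 1;
* the arm is mirrored onto the other side, so t = p - 2l.

Reads overlapping the middle coordinate of the region are disregarded, so
loop-derived fragments cannot distort the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .align import BandConfig
from .screen import ScanConfig

__all__ = [
    "MappedRead",
    "ExpressedRegion",
    "ArmLoopEstimate",
    "ScanTask",
    "extract_expressed_regions",
    "infer_arm_and_loop",
    "regions_to_scan_inputs",
]


@dataclass(frozen=True)
class MappedRead:
    """A read alignment on the reference (0-based half-open)."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("read interval must be non-empty")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExpressedRegion:
    """A maximal covered genomic run, possibly extended to pre-miRNA size."""

    sequence_id: str
    start: int
    end: int
    reads: List[MappedRead]
    extended: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmLoopEstimate:
    l: int
    t: int
    dominant_arm: str  # "5'" or "3'"

    def __post_init__(self):
        if self.l < 1 or self.t < 0:
            raise ValueError("invalid arm/loop estimate")


@dataclass
class ScanTask:
    """A per-region scan input: the sequence plus its tailored config."""

    sequence: str
    config: ScanConfig
    region: ExpressedRegion


def extract_expressed_regions(
    reads: Sequence[MappedRead],
    genome_lengths: Mapping[str, int],
    min_reads: int = 1,
    min_len: int = 70,
) -> List[ExpressedRegion]:
    """Maximal runs with coverage >= min_reads; short regions are extended
    by ``min_len`` both up- and downstream (clipped at sequence ends)."""
    by_seq: Dict[str, List[MappedRead]] = {}
    for r in reads:
        if r.sequence_id not in genome_lengths:
            warnings.warn(f"read on unknown sequence {r.sequence_id!r} skipped", stacklevel=2)
            continue
        by_seq.setdefault(r.sequence_id, []).append(r)

    regions: List[ExpressedRegion] = []
    for seq_id, rs in by_seq.items():
        L = genome_lengths[seq_id]
        delta = np.zeros(L + 1, dtype=np.int32)
        for r in rs:
            delta[min(r.start, L)] += 1
            delta[min(r.end, L)] -= 1
        cov = np.cumsum(delta[:-1])
        covered = cov >= min_reads
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            s, e = int(s), int(e)
            extended = False
            if e - s < min_len:
                s, e = max(0, s - min_len), min(L, e + min_len)
                extended = True
            region_reads = [r for r in rs if r.start < e and r.end > s]
            regions.append(ExpressedRegion(seq_id, s, e, region_reads, extended))
    regions.sort(key=lambda g: (g.sequence_id, g.start))
    return regions


def _stacks(starts_ends: List[Tuple[int, int]]) -> List[Tuple[int, List[Tuple[int, int]]]]:
    """Group reads into stacks of near-identical (+-1) start positions.

    Returns (anchor_start, members) sorted by anchor.
    """
    out = []
    for s0, _ in starts_ends:
        members = [(s, e) for s, e in starts_ends if abs(s - s0) <= 1]
        out.append((s0, members))
    out.sort(key=lambda t: t[0])
    return out


def infer_arm_and_loop(region: ExpressedRegion) -> ArmLoopEstimate:
    """Infer (l, t) from the highest read stack of a region (see module doc).

    Raises ``ValueError`` when every read covers the middle coordinate.
    """
    p = region.length
    middle = p // 2  # region-local
    local: List[Tuple[int, int]] = []
    for r in region.reads:
        s = max(0, r.start - region.start)
        e = min(p, r.end - region.start)
        if e <= s:
            continue
        if s <= middle < e:
            continue  # loop-spanning read: disregard
        local.append((s, e))
    if not local:
        raise ValueError(
            f"region {region.sequence_id}:{region.start}-{region.end}: "
            "all reads align to the middle coordinate; cannot infer arm length"
        )

    five = [(s, e) for s, e in local if e <= middle]
    three = [(s, e) for s, e in local if s > middle]

    best: Optional[Tuple[int, str, int, List[Tuple[int, int]]]] = None
    for side, rs in (("5'", five), ("3'", three)):
        for anchor, members in _stacks(rs):
            height = len(members)
            # prefer higher stacks; ties favour the 5' arm then smaller anchors
            key = (-height, 0 if side == "5'" else 1, anchor)
            if best is None or key < best[0]:
                best = (key, side, anchor, members)
    assert best is not None
    _, side, _, members = best
    if side == "5'":
        i = max(e - 1 for _, e in members)  # 0-based inclusive end
        l = i + 1
    else:
        j = min(s for s, _ in members) + 1  # 1-based start
        l = p - j + 1
    t = p - 2 * l
    if t < 0:
        raise ValueError("inferred arms overlap (2l > p)")
    return ArmLoopEstimate(l=l, t=t, dominant_arm=side)


def regions_to_scan_inputs(
    regions: Sequence[ExpressedRegion],
    estimates: Sequence[ArmLoopEstimate],
    base_config: ScanConfig,
    genome: Mapping[str, str],
) -> List[ScanTask]:
    """Build one scan task per region with arm length l and loop range
    [n_min, t]; regions too short for the geometry are skipped."""
    if len(regions) != len(estimates):
        raise ValueError("need exactly one estimate per region")
    tasks: List[ScanTask] = []
    for region, est in zip(regions, estimates):
        if 2 * est.l + base_config.n_min > region.length or est.t < base_config.n_min:
            warnings.warn(
                f"region {region.sequence_id}:{region.start}-{region.end} skipped: "
                f"estimate l={est.l}, t={est.t} incompatible with n_min={base_config.n_min}",
                stacklevel=2,
            )
            continue
        band = BandConfig(dw=est.l, full_matrix=True) if base_config.band.full_matrix \
            else base_config.band
        config = replace(base_config, l=est.l, n_max=est.t, band=band)
        seq = genome[region.sequence_id][region.start : region.end]
        tasks.append(ScanTask(sequence=seq, config=config, region=region))
    return tasks
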