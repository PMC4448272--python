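"""Synthetic study-condition generator: genomes with planted hairpins.

Builds an i.i.d. multinomial background genome, plants non-overlapping
stem-loops (a GC-rich 5' arm, a random terminal loop, and the reverse
complement of the arm, optionally degraded by substitutions and single-base
bulges), records the truth intervals (whole hairpin plus a designated
mature sub-interval on the 5' arm), and fabricates arm-anchored read stacks
with optional loop-spanning reads for the sRNA-seq modules.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calibrate import ControlInterval, ControlSet
from .procin import MappedRead
from .screen import reverse_complement

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome.

    ``mutation_rate``/``indel_rate`` are per-arm-base rates; the realized
    count per arm is round(rate * arm_length) at seed-chosen positions, so
    e.g. rate 0.08 with 25-nt arms plants exactly two mismatches.
    """

    genome_length: int = 50_000
    base_frequencies: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_hairpins: int = 10
    arm_length: int = 25
    loop_length: int = 8
    arm_gc: float = 0.8
    mutation_rate: float = 0.0
    indel_rate: float = 0.0
    reads_per_arm: int = 0
    read_length: int = 22
    loop_spanning_reads: int = 0
    mature_length: int = 22
    mature_offset: int = 1
    seed: int = 0
    sequence_id: str = "synth1"

    def __post_init__(self):
        for rate in (self.mutation_rate, self.indel_rate, self.arm_gc):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.mature_offset + self.mature_length > self.arm_length:
            raise ValueError("mature interval must fit inside the arm")

    @property
    def hairpin_length(self) -> int:
        return 2 * self.arm_length + self.loop_length


@dataclass
class Fixture:
    genome: Dict[str, str]
    hairpins: List[ControlInterval]   # whole planted stem-loops
    matures: ControlSet               # designated mature sub-intervals
    reads: List[MappedRead]
    spec: FixtureSpec


def _draw(rng: np.random.Generator, p: Sequence[float], size: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=size, p=np.asarray(p) / sum(p)))


def _degrade_arm2(
    arm2: str, arm1: str, spec: FixtureSpec, rng: np.random.Generator
) -> str:
    """Apply substitutions (mismatches) and single-base deletions (bulges)
    to the genomic 3' arm; length is restored by padding at the distal end."""
    l = spec.arm_length
    n_sub = int(round(spec.mutation_rate * l))
    n_del = int(round(spec.indel_rate * l))
    chars = list(arm2)
    if n_sub:
        positions = rng.choice(np.arange(2, l - 2), size=n_sub, replace=False)
        for pos in positions:
            # arm2[pos] pairs arm1[l-1-pos]; pick a base that cannot pair it
            partner = arm1[l - 1 - int(pos)]
            non_pairing = {
                "A": "AC", "C": "CAU", "G": "GA", "U": "UC",
            }[partner]
            chars[int(pos)] = non_pairing[rng.integers(len(non_pairing))]
    for _ in range(n_del):
        pos = int(rng.integers(2, len(chars) - 2))
        del chars[pos]
    while len(chars) < l:
        chars.append("ACGU"[rng.integers(4)])
    return "".join(chars)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the genome, truth intervals and read stacks for one spec."""
    rng = np.random.default_rng(spec.seed)
    L, hp_len = spec.genome_length, spec.hairpin_length
    margin = 100
    block = L // max(spec.n_hairpins, 1)
    if spec.n_hairpins and block < hp_len + 2 * margin:
        raise ValueError("genome too short to place the requested hairpins without overlap")

    genome = list(_draw(rng, spec.base_frequencies, L))
    gc = spec.arm_gc
    arm_p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    hairpins: List[ControlInterval] = []
    matures: List[ControlInterval] = []
    reads: List[MappedRead] = []
    for k in range(spec.n_hairpins):
        lo = k * block + margin
        hi = (k + 1) * block - margin - hp_len
        start = int(rng.integers(lo, hi + 1))
        arm1 = _draw(rng, arm_p, spec.arm_length)
        loop = _draw(rng, spec.base_frequencies, spec.loop_length)
        arm2 = _degrade_arm2(reverse_complement(arm1), arm1, spec, rng)
        planted = arm1 + loop + arm2
        genome[start : start + hp_len] = list(planted)
        end = start + hp_len
        hairpins.append(
            ControlInterval(spec.sequence_id, start, end, "+", name=f"hp{k}")
        )
        m0 = start + spec.mature_offset
        matures.append(
            ControlInterval(spec.sequence_id, m0, m0 + spec.mature_length, "+",
                            name=f"hp{k}-mir")
        )
        for r in range(spec.reads_per_arm):
            reads.append(MappedRead(spec.sequence_id, start, start + spec.read_length,
                                    "+", name=f"hp{k}-arm5-{r}"))
            reads.append(MappedRead(spec.sequence_id, end - spec.read_length, end,
                                    "+", name=f"hp{k}-arm3-{r}"))
        for r in range(spec.loop_spanning_reads):
            mid = start + hp_len // 2
            reads.append(
                MappedRead(spec.sequence_id, mid - spec.read_length // 2,
                           mid - spec.read_length // 2 + spec.read_length,
                           "+", name=f"hp{k}-loop-{r}")
            )

    return Fixture(
        genome={spec.sequence_id: "".join(genome)},
        hairpins=hairpins,
        matures=ControlSet(matures),
        reads=reads,
        spec=spec,
    )


def write_fixture(fixture: Fixture, outdir) -> Dict[str, str]:
    """Write genome.fa, truth_hairpins.bed, truth_matures.bed, reads.sam;
    returns the file paths."""
    from pathlib import Path

    from .io import write_fasta, write_sam

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "hairpins": str(outdir / "truth_hairpins.bed"),
        "matures": str(outdir / "truth_matures.bed"),
        "reads": str(outdir / "reads.sam"),
    }
    write_fasta(fixture.genome, paths["genome"])
    for key, intervals in (("hairpins", fixture.hairpins),
                           ("matures", fixture.matures.intervals)):
        with open(paths[key], "w") as fh:
            for c in intervals:
                fh.write(f"{c.sequence_id}\t{c.start}\t{c.end}\t{c.name}\t0\t{c.strand}\n")
    lengths = {name: len(seq) for name, seq in fixture.genome.items()}
    write_sam(fixture.reads, lengths, paths["reads"], sequences=fixture.genome)
    return paths
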