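"""Nearest-neighbour (NN) free-energy model for RNA stem-arm duplexes.

The stability of a hairpin stem is approximated as the sum of free-energy
increments of local structural motifs: stacked canonical base pairs
(helices), bulge loops, internal loops and dangling ends.  All increments
are tabulated at 37 C (T = 310.15 K) in kcal/mol and shipped as plain-text
TSV tables under ``hairpinscan/data``.

Canonical pairs are AU, UA, GC, CG and the GU/UG wobble.  An "RU" closure or
end is a terminal/closing pair in which a purine (A or G) pairs with U; such
pairs are penalized (0.7 kcal/mol when closing an internal loop, 0.45
kcal/mol at a helix or bulge end).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BASES",
    "CANONICAL_PAIRS",
    "RU_PAIRS",
    "ParameterLookupError",
    "MotifKind",
    "Motif",
    "NNParameterSet",
    "load_default_params",
    "internal_loop_energy",
    "bulge_energy",
    "long_loop_extension",
    "helix_energy",
    "dangling_end_energy",
    "motif_energy",
    "total_energy",
    "is_canonical",
    "encode_sequence",
]

# --------------------------------------------------------------------------
# Alphabet
# --------------------------------------------------------------------------

BASES = "ACGU"
#: integer codes: A=0 C=1 G=2 U=3, anything unknown/ambiguous = 4 (never pairs)
BASE_CODE: Dict[str, int] = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
AMBIGUOUS_CODE = 4

CANONICAL_PAIRS: Tuple[str, ...] = ("AU", "UA", "GC", "CG", "GU", "UG")
PAIR_INDEX: Dict[str, int] = {p: i for i, p in enumerate(CANONICAL_PAIRS)}
#: pairs in which a purine (R = A/G) is bound to U
RU_PAIRS = frozenset(CANONICAL_PAIRS) - {"GC", "CG"}

#: PAIR_CODE_TABLE[c1, c2] = canonical pair index, or -1 (codes 0..4)
PAIR_CODE_TABLE = np.full((5, 5), -1, dtype=np.int8)
for _p, _i in PAIR_INDEX.items():
    PAIR_CODE_TABLE[BASE_CODE[_p[0]], BASE_CODE[_p[1]]] = _i


def is_canonical(x: str, y: str) -> bool:
    """True when bases *x* (strand 1) and *y* (strand 2) form a canonical pair."""
    return (x + y) in PAIR_INDEX


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string into integer codes (unknown symbols -> 4)."""
    out = np.full(len(seq), AMBIGUOUS_CODE, dtype=np.int8)
    for base, code in BASE_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


class ParameterLookupError(KeyError):
    """A nucleotide or pair symbol has no entry in the NN tables."""


# --------------------------------------------------------------------------
# Parameter set
# --------------------------------------------------------------------------

_CAL_PER_KCAL_JOULE = 4184.0  # J per kcal


@dataclass(frozen=True)
class NNParameterSet:
    """All NN thermodynamic constants, energies in kcal/mol.

    ``stacking`` is indexed by two adjacent canonical pairs written
    strand1-base + strand2-base; it is invariant under duplex reversal.
    ``internal_init``/``bulge_init`` give the loop initiation term for
    1..30 unpaired nucleotides; longer loops use the logarithmic
    extrapolation of :func:`long_loop_extension`.
    """

    stacking: Dict[Tuple[str, str], float]
    internal_init: Dict[int, float]
    bulge_init: Dict[int, float]
    terminal_mismatch: Dict[Tuple[str, str, str], float]
    dangle: Dict[Tuple[str, str, str], float]  # (closing, base, side '5'/'3')
    asym_penalty: float = 0.6
    ru_closure: float = 0.7
    ru_end: float = 0.45
    c_bulge: float = -0.9
    sym_correction: float = 0.43
    gas_constant: float = 8.3144621  # J/(mol K)
    temperature: float = 310.15  # K
    long_loop_coeff: float = 1.75

    @property
    def rt(self) -> float:
        """R*T converted to kcal/mol."""
        return self.gas_constant * self.temperature / _CAL_PER_KCAL_JOULE

    # ---- dense views used by the alignment engine -----------------------

    def stacking_matrix(self) -> np.ndarray:
        """6x6 stacking table indexed by canonical-pair indices."""
        m = np.zeros((6, 6), dtype=np.float64)
        for (p1, p2), v in self.stacking.items():
            m[PAIR_INDEX[p1], PAIR_INDEX[p2]] = v
        return m

    def validate(self) -> None:
        for tab, name in ((self.internal_init, "internal"), (self.bulge_init, "bulge")):
            for n in range(1, 31):
                if n not in tab or not math.isfinite(tab[n]):
                    raise ValueError(f"{name} loop initiation missing/non-finite at n={n}")
            for n in range(3, 30):
                if tab[n + 1] < tab[n]:
                    raise ValueError(f"{name} initiation not non-decreasing at n={n}")
        rev = {"AU": "UA", "UA": "AU", "GC": "CG", "CG": "GC", "GU": "UG", "UG": "GU"}
        for (p1, p2), v in self.stacking.items():
            if self.stacking[(rev[p2], rev[p1])] != v:
                raise ValueError(f"stacking not reversal-symmetric at {p1}/{p2}")


def _read_tsv(name: str) -> List[List[str]]:
    text = resources.files("hairpinscan.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


@lru_cache(maxsize=1)
def load_default_params() -> NNParameterSet:
    """Load the bundled NN tables (cached)."""
    stacking = {
        (r[0], r[1]): float(r[2]) for r in _read_tsv("nn_stacking.tsv")
    }
    internal_init: Dict[int, float] = {}
    bulge_init: Dict[int, float] = {}
    for kind, n, dg in _read_tsv("nn_loop_init.tsv"):
        (internal_init if kind == "internal" else bulge_init)[int(n)] = float(dg)
    terminal_mismatch = {
        (r[0], r[1], r[2]): float(r[3]) for r in _read_tsv("nn_terminal_mismatch.tsv")
    }
    dangle = {
        (r[0], r[1], r[2]): float(r[3]) for r in _read_tsv("nn_dangle.tsv")
    }
    scalars = {r[0]: float(r[1]) for r in _read_tsv("nn_scalars.tsv")}
    params = NNParameterSet(
        stacking=stacking,
        internal_init=internal_init,
        bulge_init=bulge_init,
        terminal_mismatch=terminal_mismatch,
        dangle=dangle,
        asym_penalty=scalars["asym_penalty"],
        ru_closure=scalars["ru_closure"],
        ru_end=scalars["ru_end"],
        c_bulge=scalars["c_bulge"],
        sym_correction=scalars["sym_correction"],
        gas_constant=scalars["gas_constant"],
        temperature=scalars["temperature"],
        long_loop_coeff=scalars["long_loop_coeff"],
    )
    params.validate()
    return params


# --------------------------------------------------------------------------
# Motifs
# --------------------------------------------------------------------------


class MotifKind(Enum):
    HELIX = "helix"
    BULGE = "bulge"
    INTERNAL_LOOP = "internal_loop"
    DANGLE = "dangle"


@dataclass
class Motif:
    """A helix, bulge, internal loop or dangling end of a stem duplex.

    ``base_pairs`` holds the full ordered pair list for a HELIX, the
    (left, right) closing pairs for loops (either may be ``None`` at an
    open stem end), or the single closing pair of a DANGLE.  ``unpaired1``
    and ``unpaired2`` are the unpaired bases on strand 1 / strand 2 of a
    loop, in alignment order.
    """

    kind: MotifKind
    n1: int = 0
    n2: int = 0
    base_pairs: Tuple[Optional[Tuple[str, str]], ...] = ()
    unpaired1: str = ""
    unpaired2: str = ""
    t_conformations: int = 1
    side: Optional[str] = None  # DANGLE: '5' or '3'

    # -- convenience constructors -----------------------------------------

    @classmethod
    def helix(cls, pairs: Sequence[Tuple[str, str]]) -> "Motif":
        return cls(kind=MotifKind.HELIX, base_pairs=tuple(pairs))

    @classmethod
    def internal_loop(
        cls,
        unpaired1: str,
        unpaired2: str,
        left: Optional[Tuple[str, str]],
        right: Optional[Tuple[str, str]],
    ) -> "Motif":
        return cls(
            kind=MotifKind.INTERNAL_LOOP,
            n1=len(unpaired1),
            n2=len(unpaired2),
            base_pairs=(left, right),
            unpaired1=unpaired1,
            unpaired2=unpaired2,
        )

    @classmethod
    def bulge(
        cls,
        unpaired: str,
        strand: int,
        left: Optional[Tuple[str, str]],
        right: Optional[Tuple[str, str]],
        t_conformations: int = 1,
    ) -> "Motif":
        if strand == 1:
            u1, u2 = unpaired, ""
        else:
            u1, u2 = "", unpaired
        return cls(
            kind=MotifKind.BULGE,
            n1=len(u1),
            n2=len(u2),
            base_pairs=(left, right),
            unpaired1=u1,
            unpaired2=u2,
            t_conformations=t_conformations,
        )

    @classmethod
    def dangling_end(cls, closing: Tuple[str, str], base: str, side: str) -> "Motif":
        return cls(
            kind=MotifKind.DANGLE,
            base_pairs=(closing,),
            unpaired1=base,
            side=side,
        )


def _check_pair(pair: Tuple[str, str]) -> str:
    key = pair[0] + pair[1]
    if key not in PAIR_INDEX:
        raise ParameterLookupError(f"non-canonical base pair {key!r}")
    return key


def _closings(m: Motif) -> List[str]:
    """Closing pairs of a loop motif that are actually present."""
    return [_check_pair(p) for p in m.base_pairs if p is not None]


# --------------------------------------------------------------------------
# Motif energies
# --------------------------------------------------------------------------


def long_loop_extension(params: NNParameterSet, kind: str, n: int) -> float:
    """Jacobson-Stockmayer extrapolation for loops longer than 30 nt.

    dG = dG_i(30) + 1.75 * RT * ln(n/30).
    """
    if n <= 30:
        raise ValueError("long_loop_extension applies only for n > 30")
    if kind == "internal":
        base = params.internal_init[30]
    elif kind == "bulge":
        base = params.bulge_init[30]
    else:
        raise ValueError(f"unknown loop kind {kind!r}")
    return base + params.long_loop_coeff * params.rt * math.log(n / 30.0)


def internal_loop_energy(params: NNParameterSet, m: Motif) -> float:
    """dG of an internal loop: initiation + asymmetry + terminal mismatches
    + RU closure penalties."""
    if m.kind is not MotifKind.INTERNAL_LOOP:
        raise ValueError("motif is not an internal loop")
    if m.n1 < 1 or m.n2 < 1:
        raise ValueError("internal loop needs unpaired bases on both strands (bulge?)")
    for b in m.unpaired1 + m.unpaired2:
        if b not in BASES:
            raise ParameterLookupError(f"unknown nucleotide {b!r}")
    n = m.n1 + m.n2
    if n > 30:
        e = long_loop_extension(params, "internal", n)
    else:
        e = params.internal_init[n]
    e += params.asym_penalty * abs(m.n1 - m.n2)
    left, right = m.base_pairs if len(m.base_pairs) == 2 else (None, None)
    if left is not None:
        e += params.terminal_mismatch[(_check_pair(left), m.unpaired1[0], m.unpaired2[0])]
    if right is not None:
        e += params.terminal_mismatch[(_check_pair(right), m.unpaired1[-1], m.unpaired2[-1])]
    e += params.ru_closure * sum(1 for p in _closings(m) if p in RU_PAIRS)
    return e


def bulge_energy(params: NNParameterSet, m: Motif) -> float:
    """dG of a bulge loop.

    Single-nucleotide bulges keep the flanking stack and may gain the C-bulge
    bonus and an entropic -RT ln(t) term for t sequence-identical loop
    placements; longer bulges reduce to the initiation table.
    """
    if m.kind is not MotifKind.BULGE:
        raise ValueError("motif is not a bulge")
    if not ((m.n1 == 0) ^ (m.n2 == 0)):
        raise ValueError("bulge must have unpaired bases on exactly one strand")
    n = m.n1 + m.n2
    if n < 1:
        raise ValueError("empty bulge")
    if m.t_conformations < 1:
        raise ValueError("t_conformations must be >= 1")
    if n > 30:
        return long_loop_extension(params, "bulge", n)
    if n > 1:
        return params.bulge_init[n]

    e = params.bulge_init[1]
    bulged = (m.unpaired1 or m.unpaired2)[0]
    if bulged not in BASES:
        raise ParameterLookupError(f"unknown nucleotide {bulged!r}")
    left, right = m.base_pairs if len(m.base_pairs) == 2 else (None, None)
    if left is not None and right is not None:
        e += params.stacking[(_check_pair(left), _check_pair(right))]
        # C bulge: a bulged C next to a paired C
        strand = 0 if m.n1 else 1
        flanks = (left[strand], right[strand])
        if bulged == "C" and "C" in flanks:
            e += params.c_bulge
    e -= params.rt * math.log(m.t_conformations)
    e += params.ru_end * sum(1 for p in _closings(m) if p in RU_PAIRS)
    return e


def helix_energy(params: NNParameterSet, m: Motif) -> float:
    """dG of a helix: consecutive-pair stacking + self-complementary symmetry
    correction + 0.45 kcal/mol per AU/GU helix end."""
    if m.kind is not MotifKind.HELIX:
        raise ValueError("motif is not a helix")
    if not m.base_pairs:
        raise ValueError("helix needs at least one base pair")
    keys = [_check_pair(p) for p in m.base_pairs]
    e = 0.0
    for a, b in zip(keys, keys[1:]):
        e += params.stacking[(a, b)]
    strand1 = "".join(p[0] for p in m.base_pairs)
    strand2_5to3 = "".join(p[1] for p in reversed(m.base_pairs))
    if strand1 == strand2_5to3:
        e += params.sym_correction
    e += params.ru_end * sum(1 for p in (keys[0], keys[-1]) if p in RU_PAIRS)
    return e


def dangling_end_energy(
    params: NNParameterSet, closing_pair: Tuple[str, str], base: str, side: str
) -> float:
    """Lookup of a single dangling base stacked on a terminal pair."""
    if base not in BASES:
        raise ParameterLookupError(f"unknown nucleotide {base!r}")
    side = side.rstrip("'")
    if side not in ("5", "3"):
        raise ValueError("side must be 5' or 3'")
    return params.dangle[(_check_pair(closing_pair), base, side)]


def motif_energy(params: NNParameterSet, m: Motif) -> float:
    """Dispatch to the kind-specific energy function."""
    if m.kind is MotifKind.HELIX:
        return helix_energy(params, m)
    if m.kind is MotifKind.INTERNAL_LOOP:
        return internal_loop_energy(params, m)
    if m.kind is MotifKind.BULGE:
        return bulge_energy(params, m)
    if m.kind is MotifKind.DANGLE:
        return dangling_end_energy(params, m.base_pairs[0], m.unpaired1, m.side or "3")
    raise ValueError(f"unknown motif kind {m.kind!r}")


def total_energy(params: NNParameterSet, motifs: Sequence[Motif]) -> float:
    """Total free energy E of a stem decomposition (terminal loop unscored)."""
    if not motifs:
        warnings.warn("empty motif list: total energy is 0", stacklevel=2)
        return 0.0
    return sum(motif_energy(params, m) for m in motifs)
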