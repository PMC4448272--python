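"""Energy-threshold calibration and evaluation against control miRNAs.

Calibration follows the random-genome null: a genome with the same
nucleotide composition is drawn i.i.d. (multinomial per position), both the
original and the random genome are scanned, and the threshold is the
largest (least negative) energy at which the random genome still yields
zero "true" hits, a random-genome candidate counting as true only when its
locus coordinates (sequence, start, end, strand) equal those of a control
locus.

Evaluation uses interval containment: a prediction is a true positive when
one of its stem-arms fully covers a control (mature miRNA) interval on the
same strand; a prediction covering several controls is credited once, with
the pairing resolved in favour of the best (lowest-energy) prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .screen import HairpinCandidate

__all__ = [
    "ControlInterval",
    "ControlSet",
    "Metrics",
    "MatchResult",
    "random_genome",
    "calibrate_threshold",
    "match_predictions",
    "compute_metrics",
]


@dataclass(frozen=True)
class ControlInterval:
    """A true (mature) miRNA locus, 0-based half-open."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty control interval")


@dataclass
class ControlSet:
    intervals: List[ControlInterval]

    def __post_init__(self):
        names = [c.name for c in self.intervals if c.name]
        if len(names) != len(set(names)):
            raise ValueError("control identifiers must be unique")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class Metrics:
    """Confusion counts and the derived percentages (None when undefined)."""

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None
    sensitivity: Optional[float] = None
    precision: Optional[float] = None
    specificity: Optional[float] = None


@dataclass
class MatchResult:
    tp_pairs: List[Tuple[HairpinCandidate, ControlInterval]]
    fp: List[HairpinCandidate]
    fn: List[ControlInterval]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


def random_genome(
    base_frequencies: Union[Dict[str, float], Sequence[float]],
    length: int,
    seed: Union[int, np.random.Generator],
) -> str:
    """I.i.d. multinomial genome with the given A/C/G/U(T) composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if isinstance(base_frequencies, dict):
        freqs = {k.upper().replace("T", "U"): v for k, v in base_frequencies.items()}
        p = [freqs.get(b, 0.0) for b in "ACGU"]
    else:
        p = list(base_frequencies)
    if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
        raise ValueError("base frequencies must be 4 non-negative values summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGU"), size=length, p=np.asarray(p) / sum(p)))


def calibrate_threshold(
    real_predictions: Sequence[HairpinCandidate],
    random_predictions: Sequence[HairpinCandidate],
    controls: ControlSet,
    ceiling: float = 0.0,
) -> float:
    """Largest energy e with zero coordinate-matching random-genome hits.

    ``ceiling`` caps the returned threshold (and is returned outright, with
    a warning, when the random genome produced no candidate at all).
    ``real_predictions`` are accepted for interface completeness; the rule
    itself only consults the random genome and the control coordinates.
    """
    del real_predictions  # the rule is defined on the random genome only
    if not random_predictions:
        warnings.warn("no random-genome candidates; returning the ceiling", stacklevel=2)
        return ceiling
    keys = {(c.sequence_id, c.start, c.end, c.strand) for c in controls.intervals}
    hits = [
        c.energy
        for c in random_predictions
        if (c.sequence_id, c.start, c.end, c.strand) in keys
    ]
    if not hits:
        return ceiling
    return min(float(np.nextafter(min(hits), -np.inf)), ceiling)


def _arms(pred: HairpinCandidate) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    return pred.arm_intervals


def match_predictions(
    predictions: Sequence[HairpinCandidate], controls: ControlSet
) -> MatchResult:
    """Strand-aware TP/FP/FN assignment by arm containment of controls."""
    ranked = sorted(predictions, key=lambda c: (c.energy, c.start, c.n))
    credited: set = set()
    tp_pairs: List[Tuple[HairpinCandidate, ControlInterval]] = []
    fp: List[HairpinCandidate] = []
    for pred in ranked:
        arms = _arms(pred)
        hit = None
        for ctrl in controls.intervals:
            if id(ctrl) in credited:
                continue
            if ctrl.sequence_id != pred.sequence_id or ctrl.strand != pred.strand:
                continue
            if any(a <= ctrl.start and ctrl.end <= b for a, b in arms):
                hit = ctrl
                break
        if hit is not None:
            credited.add(id(hit))
            tp_pairs.append((pred, hit))
        else:
            fp.append(pred)
    fn = [c for c in controls.intervals if id(c) not in credited]
    return MatchResult(tp_pairs=tp_pairs, fp=fp, fn=fn)


def compute_metrics(
    assignments: Union[MatchResult, Tuple[int, int, int]],
    tn: Optional[int] = None,
) -> Metrics:
    """Sensitivity / precision / (optional) specificity as percentages.

    Zero-denominator ratios are reported as None (undefined), never as 0.
    """
    if isinstance(assignments, MatchResult):
        tp, fp, fn = assignments.tp, len(assignments.fp), len(assignments.fn)
    else:
        tp, fp, fn = assignments
    if min(tp, fp, fn) < 0 or (tn is not None and tn < 0):
        raise ValueError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    spec = None
    if tn is not None and tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn,
                   sensitivity=sens, precision=prec, specificity=spec)
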