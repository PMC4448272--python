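"""Readers and writers for the standard formats the pipeline touches.

FASTA through Biopython, SAM through pysam, BED/TSV through pandas.
Sequences are RNA (uppercase, U) in memory; FASTA output can echo a DNA
alphabet.  Genomic coordinates are 0-based half-open internally and
converted at the GFF3 boundary (1-based inclusive).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrate import ControlInterval, ControlSet
from .procin import MappedRead
from .screen import HairpinCandidate

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_bed",
    "controls_from_bed",
    "mask_intervals_from_bed",
    "write_candidates",
    "read_candidates_tsv",
]

PathLike = Union[str, Path]

TSV_COLUMNS = [
    "seq_id", "start", "end", "strand", "l", "n",
    "energy_kcal_mol", "dot_bracket", "alignment_string",
]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Multi-FASTA -> {id: RNA-uppercase sequence}; empty file -> {}."""
    path = Path(path)
    text_head = path.read_text()[:4096].lstrip()
    if text_head and not text_head.startswith(">"):
        bad_line = 1
        for k, line in enumerate(path.read_text().splitlines(), start=1):
            if line.strip():
                bad_line = k
                break
        raise ValueError(f"{path}: malformed FASTA (no '>' header at line {bad_line})")
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("T", "U")
    if not records:
        warnings.warn(f"{path}: empty FASTA", stacklevel=2)
    return records


def write_fasta(
    sequences: Mapping[str, str], path: PathLike, alphabet: str = "rna"
) -> None:
    """Write sequences; ``alphabet='dna'`` converts U back to T on output."""
    recs = []
    for name, seq in sequences.items():
        out = seq.upper()
        out = out.replace("U", "T") if alphabet == "dna" else out.replace("T", "U")
        recs.append(SeqRecord(Seq(out), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_sam(path: PathLike, include_secondary: bool = False) -> List[MappedRead]:
    """Mapped reads from a SAM file (unmapped and, by default,
    secondary/supplementary records are skipped).  The reference span is
    CIGAR-aware."""
    reads: List[MappedRead] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for idx, aln in enumerate(fh):
            try:
                if aln.is_unmapped:
                    continue
                if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                    continue
                reads.append(
                    MappedRead(
                        sequence_id=aln.reference_name,
                        start=aln.reference_start,
                        end=aln.reference_end,
                        strand="-" if aln.is_reverse else "+",
                        name=aln.query_name or f"read{idx}",
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed SAM record #{idx}: {exc}") from exc
    return reads


def write_sam(
    reads: Sequence[MappedRead],
    reference_lengths: Mapping[str, int],
    path: PathLike,
    sequences: Optional[Mapping[str, str]] = None,
) -> None:
    """Write reads as text SAM; read sequences are taken from the reference
    when ``sequences`` is provided."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in reference_lengths.items()],
    }
    ref_index = {n: k for k, n in enumerate(reference_lengths)}
    ordered = sorted(reads, key=lambda r: (ref_index[r.sequence_id], r.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for k, r in enumerate(ordered):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name or f"read{k}"
            a.reference_id = ref_index[r.sequence_id]
            a.reference_start = r.start
            a.flag = 16 if r.strand == "-" else 0
            span = r.end - r.start
            a.cigartuples = [(0, span)]
            a.mapping_quality = 255
            if sequences is not None:
                seq = sequences[r.sequence_id][r.start : r.end]
                a.query_sequence = seq.replace("U", "T")
            fh.write(a)


def read_bed(path: PathLike) -> pd.DataFrame:
    """BED3..BED6 -> DataFrame with columns seq_id/start/end[/name/score/strand]."""
    names = ["seq_id", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def controls_from_bed(path: PathLike) -> ControlSet:
    df = read_bed(path)
    intervals = []
    for k, row in df.iterrows():
        intervals.append(
            ControlInterval(
                sequence_id=str(row["seq_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row.get("strand", "+")) if "strand" in df.columns else "+",
                name=str(row["name"]) if "name" in df.columns else f"control{k}",
            )
        )
    return ControlSet(intervals)


def mask_intervals_from_bed(path: PathLike) -> Dict[str, List[tuple]]:
    df = read_bed(path)
    out: Dict[str, List[tuple]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["seq_id"]), []).append((int(row["start"]), int(row["end"])))
    return out


def write_candidates(
    candidates: Sequence[HairpinCandidate], path: PathLike, format: str = "gff3"
) -> None:
    """Serialize candidates as GFF3 (type pre_miRNA, score = energy) or TSV."""
    ordered = sorted(candidates, key=lambda c: (c.sequence_id, c.start, c.strand))
    path = Path(path)
    if format == "gff3":
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for k, c in enumerate(ordered):
                attrs = (
                    f"ID=hairpin{k};arm_length={c.l};loop_length={c.n};"
                    f"structure={c.structure}"
                )
                fh.write(
                    "\t".join(
                        [
                            c.sequence_id, "hairpinscan", "pre_miRNA",
                            str(c.start + 1), str(c.end), f"{c.energy:.2f}",
                            c.strand, ".", attrs,
                        ]
                    )
                    + "\n"
                )
    elif format == "tsv":
        rows = [
            {
                "seq_id": c.sequence_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "l": c.l,
                "n": c.n,
                "energy_kcal_mol": f"{c.energy:.2f}",
                "dot_bracket": c.structure,
                "alignment_string": c.alignment.alignment_string(),
            }
            for c in ordered
        ]
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(str(path), sep="\t", index=False)
    else:
        raise ValueError(f"unknown candidate format {format!r}")


def read_candidates_tsv(path: PathLike) -> List[HairpinCandidate]:
    """Reload TSV candidates (without alignment objects) for evaluation."""
    df = pd.read_csv(str(path), sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            HairpinCandidate(
                sequence_id=str(row["seq_id"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                l=int(row["l"]),
                n=int(row["n"]),
                alignment=None,
                energy=float(row["energy_kcal_mol"]),
                structure=str(row["dot_bracket"]),
            )
        )
    return out
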