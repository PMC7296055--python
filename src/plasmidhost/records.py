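"""Replicon sequences: reading, validation, segmentation and basic statistics.

A replicon (plasmid or chromosome) is held as a :class:`GenomeRecord`.
Chromosomes are cut into fixed, non-overlapping windows (default 5 kb) by
:func:`segment_sequence`; the trailing partial window is discarded, so a
580,076 bp chromosome yields exactly 116 five-kb segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "SegmentSet",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "segment_sequence",
    "gc_content",
    "read_metadata",
]

#: letters accepted after uppercasing (IUPAC nucleotide codes plus gap-free N)
_IUPAC = set("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


class FastaFormatError(ValueError):
    """Malformed FASTA input (empty file, bad header, duplicate id...)."""


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon sequence.

    Parameters
    ----------
    id : str
        Accession-like identifier, unique within a collection.
    sequence : str
        Nucleotide sequence, uppercased; IUPAC letters only.
    description : str
        Free-text description from the FASTA header.
    role : str
        ``"plasmid"`` or ``"chromosome"``.
    """

    id: str
    sequence: str
    description: str = ""
    role: str = "chromosome"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if self.role not in ("plasmid", "chromosome"):
            raise ValueError(f"{self.id}: role must be 'plasmid' or 'chromosome'")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(
                f"{self.id}: non-IUPAC letters in sequence: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)


@dataclass(frozen=True)
class SegmentSet:
    """Contiguous, non-overlapping, fixed-width windows of one replicon."""

    source_id: str
    window_bp: int
    segments: tuple
    n_dropped_tail_bp: int = 0

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def reassemble(self) -> str:
        """Concatenation of segments; the dropped tail is not recoverable."""
        return "".join(self.segments)


def _sanitize(raw: str, record_id: str) -> str:
    seq = raw.upper().replace(" ", "")
    bad = set(seq) - _IUPAC
    if bad:
        raise FastaFormatError(
            f"record {record_id!r}: illegal sequence letters {sorted(bad)!r}"
        )
    return seq


def read_fasta(path, role: str = "chromosome") -> List[GenomeRecord]:
    """Read a (multi-)FASTA file into a list of :class:`GenomeRecord`.

    Sequences are uppercased; record order is preserved; duplicate ids are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text_head = path.open().read(1)
    if text_head == "":
        raise FastaFormatError(f"{path}: empty FASTA file")
    if text_head != ">":
        raise FastaFormatError(f"{path}: line 1 does not start with '>'")
    records: List[GenomeRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _sanitize(str(rec.seq), rec.id)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(
            GenomeRecord(id=rec.id, sequence=seq, description=rec.description, role=role)
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_segments_fasta(segments: SegmentSet, path) -> None:
    """Debug output: one FASTA entry per segment, ids ``<source_id>|seg<i>``."""
    recs = [
        GenomeRecord(id=f"{segments.source_id}|seg{i}", sequence=s)
        for i, s in enumerate(segments.segments)
    ]
    write_fasta(recs, path)


def segment_sequence(record: GenomeRecord, window_bp: int = 5000) -> SegmentSet:
    """Cut a replicon into non-overlapping ``window_bp`` windows.

    The trailing partial window is discarded (its length is recorded in
    ``n_dropped_tail_bp``), matching floor(L / window) segment counts.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    seq = record.sequence
    n = len(seq) // window_bp
    segments = tuple(seq[i * window_bp : (i + 1) * window_bp] for i in range(n))
    return SegmentSet(
        source_id=record.id,
        window_bp=window_bp,
        segments=segments,
        n_dropped_tail_bp=len(seq) - n * window_bp,
    )


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases only.

    Ambiguous letters are excluded from both numerator and denominator.
    Raises ``ValueError`` when no unambiguous base exists.
    """
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("gc_content undefined: no unambiguous A/C/G/T bases")
    return 100.0 * gc / total


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


_METADATA_REQUIRED = ("accession", "genus")


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated genome metadata table.

    Requires at least ``accession`` and ``genus`` columns; optional columns:
    family, order, class, phylum, group, organism (for the
    largest-chromosome rule) and exclude (Candidatus / partial flags).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing required columns {missing}")
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise ValueError(f"metadata {path}: duplicate accessions {sorted(set(dup))}")
    return df.set_index("accession", drop=False)
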