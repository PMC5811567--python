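"""Sequence records and FASTA/FASTQ input/output.

All sequences inside the pipeline use the RNA alphabet {A, C, G, U}.
DNA input (T) is normalised to U on the way in; lower case is upper-cased.
File parsing and writing is delegated to Biopython's SeqIO.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_residues(residues: str) -> str:
    """Upper-case and convert T to U. Does not validate."""
    return residues.upper().replace("T", "U")


def is_clean(residues: str) -> bool:
    """True when every residue is in {A, C, G, U}."""
    return bool(residues) and set(residues) <= RNA_ALPHABET


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def gc_percent(residues: str) -> float:
    """G+C content on the 0-100 scale."""
    if not residues:
        return 0.0
    gc = sum(1 for r in residues if r in "GC")
    return 100.0 * gc / len(residues)


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence.

    residues are normalised (T->U, upper case) at construction but may still
    contain ambiguity codes such as N; downstream filters reject those and
    tally them as contaminants rather than erroring here.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        if not self.residues:
            raise ValueError(f"record {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


def _from_biopython(rec: SeqRecord) -> SequenceRecord:
    return SequenceRecord(id=rec.id, residues=str(rec.seq))


def read_fasta(source: str | Path | TextIO) -> list[SequenceRecord]:
    return [_from_biopython(r) for r in SeqIO.parse(source, "fasta")]


def read_fastq(source: str | Path | TextIO) -> list[SequenceRecord]:
    return [_from_biopython(r) for r in SeqIO.parse(source, "fastq")]


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first character."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            return read_fastq(fh)
        return read_fasta(fh)


def write_fasta(records: Iterable[SequenceRecord], target: str | Path | TextIO) -> None:
    recs = (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records)
    SeqIO.write(recs, target, "fasta")


def write_fastq(records: Iterable[SequenceRecord], target: str | Path | TextIO) -> None:
    """Write records as Phred+33 FASTQ with a uniform placeholder quality."""

    def _recs() -> Iterator[SeqRecord]:
        for r in records:
            rec = SeqRecord(Seq(r.residues), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.residues)
            yield rec

    SeqIO.write(_recs(), target, "fastq")


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
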