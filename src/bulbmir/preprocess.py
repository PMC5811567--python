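"""Small-RNA read preprocessing: adapter trimming, length filtering,
collapsing to unique tags and ncRNA contaminant removal.

The unit flowing out of this module is the :class:`TagLibrary`: collapsed
unique tags with per-library counts, length-bounded to the clean small-RNA
size range (18-30 nt by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .seqio import SequenceRecord, is_clean, normalize_residues

#: Fixed priority used to tally a contaminant that matches several classes.
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

#: Minimum 3' adapter prefix that must be seen at the read end to count as
#: adapter evidence when the full adapter is absent.
MIN_ADAPTER_OVERLAP = 8


@dataclass
class TrimTally:
    """Per-reason discard bookkeeping; reads_in = kept + sum of discards."""

    reads_in: int = 0
    kept: int = 0
    no_adapter: int = 0
    too_short: int = 0
    too_long: int = 0
    contaminant: int = 0  # ambiguous residues (e.g. N)

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "kept": self.kept,
            "no_adapter": self.no_adapter,
            "too_short": self.too_short,
            "too_long": self.too_long,
            "contaminant": self.contaminant,
        }


@dataclass
class TagLibrary:
    """Collapsed unique small-RNA tags with counts for one library."""

    library_name: str
    tags: dict[str, int] = field(default_factory=dict)
    bounds: tuple[int, int] = (18, 30)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        for seq, count in self.tags.items():
            if count < 1:
                raise ValueError(f"tag {seq} has count {count} < 1")
            if not lo <= len(seq) <= hi:
                raise ValueError(f"tag {seq} length outside bounds {self.bounds}")

    @property
    def total_reads(self) -> int:
        return sum(self.tags.values())

    @property
    def unique_reads(self) -> int:
        return len(self.tags)

    def count(self, seq: str) -> int:
        return self.tags.get(normalize_residues(seq), 0)


@dataclass
class AnnotationSet:
    """ncRNA reference records, each labelled with one contaminant class."""

    records: list[tuple[SequenceRecord, str]]

    def __post_init__(self) -> None:
        for _, label in self.records:
            if label not in NCRNA_CLASSES:
                raise ValueError(f"unknown ncRNA class {label!r}")

    @classmethod
    def from_labelled_fasta(cls, records: list[SequenceRecord]) -> "AnnotationSet":
        """Parse class labels embedded in FASTA headers as '...|rRNA'."""
        out = []
        for rec in records:
            label = rec.id.rsplit("|", 1)[-1]
            out.append((rec, label))
        return cls(out)


def _find_adapter(residues: str, adapter3: str) -> int | None:
    """Return the trim point (leftmost adapter start), or None.

    A full adapter occurrence anywhere wins; otherwise a >=8 nt prefix of the
    adapter flush with the read end counts as evidence.
    """
    pos = residues.find(adapter3)
    if pos != -1:
        return pos
    max_partial = min(len(adapter3) - 1, len(residues))
    for k in range(max_partial, MIN_ADAPTER_OVERLAP - 1, -1):
        if residues.endswith(adapter3[:k]):
            return len(residues) - k
    return None


def trim_and_filter(
    reads: list[SequenceRecord],
    adapter3: str,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[list[SequenceRecord], TrimTally]:
    """Trim the 3' adapter off each read and keep clean reads in the size range.

    The output read is the input prefix preceding the leftmost adapter
    occurrence. Reads without adapter evidence, reads containing ambiguous
    residues, and reads whose trimmed length falls outside [min_len, max_len]
    are discarded, with per-reason tallies.
    """
    adapter3 = normalize_residues(adapter3)
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")

    tally = TrimTally(reads_in=len(reads))
    kept: list[SequenceRecord] = []
    for rec in reads:
        pos = _find_adapter(rec.residues, adapter3)
        if pos is None:
            tally.no_adapter += 1
            continue
        insert = rec.residues[:pos]
        if insert and not is_clean(insert):
            tally.contaminant += 1
            continue
        if len(insert) < min_len:
            tally.too_short += 1
            continue
        if len(insert) > max_len:
            tally.too_long += 1
            continue
        kept.append(SequenceRecord(id=rec.id, residues=insert))
        tally.kept += 1
    return kept, tally


def collapse_tags(reads: list[SequenceRecord], library_name: str,
                  bounds: tuple[int, int] = (18, 30)) -> TagLibrary:
    """Collapse trimmed reads to unique tags; count = read multiplicity."""
    counts = Counter(rec.residues for rec in reads)
    return TagLibrary(library_name=library_name, tags=dict(counts), bounds=bounds)


def expand_tags(library: TagLibrary) -> list[str]:
    """Inverse of collapse_tags up to read order/ids (multiset of sequences)."""
    out: list[str] = []
    for seq, count in library.tags.items():
        out.extend([seq] * count)
    return out


def _matches_with_mismatches(tag: str, reference: str, max_mismatch: int) -> bool:
    """Ungapped substring alignment of tag against reference."""
    n, m = len(tag), len(reference)
    if n > m:
        return False
    if max_mismatch == 0:
        return tag in reference
    for start in range(m - n + 1):
        mism = 0
        window = reference[start:start + n]
        for a, b in zip(tag, window):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return True
    return False


def filter_annotated(
    tags: TagLibrary,
    annotation: AnnotationSet,
    max_mismatch: int = 0,
) -> tuple[TagLibrary, dict[str, int]]:
    """Remove tags that align ungapped inside any annotated ncRNA record.

    Removed read counts are tallied per class; a tag matching several classes
    is tallied once under the first class in the fixed order
    rRNA > tRNA > snRNA > snoRNA. Survivors form the "without annotation" pool.
    """
    if not annotation.records:
        raise ValueError("annotation set must be non-empty")
    by_class: dict[str, list[str]] = {c: [] for c in NCRNA_CLASSES}
    for rec, label in annotation.records:
        by_class[label].append(rec.residues)

    tally = {c: 0 for c in NCRNA_CLASSES}
    survivors: dict[str, int] = {}
    for seq, count in tags.tags.items():
        hit_class = None
        for cls in NCRNA_CLASSES:
            if any(_matches_with_mismatches(seq, ref, max_mismatch)
                   for ref in by_class[cls]):
                hit_class = cls
                break
        if hit_class is None:
            survivors[seq] = count
        else:
            tally[hit_class] += count
    filtered = TagLibrary(library_name=tags.library_name, tags=survivors,
                          bounds=tags.bounds)
    return filtered, tally


def length_distribution(tags: TagLibrary) -> pd.DataFrame:
    """Clean-read and unique-read counts per tag length across the bounds."""
    lo, hi = tags.bounds
    lengths = range(lo, hi + 1)
    clean = {n: 0 for n in lengths}
    unique = {n: 0 for n in lengths}
    for seq, count in tags.tags.items():
        clean[len(seq)] += count
        unique[len(seq)] += 1
    return pd.DataFrame(
        {"length": list(lengths),
         "clean_reads": [clean[n] for n in lengths],
         "unique_reads": [unique[n] for n in lengths]}
    ).set_index("length")


def tag_fasta_records(library: TagLibrary) -> list[SequenceRecord]:
    """Tags as FASTA-ready records with headers 'tag{serial}_x{count}'."""
    return [
        SequenceRecord(id=f"tag{i}_x{count}", residues=seq)
        for i, (seq, count) in enumerate(sorted(library.tags.items()), start=1)
    ]
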