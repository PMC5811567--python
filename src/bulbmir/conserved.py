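"""Conserved miRNA identification by homology to known mature miRNAs.

Filtered small-RNA tags are matched against a known mature set (miRBase-style
headers) within a mismatch budget, anchored on transcripts, and their
flanking windows folded; tags whose best window passes stem-loop validation
become conserved miRNA calls carrying the best-hit family.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .fold import PrecursorCandidate, amfe_mfei, fold_mfe, star_of, validate_stemloop
from .preprocess import TagLibrary
from .seqio import SequenceRecord, normalize_residues

logger = logging.getLogger(__name__)

#: overlap below which unequal-length comparison is meaningless
MIN_OVERLAP = 18

INFINITE_MISMATCH = 10**6

_NAME_RE = re.compile(r"^(?P<species>[a-z]{3,4})-miR(?P<family>\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class KnownMature:
    name: str
    family: str
    species: str
    residues: str


@dataclass
class KnownMatureSet:
    """Known mature miRNAs; family derived from the MIR-number convention."""

    entries: list[KnownMature]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("known mature names must be unique")

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "KnownMatureSet":
        """Parse headers of the form 'osa-miR156a' into (species, family)."""
        entries = []
        for rec in records:
            m = _NAME_RE.match(rec.id)
            if not m:
                raise ValueError(f"cannot parse miRNA name {rec.id!r}")
            entries.append(KnownMature(
                name=rec.id,
                family=f"MIR{int(m.group('family'))}",
                species=m.group("species"),
                residues=rec.residues,
            ))
        return cls(entries)


def family_number(family: str) -> int:
    m = re.search(r"(\d+)", family)
    return int(m.group(1)) if m else INFINITE_MISMATCH


@dataclass
class MiRNACall:
    """An accepted conserved or novel miRNA."""

    mature: str
    kind: str  # "conserved" | "novel"
    family: Optional[str]
    precursor: PrecursorCandidate
    counts: dict[str, int]
    star_supported: bool
    name: str = ""
    extra_precursors: list[PrecursorCandidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("conserved", "novel"):
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.kind == "conserved" and not self.family:
            raise ValueError("conserved calls must carry a family")
        if self.precursor.mature_sequence != self.mature:
            raise ValueError("mature does not match the precursor mature interval")

    @property
    def five_prime(self) -> str:
        return self.mature[0]


def mismatch_count(a: str, b: str) -> int:
    """Mismatch distance between two mature-length sequences.

    Equal lengths: Hamming distance. Unequal lengths: minimum over ungapped
    offsets of (mismatches on the overlap + length difference); overlaps
    shorter than 18 nt are not considered (effectively infinite distance).
    """
    a = normalize_residues(a)
    b = normalize_residues(b)
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    if len(a) > len(b):
        a, b = b, a
    short, long_ = a, b
    diff = len(long_) - len(short)
    if len(short) < MIN_OVERLAP:
        return INFINITE_MISMATCH
    best = INFINITE_MISMATCH
    for off in range(diff + 1):
        mism = sum(x != y for x, y in zip(short, long_[off:off + len(short)]))
        best = min(best, mism + diff)
    return best


@dataclass(frozen=True)
class HomologyHit:
    tag: str
    known_name: str
    family: str
    mismatches: int


def match_known(
    tags: TagLibrary,
    known: KnownMatureSet,
    max_mismatch: int = 2,
) -> list[HomologyHit]:
    """All (tag, known mature) pairs within the mismatch budget.

    Each tag additionally gets a best-hit family: minimum mismatches, ties
    broken by the lowest MIR family number.
    """
    if not known.entries:
        raise ValueError("known mature set must be non-empty")
    hits: list[HomologyHit] = []
    for seq in tags.tags:
        for entry in known.entries:
            d = mismatch_count(seq, entry.residues)
            if d <= max_mismatch:
                hits.append(HomologyHit(
                    tag=seq, known_name=entry.name,
                    family=entry.family, mismatches=d,
                ))
    return hits


def best_family(hits: list[HomologyHit]) -> dict[str, str]:
    """Best-hit family per tag: fewest mismatches, then lowest MIR number."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.tag)
        if cur is None or (h.mismatches, family_number(h.family)) < (
            cur.mismatches, family_number(cur.family)
        ):
            best[h.tag] = h
    return {tag: h.family for tag, h in best.items()}


def excise_windows(
    tag: str,
    transcript: SequenceRecord,
    position: int,
    flank: int = 250,
) -> list[PrecursorCandidate]:
    """Fold the windows around one exact tag occurrence.

    Window schedule: symmetric tag+/-flank, plus asymmetric downstream-only
    and upstream-only windows, all clipped to the transcript bounds. Each
    window is folded and annotated with its mature interval, AMFE and MFEI.
    """
    n = len(transcript.residues)
    tag_end = position + len(tag)
    schedule = [
        (position - flank, tag_end + flank),
        (position, tag_end + flank),
        (position - flank, tag_end),
    ]
    seen: set[tuple[int, int]] = set()
    out: list[PrecursorCandidate] = []
    for w0, w1 in schedule:
        w0, w1 = max(0, w0), min(n, w1)
        if (w0, w1) in seen:
            continue
        seen.add((w0, w1))
        window_seq = transcript.residues[w0:w1]
        if len(window_seq) < 2 * len(tag):  # cannot host a duplex
            continue
        fold = fold_mfe(window_seq)
        mature = (position - w0, tag_end - w0)
        amfe, mfei, gc = amfe_mfei(fold)
        out.append(PrecursorCandidate(
            source_id=transcript.id,
            window=(w0, w1),
            fold=fold,
            mature=mature,
            star=star_of(fold, mature),
            amfe=amfe,
            mfei=mfei,
            gc_percent=gc,
        ))
    return out


def locate_and_excise(
    hit_tag: str,
    transcripts: list[SequenceRecord],
    flank: int = 250,
    both_strands: bool = False,
) -> list[PrecursorCandidate]:
    """Find every exact occurrence of a tag and excise folded windows."""
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    tag = normalize_residues(hit_tag)
    from .seqio import reverse_complement

    queries = [tag]
    if both_strands:
        queries.append(reverse_complement(tag))
    out: list[PrecursorCandidate] = []
    for rec in transcripts:
        for q in queries:
            start = rec.residues.find(q)
            while start != -1:
                out.extend(excise_windows(q, rec, start, flank=flank))
                start = rec.residues.find(q, start + 1)
    if not out:
        logger.info("tag %s absent from all transcripts", tag)
    return out


def _star_supported(candidate: PrecursorCandidate,
                    libraries: list[TagLibrary]) -> bool:
    """True when some sequenced tag sits within +/-2 nt of the star interval."""
    if candidate.star is None:
        return False
    s0, s1 = candidate.star
    w0, _ = candidate.window
    seq = candidate.fold.sequence
    for lib in libraries:
        for tag in lib.tags:
            start = seq.find(tag)
            while start != -1:
                if abs(start - s0) <= 2 and abs(start + len(tag) - s1) <= 2:
                    return True
                start = seq.find(tag, start + 1)
    return False


def call_conserved(
    candidates_by_tag: dict[str, list[PrecursorCandidate]],
    hits: list[HomologyHit],
    libraries: list[TagLibrary],
    max_mature_unpaired: int = 8,
) -> list[MiRNACall]:
    """Emit a conserved call per homology-supported tag with a valid hairpin.

    Among accepted windows the lowest-MFEI one is kept; star support is
    granted when any library tag lies within +/-2 nt of the computed star.
    """
    families = best_family(hits)
    calls: list[MiRNACall] = []
    for tag, family in sorted(families.items()):
        accepted = []
        for cand in candidates_by_tag.get(tag, []):
            ok, _ = validate_stemloop(cand, max_mature_unpaired=max_mature_unpaired)
            if ok:
                accepted.append(cand)
        if not accepted:
            logger.info("homology hit %s: no window passed stem-loop validation", tag)
            continue
        best = min(accepted,
                   key=lambda c: c.mfei if c.mfei is not None else 0.0)
        counts = {lib.library_name: lib.count(tag) for lib in libraries}
        calls.append(MiRNACall(
            mature=tag,
            kind="conserved",
            family=family,
            precursor=best,
            counts=counts,
            star_supported=_star_supported(best, libraries),
        ))
    return calls


def summarize_families(calls: list[MiRNACall]) -> tuple[pd.DataFrame, float]:
    """Family table plus the overall fraction of calls starting with U.

    Columns: members, precursors, per-library read totals and the count of
    members whose mature begins with U.
    """
    if not calls:
        return pd.DataFrame(), float("nan")
    rows = []
    for call in calls:
        row = {
            "family": call.family or "",
            "mature": call.mature,
            "precursor": call.precursor.source_id,
            "five_prime_u": call.five_prime == "U",
        }
        row.update(call.counts)
        rows.append(row)
    df = pd.DataFrame(rows)
    count_cols = [c for c in df.columns
                  if c not in ("family", "mature", "precursor", "five_prime_u")]
    agg = {"mature": "count", "precursor": pd.Series.nunique,
           "five_prime_u": "sum"}
    agg.update({c: "sum" for c in count_cols})
    table = df.groupby("family").agg(agg).rename(
        columns={"mature": "members", "precursor": "precursors",
                 "five_prime_u": "five_prime_u_members"})
    u_fraction = sum(c.five_prime == "U" for c in calls) / len(calls)
    return table, u_fraction


def calls_table(calls: list[MiRNACall]) -> pd.DataFrame:
    """Calls as a report table (family, name, precursor, sequence, counts)."""
    rows = []
    for call in calls:
        row = {
            "family": call.family or "",
            "name": call.name or call.mature[:12],
            "precursor_id": call.precursor.source_id,
            "sequence": call.mature,
            "length": len(call.mature),
            "mfei": call.precursor.mfei,
            "star_supported": call.star_supported,
        }
        row.update(call.counts)
        rows.append(row)
    return pd.DataFrame(rows)
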