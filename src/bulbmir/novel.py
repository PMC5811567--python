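"""Novel miRNA calling from unannotated tags.

Rule-based discovery: transcript-anchored read loci are excised and folded,
and a locus is called when its dominant tag sits on a valid stem-loop and
the locus read stack is Dicer-consistent (5' ends concentrated at the
dominant 5' end or falling in the star/loop regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .conserved import MiRNACall, excise_windows
from .fold import PrecursorCandidate, validate_stemloop
from .preprocess import TagLibrary
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

MERGE_DISTANCE = 30  # loci closer than this on one transcript are merged


@dataclass
class Locus:
    """A cluster of exact-match tag placements on one transcript."""

    transcript_id: str
    start: int
    end: int
    members: list[tuple[str, int, int]] = field(default_factory=list)
    # members: (tag sequence, position, count)

    @property
    def total_count(self) -> int:
        return sum(c for _, _, c in self.members)

    @property
    def dominant(self) -> tuple[str, int, int]:
        """Highest-count member tag; position breaks ties deterministically."""
        return max(self.members, key=lambda m: (m[2], -m[1], m[0]))


def candidate_loci(
    tags: TagLibrary,
    transcripts: list[SequenceRecord],
    min_count: int = 3,
) -> list[Locus]:
    """Exact-match loci of the unannotated tag pool.

    Placements within MERGE_DISTANCE nt on the same transcript are merged;
    loci below min_count total reads are dropped.
    """
    placements: dict[str, list[tuple[int, str, int]]] = {}
    for seq, count in tags.tags.items():
        for rec in transcripts:
            start = rec.residues.find(seq)
            while start != -1:
                placements.setdefault(rec.id, []).append((start, seq, count))
                start = rec.residues.find(seq, start + 1)

    loci: list[Locus] = []
    for tid, hits in placements.items():
        hits.sort()
        current: Locus | None = None
        for pos, seq, count in hits:
            end = pos + len(seq)
            if current is not None and pos - current.end < MERGE_DISTANCE:
                current.members.append((seq, pos, count))
                current.end = max(current.end, end)
            else:
                current = Locus(transcript_id=tid, start=pos, end=end,
                                members=[(seq, pos, count)])
                loci.append(current)
    return [l for l in loci if l.total_count >= min_count]


def _read_consistency(locus: Locus, candidate: PrecursorCandidate) -> float:
    """Fraction of locus reads with 5' ends near the dominant 5' end or in
    the star/loop regions of the candidate fold."""
    dom_seq, dom_pos, _ = locus.dominant
    w0, w1 = candidate.window
    star = candidate.star
    m0, m1 = candidate.mature
    # loop region between mature and star (window coordinates)
    if star is not None:
        lo = min(m1, star[1])
        hi = max(m0, star[0])
        loop_region = (lo, hi)
    else:
        loop_region = None
    good = 0
    total = 0
    for seq, pos, count in locus.members:
        total += count
        five_prime = pos  # transcript coordinate of the read 5' end
        if abs(five_prime - dom_pos) <= 2:
            good += count
            continue
        wpos = five_prime - w0
        if star is not None and star[0] - 2 <= wpos <= star[1] + 2:
            good += count
            continue
        if loop_region and loop_region[0] <= wpos < loop_region[1]:
            good += count
    return good / total if total else 0.0


def call_novel(
    loci: list[Locus],
    transcripts: list[SequenceRecord],
    libraries: list[TagLibrary],
    read_consistency: float = 0.75,
    flank: int = 250,
    max_mature_unpaired: int = 8,
    keep_duplicates: bool = False,
) -> list[MiRNACall]:
    """Call novel miRNAs from candidate loci.

    A locus is called when some excised window around the dominant tag passes
    stem-loop validation and the locus read stack is consistent (fraction of
    reads with 5' ends within +/-2 nt of the dominant 5' end, or inside the
    star/loop regions, at least `read_consistency`). Calls sharing a mature
    sequence are deduplicated to the lowest-MFEI precursor unless
    keep_duplicates is set; the other loci are kept as extra precursors.
    """
    by_id = {rec.id: rec for rec in transcripts}
    calls: list[MiRNACall] = []
    for locus in sorted(loci, key=lambda l: (l.transcript_id, l.start)):
        dom_seq, dom_pos, _ = locus.dominant
        rec = by_id[locus.transcript_id]
        accepted = []
        for cand in excise_windows(dom_seq, rec, dom_pos, flank=flank):
            ok, _ = validate_stemloop(cand, max_mature_unpaired=max_mature_unpaired)
            if ok and _read_consistency(locus, cand) >= read_consistency:
                accepted.append(cand)
        if not accepted:
            logger.info("locus %s:%d rejected", locus.transcript_id, locus.start)
            continue
        best = min(accepted,
                   key=lambda c: c.mfei if c.mfei is not None else 0.0)
        counts = {lib.library_name: lib.count(dom_seq) for lib in libraries}
        from .conserved import _star_supported

        calls.append(MiRNACall(
            mature=dom_seq,
            kind="novel",
            family=None,
            precursor=best,
            counts=counts,
            star_supported=_star_supported(best, libraries),
        ))

    if keep_duplicates:
        return calls
    deduped: dict[str, MiRNACall] = {}
    for call in calls:
        prev = deduped.get(call.mature)
        if prev is None:
            deduped[call.mature] = call
            continue
        key = lambda c: c.precursor.mfei if c.precursor.mfei is not None else 0.0
        keep, drop = (call, prev) if key(call) < key(prev) else (prev, call)
        keep.extra_precursors = prev.extra_precursors + [drop.precursor]
        deduped[call.mature] = keep
    return list(deduped.values())


def composition_stats(matures: list[str]) -> dict:
    """5'-nucleotide and length composition of a set of mature sequences.

    Accepts raw mature sequences (or MiRNACalls via their .mature attribute
    upstream). Returns the 5'-U fraction, length extremes and a histogram;
    fractions are None for an empty set.
    """
    seqs = [m.mature if hasattr(m, "mature") else m for m in matures]
    if not seqs:
        return {"five_prime_u_fraction": None, "length_min": None,
                "length_max": None, "length_histogram": {}}
    lengths = [len(s) for s in seqs]
    hist: dict[int, int] = {}
    for n in lengths:
        hist[n] = hist.get(n, 0) + 1
    return {
        "five_prime_u_fraction": sum(s[0] == "U" for s in seqs) / len(seqs),
        "length_min": min(lengths),
        "length_max": max(lengths),
        "length_histogram": dict(sorted(hist.items())),
    }
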