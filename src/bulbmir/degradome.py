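"""Degradome (PARE) analysis: 5'-end profiles, cleavage-site calling
opposite miRNA positions 10-11, and 5-category classification.

Categories rank a site's tag abundance against the whole transcript's
degradome signal: 0 unique maximum, 1 tied maximum, 2 above the median of
expressed positions but below the maximum, 3 above one read but at most the
median, 4 a single read. Multi-mapping tags split their counts equally, so
counts may be fractional; a split count <= 1 still classifies as category 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

import pandas as pd

from .preprocess import TagLibrary
from .seqio import SequenceRecord
from .targets import TargetAlignment

logger = logging.getLogger(__name__)

#: the slicing position: transcript nucleotide paired to miRNA position 10
CLEAVAGE_MIRNA_POSITION = 10


@dataclass
class DegradomeProfile:
    """Position-indexed degradome tag 5'-end counts for one transcript."""

    transcript_id: str
    counts: dict[int, float]

    def total(self) -> float:
        return sum(self.counts.values())

    def maximum(self) -> float:
        return max(self.counts.values()) if self.counts else 0.0

    def expressed_median(self) -> float:
        """Median count over positions with signal (count > 0)."""
        positive = [c for c in self.counts.values() if c > 0]
        if not positive:
            raise ValueError("profile has no expressed positions")
        return float(median(positive))


@dataclass
class CleavageSite:
    """A degradome-supported slice position with its category and context."""

    mirna: str
    transcript_id: str
    position: int  # 0-based 5' nucleotide of the 3' cleavage fragment
    site_count: float
    category: int
    alignment: TargetAlignment


def build_profile(
    tags: TagLibrary,
    transcripts: list[SequenceRecord],
) -> tuple[dict[str, DegradomeProfile], float]:
    """Map degradome tags exactly and accumulate 5'-end counts.

    A tag occurring at several positions (across all transcripts) splits its
    count equally over the occurrences. Returns profiles keyed by transcript
    id plus the unmapped read tally; mapped + unmapped equals the input total.
    """
    profiles: dict[str, dict[int, float]] = {}
    unmapped = 0.0
    for seq, count in tags.tags.items():
        occurrences: list[tuple[str, int]] = []
        for rec in transcripts:
            start = rec.residues.find(seq)
            while start != -1:
                occurrences.append((rec.id, start))
                start = rec.residues.find(seq, start + 1)
        if not occurrences:
            unmapped += count
            continue
        share = count / len(occurrences)
        for tid, pos in occurrences:
            prof = profiles.setdefault(tid, {})
            prof[pos] = prof.get(pos, 0.0) + share
    return (
        {tid: DegradomeProfile(transcript_id=tid, counts=c)
         for tid, c in profiles.items()},
        unmapped,
    )


def categorize_site(profile: DegradomeProfile, position: int) -> int:
    """Classify one expressed position into category 0-4.

    With c the count at the position, M the transcript maximum and med the
    median over expressed positions: category 4 iff c <= 1; else 0 iff c = M
    attained uniquely; 1 iff c = M attained at several positions; 2 iff
    med < c < M; 3 iff 1 < c <= med.
    """
    c = profile.counts.get(position, 0.0)
    if c <= 0:
        raise ValueError(f"not a site: position {position} has no signal")
    if c <= 1:
        return 4
    m = profile.maximum()
    med = profile.expressed_median()
    if c == m:
        n_max = sum(1 for v in profile.counts.values() if v == m)
        return 0 if n_max == 1 else 1
    if med < c < m:
        return 2
    return 3  # 1 < c <= med


def _expected_position(alignment: TargetAlignment) -> int:
    """Transcript coordinate paired to miRNA position 10.

    The transcript is consumed 3'->5' from the site end, one nucleotide per
    column that is not a target gap. Which strand carries a gap column is
    recovered by comparing site length with miRNA length.
    """
    s0, s1 = alignment.site
    site_len = s1 - s0
    L = len(alignment.mirna)
    p = CLEAVAGE_MIRNA_POSITION
    if p > L:
        raise ValueError("miRNA shorter than the cleavage position")
    if site_len == L - 1:  # single gap in the target strand
        gap_col = alignment.pairing.index("-")
        col = p - 1  # miRNA numbering is unchanged by a target gap
        consumed = col + 1 - (1 if gap_col <= col else 0)
    else:
        if site_len == L + 1:  # single gap in the miRNA strand
            gap_col = alignment.pairing.index("-")
            col = p - 1 if p - 1 < gap_col else p
        else:  # gapless
            col = p - 1
        consumed = col + 1  # every column consumes one transcript nucleotide
    return s1 - consumed


def call_cleavage_sites(
    alignments: list[TargetAlignment],
    profiles: dict[str, DegradomeProfile],
    min_count: float = 1.0,
    window: int = 1,
) -> list[CleavageSite]:
    """Call a cleavage site per alignment when degradome signal supports it.

    The expected position is the target nucleotide paired to miRNA position
    10; signal within +/-window of it at or above min_count calls a site at
    the maximal position in the window.
    """
    sites: list[CleavageSite] = []
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            logger.info("transcript %s has no degradome profile; skipped",
                        aln.transcript_id)
            continue
        expected = _expected_position(aln)
        in_window = {
            pos: c for pos, c in profile.counts.items()
            if abs(pos - expected) <= window and c > 0
        }
        if not in_window:
            continue
        pos, count = max(in_window.items(), key=lambda kv: (kv[1], -kv[0]))
        if count < min_count:
            continue
        sites.append(CleavageSite(
            mirna=aln.mirna,
            transcript_id=aln.transcript_id,
            position=pos,
            site_count=count,
            category=categorize_site(profile, pos),
            alignment=aln,
        ))
    return sites


def tplot_table(
    profile: DegradomeProfile,
    sites: list[CleavageSite],
) -> pd.DataFrame:
    """Per-position signal table with called-site annotations (T-plot data)."""
    called = {s.position: s.category for s in sites
              if s.transcript_id == profile.transcript_id}
    rows = [
        {"position": pos, "count": count,
         "is_called_site": pos in called,
         "category": called.get(pos, pd.NA)}
        for pos, count in sorted(profile.counts.items())
        if count > 0
    ]
    return pd.DataFrame(rows, columns=["position", "count",
                                       "is_called_site", "category"])
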