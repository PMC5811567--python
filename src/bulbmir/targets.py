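"""Plant-style miRNA target prediction.

Complementarity between a miRNA and a transcript site is scored with a
position-weighted penalty scheme (Allen-style): per alignment column from
the miRNA 5' end, match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, with
columns 2-13 doubled. Sites are found by an exact-complement 7-mer seed
over miRNA positions 2-8 followed by banded extension allowing at most one
gap outside the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SequenceRecord, normalize_residues, reverse_complement

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

#: alignment columns (1-based from the miRNA 5' end) with doubled weight
CORE_COLUMNS = range(2, 14)

#: seed: miRNA positions 2-8 must be exactly Watson-Crick complementary
SEED_START, SEED_END = 2, 8

DEFAULT_MAX_PENALTY = 4.0


@dataclass(frozen=True)
class TargetAlignment:
    """A scored miRNA/transcript duplex.

    site is 0-based half-open on the transcript; the pairing string runs
    from the miRNA 5' end ('|' match, 'o' G:U, 'x' mismatch, '-' gap).
    """

    mirna: str
    transcript_id: str
    site: tuple[int, int]
    pairing: str
    penalty: float


def _column_penalty(m: str, t: str, column: int) -> tuple[float, str]:
    """Penalty and pairing symbol for one alignment column (1-based)."""
    if m == "-" and t == "-":
        raise ValueError("gap aligned to gap")
    if m == "-" or t == "-":
        base, sym = 2.0, "-"
    elif (m, t) in _WC:
        base, sym = 0.0, "|"
    elif (m, t) in _WOBBLE:
        base, sym = 0.5, "o"
    else:
        base, sym = 1.0, "x"
    if column in CORE_COLUMNS:
        base *= 2.0
    return base, sym


def score_duplex(mirna: str, target_site: str) -> tuple[float, str]:
    """Score an aligned miRNA/target pair.

    Both strings may contain '-' gaps and must be equal length; the target
    site is given 3'->5' so that column i pairs miRNA column i.
    """
    mirna = normalize_residues(mirna)
    target_site = normalize_residues(target_site)
    if len(mirna) != len(target_site):
        raise ValueError("aligned strings must have equal length")
    penalty = 0.0
    pairing = []
    for col, (m, t) in enumerate(zip(mirna, target_site), start=1):
        p, sym = _column_penalty(m, t, col)
        penalty += p
        pairing.append(sym)
    return penalty, "".join(pairing)


def _alignments_at(mirna: str, transcript: str, s1: int):
    """Candidate alignments whose duplex 3' end sits at transcript position s1.

    Yields (penalty, pairing, s0): the gapless alignment plus every placement
    of a single gap (in either strand) outside the seed columns. Transcript
    nucleotides are consumed 3'->5' from s1-1 downward.
    """
    L = len(mirna)

    def t_at(k: int) -> str | None:
        pos = s1 - 1 - k
        return transcript[pos] if 0 <= pos < len(transcript) else None

    # gapless
    cols = [(mirna[i], t_at(i)) for i in range(L)]
    if all(t is not None for _, t in cols):
        pen, pairing = _score_cols(cols)
        yield pen, pairing, s1 - L
    # one gap in the target (miRNA nucleotide bulged out); gaps are only
    # permitted 3' of the seed so the seed anchoring stays fixed
    for g in range(SEED_END, L):
        cols = []
        shift = 0
        for i in range(L):
            if i == g:
                cols.append((mirna[i], "-"))
                shift = 1
            else:
                cols.append((mirna[i], t_at(i - shift)))
        if all(t is not None for _, t in cols):
            pen, pairing = _score_cols(cols)
            yield pen, pairing, s1 - (L - 1)
    # one gap in the miRNA (target nucleotide bulged out), 3' of the seed
    for g in range(SEED_END, L + 1):
        cols = []
        used = 0
        for col in range(L + 1):
            if col == g:
                cols.append(("-", t_at(used)))
                used += 1
            else:
                cols.append((mirna[col - (1 if col > g else 0)], t_at(used)))
                used += 1
        if all(t is not None for _, t in cols):
            pen, pairing = _score_cols(cols)
            yield pen, pairing, s1 - (L + 1)


def _score_cols(cols) -> tuple[float, str]:
    penalty = 0.0
    pairing = []
    for col, (m, t) in enumerate(cols, start=1):
        p, sym = _column_penalty(m, t, col)
        penalty += p
        pairing.append(sym)
    return penalty, "".join(pairing)


def _seed_ok(mirna: str, transcript: str, s1: int) -> bool:
    for k in range(SEED_START - 1, SEED_END):
        pos = s1 - 1 - k
        if pos < 0 or pos >= len(transcript):
            return False
        if (mirna[k], transcript[pos]) not in _WC:
            return False
    return True


def sites_for_end(mirna: str, transcript: str, s1: int,
                  max_penalty: float) -> list[tuple[float, str, int]]:
    """Best alignment(s) with duplex 3' end at s1, provided the seed matches."""
    if not _seed_ok(mirna, transcript, s1):
        return []
    out = [a for a in _alignments_at(mirna, transcript, s1)
           if a[0] <= max_penalty]
    return out


def scan_targets(
    mirnas,
    transcripts: list[SequenceRecord],
    max_penalty: float = DEFAULT_MAX_PENALTY,
) -> list[TargetAlignment]:
    """All target sites at penalty <= max_penalty for each miRNA.

    Seeded scan: transcript occurrences of the exact complement of miRNA
    positions 2-8 anchor the duplex; banded extension tries the gapless
    alignment and every single-gap variant. Overlapping sites of one miRNA
    on one transcript are merged to the best-scoring (ties: leftmost).
    """
    results: list[TargetAlignment] = []
    for mirna_obj in mirnas:
        mirna = normalize_residues(
            mirna_obj.mature if hasattr(mirna_obj, "mature") else mirna_obj
        )
        seed_rc = reverse_complement(mirna[SEED_START - 1:SEED_END])
        per_transcript: list[TargetAlignment] = []
        for rec in transcripts:
            seq = rec.residues
            found: list[TargetAlignment] = []
            p = seq.find(seed_rc)
            while p != -1:
                s1 = p + (SEED_END - SEED_START + 1) + (SEED_START - 1)
                for pen, pairing, s0 in sites_for_end(mirna, seq, s1, max_penalty):
                    if s0 >= 0:
                        found.append(TargetAlignment(
                            mirna=mirna, transcript_id=rec.id,
                            site=(s0, s1), pairing=pairing, penalty=pen))
                p = seq.find(seed_rc, p + 1)
            per_transcript.extend(_merge_overlaps(found))
        per_transcript.sort(key=lambda a: (a.penalty, a.transcript_id, a.site))
        results.extend(per_transcript)
    return results


def _merge_overlaps(sites: list[TargetAlignment]) -> list[TargetAlignment]:
    """Keep the best-scoring site among mutually overlapping ones."""
    kept: list[TargetAlignment] = []
    for site in sorted(sites, key=lambda a: (a.penalty, a.site)):
        if all(site.site[1] <= k.site[0] or site.site[0] >= k.site[1]
               for k in kept):
            kept.append(site)
    return sorted(kept, key=lambda a: a.site)
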