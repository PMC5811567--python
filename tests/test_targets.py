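"""Position-weighted duplex scoring and seeded target scanning."""

import numpy as np
import pytest

from bulbmir.seqio import SequenceRecord, reverse_complement
from bulbmir.targets import (SEED_END, SEED_START, scan_targets, score_duplex,
                             sites_for_end)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def complement35(mirna: str) -> str:
    """Exact complement, 3'->5' (column-aligned with the miRNA)."""
    return "".join(_COMP[c] for c in mirna)


class TestScoreDuplex:
    def test_perfect_complement_is_zero(self):
        m = "UGACAGAAGAGAGUGAGCACA"
        penalty, pairing = score_duplex(m, complement35(m))
        assert penalty == 0.0 and pairing == "|" * 21

    def test_wobble_weight_depends_on_position(self):
        m = "GGACAGAAGAGAGUGAGCACA"
        t = list(complement35(m))
        t[0] = "U"  # G:U at miRNA position 1 -> 0.5, outside the core
        assert score_duplex(m, "".join(t))[0] == pytest.approx(0.5)
        m5 = "UGACGGAAGAGAGUGAGCACA"
        t5 = list(complement35(m5))
        t5[4] = "U"  # G:U at position 5 -> doubled to 1.0
        assert score_duplex(m5, "".join(t5))[0] == pytest.approx(1.0)

    def test_penalties_are_additive(self):
        m = "UGGCAGAAGAGAGUGAGCACA"
        t = list(complement35(m))
        t[2] = "U"  # G:U at position 3 (core, 1.0)
        t[14] = "A"  # mismatch (G:A) at position 15 (1.0)
        penalty, pairing = score_duplex(m, "".join(t))
        assert penalty == pytest.approx(2.0)
        assert pairing[2] == "o" and pairing[14] == "x"

    def test_gap_against_gap_is_an_error(self):
        with pytest.raises(ValueError):
            score_duplex("AC-GU", "UG-CA")

    def test_swapping_strands_preserves_penalty(self):
        m = "UGACGGAAGAGAGUGAGCACA"
        t = list(complement35(m))
        t[4] = "U"
        t[15] = "A"
        t = "".join(t)
        assert score_duplex(m, t) == score_duplex(t, m)


def _embed(site: str, rng, pad=60):
    left = "".join(rng.choice(list("ACGU"), size=pad))
    right = "".join(rng.choice(list("ACGU"), size=pad))
    return SequenceRecord(id="t1", residues=left + site + right), pad


class TestScanTargets:
    def test_exact_reverse_complement_scores_zero(self):
        rng = np.random.default_rng(3)
        m = "UGACAGAAGAGAGUGAGCACA"
        rec, pad = _embed(reverse_complement(m), rng)
        sites = scan_targets([m], [rec])
        assert len(sites) == 1
        site = sites[0]
        assert site.penalty == 0.0
        assert site.site == (pad, pad + len(m))

    def test_threshold_boundary_two_vs_three_core_mismatches(self):
        rng = np.random.default_rng(4)
        m = "UGACAGAAGAGAGUGAGCACA"
        site = list(reverse_complement(m))
        # miRNA positions 10 and 12 map to site columns len-10 and len-12
        for pos in (10, 12):  # 1-based miRNA positions, inside the x2 core
            col = len(m) - pos
            site[col] = _COMP[site[col]]  # break the pair
        rec, pad = _embed("".join(site), rng)
        found = scan_targets([m], [rec], max_penalty=4.0)
        assert len(found) == 1 and found[0].penalty == pytest.approx(4.0)
        site[len(m) - 13] = _COMP[site[len(m) - 13]]  # third core mismatch
        rec3, _ = _embed("".join(site), rng)
        assert scan_targets([m], [rec3], max_penalty=4.0) == []

    def test_no_complementarity_is_empty(self):
        m = "UGACAGAAGAGAGUGAGCACA"
        rec = SequenceRecord(id="t1", residues="A" * 200)
        assert scan_targets([m], [rec]) == []

    def test_added_mismatch_never_lowers_penalty(self):
        rng = np.random.default_rng(5)
        m = "UGACAGAAGAGAGUGAGCACA"
        site = reverse_complement(m)
        rec, pad = _embed(site, rng)
        base = scan_targets([m], [rec])[0].penalty
        for col in (0, 3, 8):  # transcript-side columns outside the seed
            mutated = list(site)
            mutated[col] = _COMP[mutated[col]]
            rec2, _ = _embed("".join(mutated), np.random.default_rng(5))
            found = scan_targets([m], [rec2])
            if found:
                assert found[0].penalty >= base

    def test_seeded_scan_matches_brute_force(self):
        """Independent all-offsets rescoring finds the same best penalties."""
        rng = np.random.default_rng(6)
        weights = [2.0 if 2 <= c <= 13 else 1.0 for c in range(1, 40)]

        def naive_penalty(m, t35):
            p = 0.0
            for c, (a, b) in enumerate(zip(m, t35)):
                if a == "-" or b == "-":
                    unit = 2.0
                elif _COMP[a] == b:
                    unit = 0.0
                elif (a, b) in (("G", "U"), ("U", "G")):
                    unit = 0.5
                else:
                    unit = 1.0
                p += unit * weights[c]
            return p

        def naive_best(m, seq, s1):
            # seed: positions 2-8 perfectly complementary
            for k in range(1, 8):
                pos = s1 - 1 - k
                if pos < 0 or seq[pos] != _COMP[m[k]]:
                    return None
            L = len(m)
            cands = []
            if s1 - L >= 0:
                t = seq[s1 - L:s1][::-1]
                cands.append(naive_penalty(m, t))
            for g in range(8, L):  # gap in target
                if s1 - (L - 1) < 0:
                    continue
                t = seq[s1 - (L - 1):s1][::-1]
                t_aln = t[:g] + "-" + t[g:]
                cands.append(naive_penalty(m, t_aln))
            for g in range(8, L + 1):  # gap in miRNA
                if s1 - (L + 1) < 0:
                    continue
                t = seq[s1 - (L + 1):s1][::-1]
                m_aln = m[:g] + "-" + m[g:]
                cands.append(naive_penalty(m_aln, t))
            return min(cands) if cands else None

        for _ in range(15):
            m = "".join(rng.choice(list("ACGU"), size=21))
            seq = "".join(rng.choice(list("ACGU"), size=150))
            # embed a degraded site to make hits likely
            site = list(reverse_complement(m))
            site[2] = _COMP[site[2]]
            seq = seq[:60] + "".join(site) + seq[60:]
            for s1 in range(1, len(seq) + 1):
                expected = naive_best(m, seq, s1)
                got = sites_for_end(m, seq, s1, max_penalty=1e9)
                got_best = min((p for p, _, s0 in got if s0 >= 0), default=None)
                if expected is None:
                    assert not got
                else:
                    assert got_best == pytest.approx(expected)
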