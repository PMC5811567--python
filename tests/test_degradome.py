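"""Degradome profiles, cleavage-site calling and category classification."""

from itertools import combinations_with_replacement
from statistics import median

import pytest

from bulbmir.degradome import (DegradomeProfile, build_profile,
                               call_cleavage_sites, categorize_site,
                               tplot_table)
from bulbmir.preprocess import TagLibrary
from bulbmir.seqio import SequenceRecord, reverse_complement
from bulbmir.targets import TargetAlignment, scan_targets


class TestBuildProfile:
    def test_single_tag_counts_at_its_five_prime_end(self):
        t = SequenceRecord(id="t1", residues="ACGU" * 50)
        tag = t.residues[100:120]
        lib = TagLibrary("d", {tag: 5}, bounds=(1, 100))
        profiles, unmapped = build_profile(lib, [SequenceRecord(
            id="t1", residues="AAGG" + "CU" * 60 + t.residues[100:140])])
        # use a non-repetitive host so the tag maps once
        host = SequenceRecord(id="h", residues="AAGG" + "CU" * 60 + tag + "GG")
        profiles, unmapped = build_profile(lib, [host])
        pos = host.residues.find(tag)
        assert profiles["h"].counts == {pos: 5.0}
        assert unmapped == 0

    def test_multimapping_tag_splits_count_equally(self):
        tag = "UGACAGAAGAGAGUGAGCAC"
        t1 = SequenceRecord(id="t1", residues="CC" + tag + "GGAAGGAAGG")
        t2 = SequenceRecord(id="t2", residues="GGGGAA" + tag + "AAAA")
        lib = TagLibrary("d", {tag: 5}, bounds=(1, 100))
        profiles, unmapped = build_profile(lib, [t1, t2])
        assert profiles["t1"].counts[2] == pytest.approx(2.5)
        assert profiles["t2"].counts[6] == pytest.approx(2.5)

    def test_unmapped_tally_conserves_reads(self):
        lib = TagLibrary("d", {"UUUUGGGGCCCCAAAAUUUU": 7}, bounds=(1, 100))
        profiles, unmapped = build_profile(
            lib, [SequenceRecord(id="t1", residues="ACGU" * 30)])
        assert unmapped == 7 and not profiles


class TestCategorizeSite:
    @pytest.mark.parametrize("counts,pos,expected", [
        ({10: 5}, 10, 0),                      # unique maximum
        ({10: 5, 50: 5, 70: 1}, 10, 1),        # tied maxima
        ({10: 1, 50: 9}, 10, 4),               # single read
        ({10: 3, 20: 9, 30: 2, 40: 2}, 10, 2),  # med 2.5 < 3 < 9
        ({10: 2, 20: 9, 30: 7, 40: 3}, 10, 3),  # 1 < 2 <= med 5
    ])
    def test_reference_profiles(self, counts, pos, expected):
        profile = DegradomeProfile(transcript_id="t", counts=counts)
        assert categorize_site(profile, pos) == expected

    def test_zero_count_position_is_not_a_site(self):
        profile = DegradomeProfile(transcript_id="t", counts={10: 5})
        with pytest.raises(ValueError, match="not a site"):
            categorize_site(profile, 99)

    def test_exactly_one_clause_holds_for_every_expressed_position(self):
        """Exhaustive check over count multisets (values 0-10, size <= 6)."""
        for size in range(1, 7):
            for values in combinations_with_replacement(range(11), size):
                positive = [v for v in values if v > 0]
                if not positive:
                    continue
                m = max(positive)
                med = median(positive)
                n_max = positive.count(m)
                profile = DegradomeProfile(
                    transcript_id="t",
                    counts={i * 30: float(v) for i, v in enumerate(values)
                            if v > 0})
                for c in set(positive):
                    clauses = [
                        c <= 1,                         # category 4
                        c > 1 and c == m and n_max == 1,  # 0
                        c > 1 and c == m and n_max > 1,   # 1
                        c > 1 and med < c < m,            # 2
                        1 < c <= med and c < m,           # 3
                    ]
                    assert sum(clauses) == 1, (values, c)
                    pos = next(p for p, v in profile.counts.items() if v == c)
                    assert clauses[
                        {4: 0, 0: 1, 1: 2, 2: 3, 3: 4}[
                            categorize_site(profile, pos)]
                    ]


def _alignment(mirna, transcript_id, s0):
    return TargetAlignment(mirna=mirna, transcript_id=transcript_id,
                           site=(s0, s0 + len(mirna)),
                           pairing="|" * len(mirna), penalty=0.0)


class TestCallCleavageSites:
    def _setup(self, counts_at_offset):
        m = "UGACAGAAGAGAGUGAGCACA"
        pad = "GGAAGGAAGGAAGGAAGGAACCUUCCUUAACCAAGGAACC"
        site = reverse_complement(m)
        seq = pad + site + pad
        rec = SequenceRecord(id="t1", residues=seq)
        s0 = len(pad)
        expected = s0 + len(m) - 10  # paired to miRNA position 10
        counts = {expected + off: c for off, c in counts_at_offset.items()}
        profile = DegradomeProfile(transcript_id="t1", counts=counts)
        return _alignment(m, "t1", s0), profile, expected

    def test_signal_at_expected_position(self):
        aln, profile, expected = self._setup({0: 6.0})
        sites = call_cleavage_sites([aln], {"t1": profile})
        assert len(sites) == 1
        assert sites[0].position == expected and sites[0].category == 0

    def test_window_picks_off_by_one_signal(self):
        aln, profile, expected = self._setup({1: 4.0})
        sites = call_cleavage_sites([aln], {"t1": profile}, window=1)
        assert sites and sites[0].position == expected + 1

    def test_no_signal_no_site(self):
        aln, profile, expected = self._setup({5: 9.0})
        assert call_cleavage_sites([aln], {"t1": profile}, window=1) == []

    def test_transcript_without_profile_is_skipped(self):
        aln, profile, _ = self._setup({0: 6.0})
        assert call_cleavage_sites([aln], {}) == []

    def test_cleavage_position_on_scanned_alignment(self):
        """End-to-end: scanner alignment plus profile give the 10-11 site."""
        m = "UGACAGAAGAGAGUGAGCACA"
        pad = "GGAAGGAAGGAAGGAAGGAACCUUCCUUAACCAAGGAACC"
        rec = SequenceRecord(id="t1",
                             residues=pad + reverse_complement(m) + pad)
        aln = scan_targets([m], [rec])[0]
        expected = aln.site[1] - 10
        profile = DegradomeProfile(transcript_id="t1",
                                   counts={expected: 3.0, 5: 1.0})
        sites = call_cleavage_sites([aln], {"t1": profile})
        assert sites[0].position == expected


class TestTplotTable:
    def test_flags_called_sites(self):
        aln, profile, expected = (TestCallCleavageSites()._setup({0: 6.0}))
        sites = call_cleavage_sites([aln], {"t1": profile})
        table = tplot_table(profile, sites)
        assert len(table) == 1
        row = table.iloc[0]
        assert bool(row["is_called_site"]) and row["category"] == 0

    def test_empty_profile(self):
        profile = DegradomeProfile(transcript_id="t", counts={})
        assert tplot_table(profile, []).empty
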