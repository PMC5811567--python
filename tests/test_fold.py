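"""Folding model: MFE search, energy scoring, duplex geometry, validation."""

import numpy as np
import pytest

from bulbmir.fold import (HairpinFold, PrecursorCandidate, amfe_mfei,
                          enumerate_structures, fold_mfe, pairs_to_dotbracket,
                          star_of, structure_energy, validate_stemloop)
from bulbmir.seqio import reverse_complement


def brute_force_mfe(seq: str) -> float:
    """Exhaustive minimum of structure_energy over all legal structures."""
    return min(structure_energy(seq, pairs_to_dotbracket(p, len(seq)))
               for p in enumerate_structures(seq))


class TestFoldMfe:
    def test_unpairable_sequence_stays_open(self):
        fold = fold_mfe("A" * 10)
        assert fold.structure == "." * 10 and fold.mfe == 0.0

    def test_nested_gc_stem_matches_enumeration(self):
        fold = fold_mfe("GGGGAAAACCCC")
        assert fold.structure == "((((....))))"
        assert fold.mfe == brute_force_mfe("GGGGAAAACCCC")
        # 3 GC stacks (-9.0) + hairpin init 4.0 + 1 nt beyond minimum loop
        assert fold.mfe == pytest.approx(-4.5)

    def test_minimum_hairpin_loop_forbids_tight_pairs(self):
        # the only complementary pairs span < 4 nt, so nothing may form
        fold = fold_mfe("GGCCAAAAAA")
        assert fold.structure == "." * 10 and fold.mfe == 0.0

    def test_too_short_to_fold(self):
        with pytest.raises(ValueError, match="too short to fold"):
            fold_mfe("GGCC")

    def test_deterministic(self):
        seq = "GGCAUCGAUCGGCGAUUAGCCGAUCGAUGCC"
        assert fold_mfe(seq) == fold_mfe(seq)

    def test_oracle_equivalence_random_sample(self):
        """DP energy equals the exhaustive minimum on random sequences."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(10, 25))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert fold_mfe(seq).mfe == pytest.approx(brute_force_mfe(seq))

    @pytest.mark.parametrize("seq", [
        "GGGGAAAACCCC", "GCGCUUCGAUAGCGC", "AUGGCUAGCUAGCCAU"])
    def test_polya_tail_never_raises_mfe(self, seq):
        base = fold_mfe(seq).mfe
        assert fold_mfe(seq + "A" * 15).mfe <= base


class TestStructureEnergy:
    def test_open_structure_is_zero(self):
        assert structure_energy("ACGUACGUAC", ".........." ) == 0.0

    def test_isolated_pair_gets_half_pair_energy(self):
        # one G-C pair, unstacked: half of -3.0, plus hairpin 4.0 + 5*0.5
        energy = structure_energy("GAAAAAAAC", "(.......)")
        assert energy == pytest.approx(-1.5 + 4.0 + 0.5 * 4)

    def test_every_enumerated_structure_bounded_by_mfe(self):
        seq = "GGCAUCGAAACGAUGCCAAG"
        mfe = fold_mfe(seq).mfe
        for pairs in enumerate_structures(seq):
            s = pairs_to_dotbracket(pairs, len(seq))
            assert structure_energy(seq, s) >= mfe - 1e-9

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError):
            structure_energy("ACGUACGUAC", "((........")

    def test_fold_energy_consistency(self):
        seq = "GGAUGCAUCGAUCGAUUUCGAUCGAUGCAUCC"
        fold = fold_mfe(seq)
        assert structure_energy(seq, fold.structure) == pytest.approx(fold.mfe)


class TestAmfeMfei:
    def _fold(self, length, gc_count, mfe):
        seq = "G" * (gc_count // 2) + "C" * (gc_count - gc_count // 2) \
            + "A" * (length - gc_count)
        return HairpinFold(sequence=seq, structure="." * length, mfe=mfe)

    @pytest.mark.parametrize("length,gc,mfe,exp_amfe,exp_mfei", [
        (100, 50, -40.0, -40.0, -0.8),
        (150, 60, -30.0, -20.0, -0.5),
        (100, 50, 0.0, 0.0, 0.0),
    ])
    def test_formulas(self, length, gc, mfe, exp_amfe, exp_mfei):
        amfe, mfei, gc_pct = amfe_mfei(self._fold(length, gc, mfe))
        assert amfe == pytest.approx(exp_amfe)
        assert mfei == pytest.approx(exp_mfei)
        assert gc_pct == pytest.approx(100.0 * gc / length)

    def test_gc_free_sequence_has_undefined_mfei(self):
        amfe, mfei, gc = amfe_mfei(self._fold(100, 0, -10.0))
        assert mfei is None and gc == 0.0

    def test_amfe_invariant_under_tandem_duplication(self):
        unit = "GGGAGCAUCGAAACGAUGCUCCC"
        single = fold_mfe(unit)
        double = fold_mfe(unit + unit)
        assert amfe_mfei(double)[0] == pytest.approx(amfe_mfei(single)[0])


def perfect_hairpin(mature="UGACAGAAGAGAGUGAGCACA", loop="CAACAAUC"):
    star = reverse_complement(mature[:len(mature) - 2]) + "GA"
    return mature + loop + star, len(mature), len(loop)


class TestStarOf:
    def test_perfect_stem_star_with_two_nt_offset(self):
        seq, L, loop_len = perfect_hairpin()
        fold = fold_mfe(seq)
        star = star_of(fold, (0, L))
        assert star == (L + loop_len, len(seq))
        assert star[1] - star[0] == L

    def test_mature_deep_in_loop_has_no_star(self):
        seq, L, loop_len = perfect_hairpin()
        fold = fold_mfe(seq)
        # shift the mature interval so >4 nt reach past the arm into the loop
        assert star_of(fold, (7, 7 + L)) is None

    def test_unpaired_mature_has_no_star(self):
        seq, L, _ = perfect_hairpin()
        fold = HairpinFold(sequence=seq, structure="." * len(seq), mfe=0.0)
        assert star_of(fold, (0, L)) is None


def _candidate(seq, mature):
    fold = fold_mfe(seq)
    amfe, mfei, gc = amfe_mfei(fold)
    return PrecursorCandidate(
        source_id="t", window=(0, len(seq)), fold=fold, mature=mature,
        star=star_of(fold, mature), amfe=amfe, mfei=mfei, gc_percent=gc)


class TestValidateStemloop:
    def test_canonical_hairpin_accepted(self):
        seq, L, _ = perfect_hairpin()
        ok, reasons = validate_stemloop(_candidate(seq, (0, L)))
        assert ok and not reasons

    def test_mature_on_the_loop_rejected(self):
        seq, L, loop_len = perfect_hairpin()
        centre = L + loop_len // 2
        ok, reasons = validate_stemloop(
            _candidate(seq, (centre - 10, centre + 11)))
        assert not ok
        assert any("straddles" in r or "no pairing" in r for r in reasons)

    def test_unpaired_budget_boundary(self):
        seq, L, _ = perfect_hairpin()
        cand = _candidate(seq, (0, L))
        partner = cand.fold.pair_partner()
        unpaired = sum(1 for i in range(0, L) if partner[i] is None)
        ok_tight, reasons = validate_stemloop(
            cand, max_mature_unpaired=max(0, unpaired - 1))
        assert not ok_tight and any("unpaired" in r for r in reasons)
        assert validate_stemloop(cand, max_mature_unpaired=unpaired)[0]

    def test_open_fold_rejected_for_positive_mfe(self):
        seq = "A" * 30
        fold = fold_mfe(seq)
        cand = PrecursorCandidate(
            source_id="t", window=(0, 30), fold=fold, mature=(0, 21),
            star=None, amfe=0.0, mfei=None, gc_percent=0.0)
        ok, reasons = validate_stemloop(cand)
        assert not ok and any("MFE" in r for r in reasons)
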