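"""Physicochemical scalars: GRAVY, Mr, net charge, pI and plot coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leascan.physchem import (RESIDUE_MASSES, WATER_MASS, get_pka_set, get_scale,
                              gravy, isoelectric_point, mean_net_charge,
                              molecular_weight, net_charge, physchem_profile,
                              uversky_coordinates)
from leascan.seq_records import ProteinSequence

PROTEIN = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


def _p(residues: str) -> ProteinSequence:
    return ProteinSequence("p", residues)


class TestGravy:
    @pytest.mark.parametrize("residue", list("ACDEFGHIKLMNPQRSTVWY"))
    def test_homopolymer_equals_scale_entry(self, residue):
        scale = get_scale("eisenberg")
        assert gravy(_p(residue * 7)) == pytest.approx(scale[residue], abs=1e-12)

    @given(PROTEIN, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariant(self, residues, rnd):
        shuffled = list(residues)
        rnd.shuffle(shuffled)
        assert gravy(_p(residues)) == pytest.approx(gravy(_p("".join(shuffled))))

    def test_x_excluded_from_mean(self):
        assert gravy(_p("GXG")) == pytest.approx(gravy(_p("GG")))

    def test_all_x_rejected(self):
        with pytest.raises(ValueError):
            gravy(_p("XXX"))

    def test_u_uses_cys_value(self):
        assert gravy(_p("U")) == pytest.approx(get_scale("eisenberg")["C"])


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight(_p("G")) == pytest.approx(
            RESIDUE_MASSES["G"] + WATER_MASS)

    def test_dipeptide_additivity(self):
        mw_ab = molecular_weight(_p("GK"))
        mw_a, mw_b = molecular_weight(_p("G")), molecular_weight(_p("K"))
        assert mw_ab == pytest.approx(mw_a + mw_b - WATER_MASS)

    @given(PROTEIN.filter(lambda s: len(s) >= 2),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_random_split_additivity(self, residues, data):
        cut = data.draw(st.integers(1, len(residues) - 1))
        whole = molecular_weight(_p(residues))
        parts = molecular_weight(_p(residues[:cut])) + molecular_weight(_p(residues[cut:]))
        assert whole == pytest.approx(parts - WATER_MASS)

    def test_x_rejected_with_positions(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            molecular_weight(_p("GXG"))

    def test_agrees_with_biopython(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        ours = molecular_weight(_p(seq))
        theirs = ProteinAnalysis(seq).molecular_weight()
        assert ours == pytest.approx(theirs, abs=0.5)


class TestNetChargeAndPI:
    def test_poly_g_near_neutral(self):
        assert abs(net_charge(_p("GGGGG"), 7.0)) < 1.0

    def test_kkdd_balances(self):
        assert net_charge(_p("KKDD"), 7.0) == pytest.approx(0.0, abs=0.2)

    @given(PROTEIN)
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_ph(self, residues):
        p = _p(residues)
        assert net_charge(p, 1.0) > net_charge(p, 13.0)

    @given(PROTEIN)
    @settings(max_examples=50, deadline=None)
    def test_charge_at_pi_is_zero(self, residues):
        p = _p(residues)
        pi = isoelectric_point(p)
        assert abs(net_charge(p, pi)) < 0.05

    @given(PROTEIN)
    @settings(max_examples=50, deadline=None)
    def test_appending_lysine_never_decreases_pi(self, residues):
        p = _p(residues)
        assert isoelectric_point(_p(residues + "K")) >= isoelectric_point(p) - 0.02

    def test_unknown_pka_set(self):
        with pytest.raises(KeyError):
            net_charge(_p("K"), 7.0, pka_set="bogus")

    def test_sillero_set_also_roots(self):
        p = _p("MKDEHRKY")
        pi = isoelectric_point(p, pka_set="sillero")
        assert abs(net_charge(p, pi, pka_set="sillero")) < 0.05

    def test_near_biopython_pi(self):
        # different pKa tables (EMBOSS vs Bjellqvist) move pI by up to ~1 unit
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        for seq in ["MKTAYIAKQRQISFVK", "DDDDKKK", "MEEEVVKKHH"]:
            ours = isoelectric_point(_p(seq))
            theirs = IsoelectricPoint(seq).pi()
            assert ours == pytest.approx(theirs, abs=1.2)


class TestUverskyCoordinates:
    def test_poly_i_maximal_hydropathy(self):
        h, r = uversky_coordinates(_p("I" * 20))
        assert h == pytest.approx(1.0)
        assert r == 0.0

    def test_balanced_charges_cancel(self):
        _, r = uversky_coordinates(_p("KKDDKKDDKK" + "DD"))
        assert r == 0.0

    def test_windowed_mean_matches_hand_arithmetic(self):
        # 7-mer, window 5: spreadsheet-style truncated window means
        residues = "IKDGSAV"
        kd = {"I": 4.5, "K": -3.9, "D": -3.5, "G": -0.4, "S": -0.8,
              "A": 1.8, "V": 4.2}
        raw = [(kd[r] + 4.5) / 9 for r in residues]
        per_residue = []
        for i in range(7):
            lo, hi = max(0, i - 2), min(7, i + 3)
            per_residue.append(sum(raw[lo:hi]) / (hi - lo))
        expected_h = sum(per_residue) / 7
        expected_r = abs(1 - 1) / 7
        h, r = uversky_coordinates(_p(residues), window=5)
        assert h == pytest.approx(expected_h)
        assert r == pytest.approx(expected_r)

    def test_short_protein_shrinks_window(self, caplog):
        h, r = uversky_coordinates(_p("IK"), window=5)
        assert 0 <= h <= 1

    @given(PROTEIN, st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_r_permutation_invariant_h_only_at_window_one(self, residues, rnd):
        shuffled = list(residues)
        rnd.shuffle(shuffled)
        shuffled = "".join(shuffled)
        _, r1 = uversky_coordinates(_p(residues), window=1)
        _, r2 = uversky_coordinates(_p(shuffled), window=1)
        assert r1 == pytest.approx(r2)
        h1, _ = uversky_coordinates(_p(residues), window=1)
        h2, _ = uversky_coordinates(_p(shuffled), window=1)
        assert h1 == pytest.approx(h2)

    def test_h_not_permutation_invariant_with_window(self):
        a, b = "IIIKK", "IKIKI"
        ha, _ = uversky_coordinates(_p(a), window=5)
        hb, _ = uversky_coordinates(_p(b), window=5)
        assert ha != pytest.approx(hb)


def test_full_profile_fields():
    prof = physchem_profile(ProteinSequence("p", "MKDECW" * 5))
    assert prof.length == 30
    assert prof.has_cys and prof.has_trp
    assert 0 <= prof.mean_scaled_hydropathy <= 1
    assert 0 <= prof.mean_net_charge <= 1
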