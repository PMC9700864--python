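"""Charge assignment, layer sums and cross-sectional asymmetry."""

import numpy as np
import pandas as pd
import pytest

import fibrilgeom as fg
from fibrilgeom.charge import (ChargeConfig, DEFAULT_PKA, charge_asymmetry,
                               interior_layer_charge, layer_net_charge,
                               residue_charges, sequence_net_charge)
from fibrilgeom.model import FibrilModel

from conftest import rotation_matrix


class TestResidueCharges:
    def test_ggg_termini_cancel(self):
        assert sequence_net_charge("GGG") == pytest.approx(0.0)

    def test_dke_net_minus_one(self):
        assert sequence_net_charge("DKE") == pytest.approx(-1.0)

    def test_integer_assignments_at_ph_7_4(self):
        cfg = ChargeConfig()
        assert cfg.group_charge("ASP") == -1
        assert cfg.group_charge("GLU") == -1
        assert cfg.group_charge("ARG") == +1
        assert cfg.group_charge("LYS") == +1
        for neutral in ("HIS", "CYS", "TYR", "SER", "GLY"):
            assert cfg.group_charge(neutral) == 0
        assert cfg.group_charge("N_TERM") == +1
        assert cfg.group_charge("C_TERM") == -1

    def test_his_half_charged_at_its_pka(self):
        cfg = ChargeConfig(pH=6.0, mode="henderson_hasselbalch")
        assert cfg.group_charge("HIS") == pytest.approx(0.5)

    def test_hh_converges_to_integer_far_from_pka(self):
        """Three pH units past every pKa the fractional charge is within
        0.002 of the integer assignment."""
        for group, pka in DEFAULT_PKA.items():
            for ph in (pka - 3.5, pka + 3.5):
                if not 0 < ph < 14:
                    continue
                hh = ChargeConfig(pH=ph, mode="henderson_hasselbalch")
                integer = ChargeConfig(pH=ph, mode="integer")
                assert abs(hh.group_charge(group)
                           - integer.group_charge(group)) < 0.002

    def test_model_charges_and_termini(self, simple_fibril):
        profile = residue_charges(simple_fibril, ChargeConfig())
        per = profile.per_residue
        chain = per[per["chain_id"] == "A"]
        # sequence AEAKAAEK: 2 Glu (-1), 2 Lys (+1), termini cancel
        assert chain["charge_e"].sum() == pytest.approx(0.0)
        assert chain["termini_e"].sum() == pytest.approx(0.0)
        no_term = residue_charges(
            simple_fibril, ChargeConfig(include_termini=False))
        assert (no_term.per_residue["termini_e"] == 0).all()


class TestLayerCharge:
    def test_charge_conservation(self, vascular_like):
        profile = layer_net_charge(vascular_like, ChargeConfig())
        assert sum(profile.layer_net.values()) == pytest.approx(
            profile.total_charge)

    def test_two_stack_layer_sum(self):
        a = fg.build_fibril(fg.GeneratorSpec(sequence="DKE", n_layers=3))
        b = fg.build_fibril(fg.GeneratorSpec(sequence="GGG", n_layers=3))
        both = fg.synthetic.combine_stacks(
            a, b.transformed(translation=(0.0, 10.0, 0.0)))
        profile = layer_net_charge(both, ChargeConfig())
        for v in profile.layer_net.values():
            assert v == pytest.approx(-1.0)

    def test_saa_fragment_layer_charges(self, vascular_like, glomerular_like):
        """Integer charges at pH 7.4: -2 per vascular layer (subunits 2-40
        and 2-69), 0 per glomerular layer (two copies of 2-55)."""
        assert interior_layer_charge(vascular_like) == pytest.approx(-2.0)
        assert interior_layer_charge(glomerular_like) == pytest.approx(0.0)

    def test_termini_policy_does_not_change_net(self, vascular_like):
        incl = interior_layer_charge(vascular_like, ChargeConfig())
        excl = interior_layer_charge(vascular_like,
                                     ChargeConfig(include_termini=False))
        assert incl == pytest.approx(excl)


class TestAsymmetry:
    def _point_model(self, entries):
        """entries: (resname, x, y) placed as lone CA/carrier atoms."""
        rows = []
        for i, (resname, x, y) in enumerate(entries, start=1):
            rows.append(("L", i, resname, "CA", "C", x, y, 0.0))
        atoms = pd.DataFrame(rows, columns=["chain_id", "residue_number",
                                            "residue_name", "atom_name",
                                            "element", "x", "y", "z"])
        return FibrilModel(atoms=atoms, layer_of={"L": 0}, stack_of={"L": "A"})

    def test_mirror_symmetric_charges_cancel(self):
        m = self._point_model([("ASP", 10.0, 0.0), ("GLU", -10.0, 0.0),
                               ("GLY", 0.0, 5.0), ("GLY", 0.0, -5.0)])
        asym = charge_asymmetry(m, ChargeConfig(include_termini=False))
        assert asym["magnitude_eA"] == pytest.approx(0.0, abs=1e-9)
        assert asym["normalized_score"] == 0.0

    def test_single_charge_moment(self):
        # lone +1 charge 10 A from the CA centroid
        m = self._point_model([("LYS", 10.0, 0.0), ("GLY", 0.0, 0.0),
                               ("GLY", -10.0, 0.0)])
        asym = charge_asymmetry(m, ChargeConfig(include_termini=False))
        assert asym["magnitude_eA"] == pytest.approx(10.0 * 1.0, abs=1e-9)

    def test_all_neutral_gives_zero_score(self):
        m = self._point_model([("GLY", 3.0, 0.0), ("SER", -3.0, 0.0)])
        asym = charge_asymmetry(m, ChargeConfig(include_termini=False))
        assert asym["normalized_score"] == 0.0

    def test_rotation_about_axis_preserves_magnitude(self, vascular_like):
        a0 = charge_asymmetry(vascular_like)
        rot = vascular_like.transformed(rotation=rotation_matrix([0, 0, 1], 37.0))
        a1 = charge_asymmetry(rot)
        assert a1["magnitude_eA"] == pytest.approx(a0["magnitude_eA"], abs=1e-9)
        assert a1["normalized_score"] == pytest.approx(
            a0["normalized_score"], abs=1e-12)

    def test_pseudo_21_layer_nearly_balanced(self, vascular_like,
                                             glomerular_like):
        """The screw-symmetric glomerular layer cancels its charge moment;
        the two-sequence C1 vascular layer does not."""
        vas = charge_asymmetry(vascular_like)["normalized_score"]
        glo = charge_asymmetry(glomerular_like)["normalized_score"]
        assert glo < 0.01
        assert vas > glo
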