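"""Dihedral statistics and helical-parameter estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fibrilgeom as fg
from fibrilgeom.geometry import DihedralRecord, dihedral_deg, wrap_angle
from fibrilgeom.model import FibrilModel

from conftest import rotation_matrix


def record(phi, psi, n=1, beta=True):
    delta = wrap_angle(phi + psi) if phi is not None and psi is not None else None
    return DihedralRecord("A", n, "ALA", phi, psi, delta, is_beta=beta)


class TestAngles:
    def test_wrap_examples(self):
        assert wrap_angle(210.0) == pytest.approx(-150.0)
        assert wrap_angle(170.0 + 40.0) == pytest.approx(-150.0)
        assert wrap_angle(180.0) == pytest.approx(180.0)
        assert wrap_angle(-180.0) == pytest.approx(180.0)

    @given(st.floats(-1e4, 1e4))
    @settings(deadline=None, derandomize=True)
    def test_wrap_in_half_open_interval(self, x):
        w = wrap_angle(x)
        assert -180.0 < w <= 180.0
        d = (w - x) % 360.0
        assert min(d, 360.0 - d) == pytest.approx(0.0, abs=1e-6)

    def test_dihedral_sign_convention(self):
        # +90 deg: looking down the b-c bond, d is rotated clockwise from a
        p = [np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])]
        d_pos = np.array([0, 1.0, -1.0])
        assert dihedral_deg(p[0], p[1], p[2], d_pos) == pytest.approx(90.0)
        assert dihedral_deg(p[0], p[1], p[2],
                            np.array([0, 1.0, 1.0])) == pytest.approx(-90.0)

    def test_mirror_negates_dihedrals(self, simple_fibril):
        recs = fg.backbone_dihedrals(simple_fibril, "A")
        mrecs = fg.backbone_dihedrals(simple_fibril.mirrored(), "A")
        for r, m in zip(recs, mrecs):
            if r.phi_deg is not None:
                assert m.phi_deg == pytest.approx(-r.phi_deg, abs=1e-9)
            if r.psi_deg is not None:
                assert m.psi_deg == pytest.approx(-r.psi_deg, abs=1e-9)

    def test_chain_break_treated_as_termini(self, simple_spec):
        strand = fg.build_strand(simple_spec)
        # pull the second half of the chain far away: C-N bond broken
        atoms = strand.atoms.copy()
        far = atoms["residue_number"] >= 5
        atoms.loc[far, "z"] += 100.0
        broken = FibrilModel(atoms=atoms, layer_of={"A": 0}, stack_of={"A": "A"})
        recs = {r.residue_number: r for r in fg.backbone_dihedrals(broken, "A")}
        assert recs[4].psi_deg is None
        assert recs[5].phi_deg is None
        assert recs[5].psi_deg is not None


class TestDeltaStatistic:
    def test_single_residue(self):
        s = fg.delta_statistic([record(-120.0, 130.0)])
        assert s.delta_mean_deg == pytest.approx(10.0)
        assert s.delta_sd_deg == 0.0
        assert s.n_residues == 1

    def test_mean_and_sample_sd(self):
        recs = [record(-120.0, 130.0, 1), record(-130.0, 150.0, 2),
                record(-110.0, 140.0, 3)]
        s = fg.delta_statistic(recs)
        deltas = np.array([10.0, 20.0, 30.0])
        assert s.delta_mean_deg == pytest.approx(deltas.mean())
        assert s.delta_sd_deg == pytest.approx(deltas.std(ddof=1))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            fg.delta_statistic([record(-120.0, 130.0, beta=False)], subset="beta")

    def test_handedness_calls(self):
        left = fg.delta_statistic([record(-120.0, 140.0, i) for i in range(5)])
        assert left.handedness_call == "left"
        right = fg.delta_statistic([record(-140.0, 120.0, i) for i in range(5)])
        assert right.handedness_call == "right"
        mixed = [record(-120.0, 140.0, 1), record(-140.0, 120.0, 2),
                 record(-150.0, 120.0, 3), record(-100.0, 140.0, 4)]
        assert fg.delta_statistic(mixed).handedness_call == "indeterminate"

    def test_zero_delta_counts_in_n_but_no_side(self):
        recs = [record(-130.0, 130.0, 1), record(-120.0, 140.0, 2)]
        s = fg.ramachandran_side(recs)
        assert s.n_residues == 2
        assert s.right_side_fraction == pytest.approx(0.5)

    def test_mirror_flips_call(self, simple_fibril):
        # the mirror image has inverted chirality, so classify over all
        # residues (its dihedrals fall outside the L-chain beta window)
        recs = fg.backbone_dihedrals(simple_fibril, "A")
        mrecs = fg.backbone_dihedrals(simple_fibril.mirrored(), "A")
        s, m = fg.ramachandran_side(recs), fg.ramachandran_side(mrecs)
        assert m.delta_mean_deg == pytest.approx(-s.delta_mean_deg, abs=1e-9)
        assert {s.handedness_call, m.handedness_call} == {"left", "right"}


class TestHelicalParameters:
    @pytest.mark.parametrize("twist", [-4.0, -1.66, -0.5, 0.5, 1.66, 4.0])
    @pytest.mark.parametrize("rise", [2.4, 4.8])
    def test_noise_free_recovery_grid(self, twist, rise):
        fib = fg.build_fibril(fg.GeneratorSpec(
            sequence="AAAAAA", twist_deg_per_layer=twist, rise_A=rise,
            n_layers=4))
        hp = fg.helical_parameters(fib)
        assert hp.twist_deg_per_layer == pytest.approx(twist, abs=1e-6)
        assert hp.rise_A == pytest.approx(rise, abs=1e-6)

    def test_noisy_recovery(self):
        fib = fg.build_fibril(fg.GeneratorSpec(
            sequence="A" * 30, twist_deg_per_layer=-1.66, rise_A=4.8,
            n_layers=6, noise_sd_A=0.3, seed=11))
        hp = fg.helical_parameters(fib)
        assert hp.twist_deg_per_layer == pytest.approx(-1.66, abs=0.1)
        assert hp.rise_A == pytest.approx(4.8, abs=0.05)
        assert hp.rmsd_A > 0

    def test_crossover_pitch_identities(self, simple_fibril):
        hp = fg.helical_parameters(simple_fibril)
        assert hp.pitch_nm == pytest.approx(2.0 * hp.crossover_nm)
        assert hp.crossover_nm == pytest.approx(
            180.0 / abs(hp.twist_deg_per_layer) * hp.rise_A / 10.0)
        assert hp.crossover_nm == pytest.approx(52.048, abs=1e-3)

    def test_two_stack_model_pools_both_stacks(self, glomerular_like):
        hp = fg.helical_parameters(glomerular_like)
        assert hp.twist_deg_per_layer == pytest.approx(1.66, abs=1e-6)
        assert len(hp.per_step_values) == 2 * 5  # 2 stacks x 5 steps

    def test_single_layer_rejected(self):
        fib = fg.build_fibril(fg.GeneratorSpec(sequence="AAAA", n_layers=1))
        with pytest.raises(ValueError):
            fg.helical_parameters(fib)

    def test_off_axis_rotation_rejected(self, simple_fibril):
        # bend the top layers: superposition rotation no longer about z
        m = simple_fibril
        atoms = m.atoms.copy()
        top = atoms["chain_id"].isin([c for c in m.chains if m.layer_of[c] >= 3])
        R = rotation_matrix([1, 0, 0], 45.0)
        xyz = atoms.loc[top, ["x", "y", "z"]].to_numpy() @ R.T
        atoms.loc[top, ["x", "y", "z"]] = xyz
        bent = FibrilModel(atoms=atoms, layer_of=dict(m.layer_of),
                           stack_of=dict(m.stack_of))
        with pytest.raises(ValueError, match="axis"):
            fg.helical_parameters(bent)


class TestModelWidth:
    def _two_atom_model(self, p, q):
        atoms = pd.DataFrame(
            [("A", 1, "GLY", "CA", "C", *p), ("A", 2, "GLY", "CA", "C", *q)],
            columns=["chain_id", "residue_number", "residue_name",
                     "atom_name", "element", "x", "y", "z"])
        return FibrilModel(atoms=atoms, layer_of={"A": 0}, stack_of={"A": "A"})

    def test_two_atoms_in_cross_section(self):
        m = self._two_atom_model((0, 0, 0), (50.0, 0, 3.0))
        assert fg.model_width(m) == pytest.approx(5.34)

    def test_axial_strand_margin_only(self):
        m = self._two_atom_model((0, 0, 0), (0, 0, 30.0))
        assert fg.model_width(m) == pytest.approx(0.34)

    def test_rotation_invariance(self, vascular_like):
        w0 = fg.model_width(vascular_like)
        Rz = rotation_matrix([0, 0, 1], 73.0)
        w1 = fg.model_width(vascular_like.transformed(rotation=Rz))
        assert w1 == pytest.approx(w0, abs=1e-9)
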