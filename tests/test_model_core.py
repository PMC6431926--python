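"""Unit and property tests for the four-term potential and its geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helibundle.model_core import (ForbiddenBondError,
                                   ModelParams, bend_energy, bending_angle,
                                   bending_angles, bond_lengths,
                                   dihedral_angle, dihedral_angles,
                                   displacement_delta, fene_energy, lj_energy,
                                   pivot_delta, torsion_energy, total_energy,
                                   validate_conformation)
from helibundle.structure_analysis import make_ideal_helix, make_random_coil, make_rod

from conftest import random_rigid_motion


class TestScalarPotentials:
    def test_fene_zero_at_reference(self, params):
        assert fene_energy(1.0, params) == 0.0

    def test_fene_value(self, params):
        # -log(1 - (0.2 * 7/3)^2), frozen from scalar evaluation
        assert fene_energy(1.2, params) == pytest.approx(0.24561640716626845)

    def test_fene_symmetric_and_monotone(self, params):
        assert fene_energy(0.8, params) == pytest.approx(fene_energy(1.2, params))
        rs = np.linspace(1.0, 1.0 + params.R - 1e-3, 50)
        es = [fene_energy(r, params) for r in rs]
        assert np.all(np.diff(es) > 0)

    @pytest.mark.parametrize("r", [1 + 3 / 7, 1 - 3 / 7, 1.6, 0.2])
    def test_fene_forbidden(self, params, r):
        with pytest.raises(ForbiddenBondError):
            fene_energy(r, params)

    def test_lj_zero_at_and_beyond_cutoff(self, params):
        assert lj_energy(params.rc, params) == 0.0
        assert lj_energy(10 * params.rc, params) == 0.0

    def test_lj_minimum_is_shifted_well_depth(self, params):
        # minimum of the unshifted LJ is -1 at r = 2^(1/6) sigma = r0
        assert params.vc == pytest.approx(-0.016316891136, rel=1e-9)
        assert lj_energy(1.0, params) == pytest.approx(-0.983683108864, rel=1e-9)

    def test_lj_continuous_at_cutoff(self, params):
        below = lj_energy(params.rc - 1e-9, params)
        above = lj_energy(params.rc + 1e-9, params)
        assert abs(below - above) < 1e-6

    def test_lj_singular_overlap(self, params):
        with pytest.raises(ValueError):
            lj_energy(0.0, params)

    def test_bend_values(self, params):
        assert bend_energy(1.4, params) == 0.0
        assert bend_energy(1.4 + math.pi / 2, params) == pytest.approx(1.0)
        assert bend_energy(0.0, params) == pytest.approx(0.8300328570997589)

    def test_torsion_values(self, params):
        assert torsion_energy(0.873, params) == 0.0
        # chirality selection: the mirror dihedral -tau0 is penalised
        assert torsion_energy(-0.873, params) == pytest.approx(1.174308696391294)
        assert torsion_energy(0.873 - 2 * math.pi, params) == pytest.approx(0.0, abs=1e-12)


class TestGeometry:
    def test_bending_angle_examples(self):
        a, b = np.zeros(3), np.array([1.0, 0, 0])
        assert bending_angle(a, b, [2, 0, 0]) == pytest.approx(0.0)
        assert bending_angle(a, b, [1, 1, 0]) == pytest.approx(math.pi / 2)
        assert bending_angle(a, b, [0.1, 0, 0]) == pytest.approx(math.pi)

    def test_bending_angle_degenerate(self):
        with pytest.raises(ValueError):
            bending_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_dihedral_sign_convention(self):
        a, b, c = np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])
        assert dihedral_angle(a, b, c, [1, 1, 1]) == pytest.approx(math.pi / 2)
        # planar cis (d on the same side as a) anchors 0
        assert dihedral_angle(a, b, c, [0, 1, 0]) == pytest.approx(0.0)
        # planar trans (zig-zag) is pi
        assert abs(dihedral_angle(a, b, c, [2, 1, 0])) == pytest.approx(math.pi)

    def test_dihedral_degenerate(self):
        with pytest.raises(ValueError):
            dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestTotalEnergy:
    def test_straight_rod_hand_summation(self, params):
        # spacing 1.2: all non-bonded pairs beyond rc, bonds stretched,
        # both bending angles 0, dihedrals degenerate (contribute 0)
        p = params.with_s_tau(7.0)
        rod = make_rod(4, p, spacing=1.2)
        e = total_energy(rod, p)
        assert e.e_lj == 0.0
        assert e.e_fene == pytest.approx(3 * p.s_fene * 0.24561640716626845)
        assert e.e_bend == pytest.approx(2 * p.s_theta * 0.8300328570997589)
        assert e.e_tor == 0.0

    def test_unit_rod_lj_pairs(self, params):
        rod = make_rod(4, params, spacing=1.0)
        e = total_energy(rod, params)
        # pairs at distance 2 (two of them) and 3 (beyond cutoff)
        assert e.e_lj == pytest.approx(2 * (-0.014688968239), rel=1e-9)
        assert e.e_fene == pytest.approx(0.0, abs=1e-12)

    def test_ideal_helix_reference_geometry(self, params):
        p = params.with_s_tau(5.0)
        helix = make_ideal_helix(20, p)
        e = total_energy(helix, p)
        assert e.e_fene == pytest.approx(0.0, abs=1e-9)
        assert e.e_bend == pytest.approx(0.0, abs=1e-9)
        assert e.e_tor == pytest.approx(0.0, abs=1e-9)
        assert e.e_lj < 0
        assert e.e_total == pytest.approx(e.e_lj)

    def test_breakdown_total_is_sum(self, params, coil30):
        e = total_energy(coil30, params.with_s_tau(3.0))
        assert e.e_total == pytest.approx(e.e_fene + e.e_lj + e.e_bend + e.e_tor)

    def test_forbidden_bond_propagates(self, params):
        pos = make_rod(5, params, spacing=1.2)
        pos[4, 0] += 0.5  # stretch last bond to 1.7 > r0 + R
        with pytest.raises(ForbiddenBondError):
            total_energy(pos, params)
        with pytest.raises(ForbiddenBondError):
            validate_conformation(pos, params)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), s_tau=st.floats(0.0, 30.0))
    def test_rigid_motion_invariance(self, seed, s_tau):
        rng = np.random.default_rng(seed)
        p = ModelParams(s_tau=s_tau)
        pos = make_random_coil(15, p, rng)
        e0 = total_energy(pos, p)
        e1 = total_energy(random_rigid_motion(pos, rng), p)
        for attr in ("e_fene", "e_lj", "e_bend", "e_tor"):
            assert getattr(e1, attr) == pytest.approx(getattr(e0, attr),
                                                      rel=1e-9, abs=1e-9)

    def test_mirror_image_changes_only_torsion(self, params):
        p = params.with_s_tau(4.0)
        helix = make_ideal_helix(16, p)
        mirror = helix * np.array([1.0, 1.0, -1.0])
        e0, e1 = total_energy(helix, p), total_energy(mirror, p)
        assert e1.e_fene == pytest.approx(e0.e_fene, abs=1e-9)
        assert e1.e_lj == pytest.approx(e0.e_lj, rel=1e-9)
        assert e1.e_bend == pytest.approx(e0.e_bend, abs=1e-9)
        # dihedrals negate: each contributes 1 - cos(2 tau0) instead of 0
        assert e1.e_tor == pytest.approx(13 * 4.0 * 1.174308696391294, rel=1e-9)
        assert np.allclose(dihedral_angles(mirror), -dihedral_angles(helix))


class TestIncrementalDeltas:
    def test_null_displacement(self, params, coil30):
        de = displacement_delta(coil30, 7, coil30[7], params)
        assert de == 0.0

    def test_displacement_matches_full_recompute(self, params, coil30):
        p = params.with_s_tau(9.0)
        rng = np.random.default_rng(5)
        pos = coil30.copy()
        for _ in range(300):
            i = int(rng.integers(0, len(pos)))
            new = pos[i] + 0.25 * (rng.random(3) - 0.5)
            de = displacement_delta(pos, i, new, p)
            trial = pos.copy()
            trial[i] = new
            if not math.isfinite(de):
                with pytest.raises(ForbiddenBondError):
                    total_energy(trial, p)
                continue
            de_full = (total_energy(trial, p).e_total
                       - total_energy(pos, p).e_total)
            assert de == pytest.approx(de_full, rel=1e-9, abs=1e-9)
            pos = trial

    def test_displacement_forbidden_is_inf(self, params, rod10):
        new = rod10[0] + np.array([-1.0, 0.0, 0.0])
        assert displacement_delta(rod10, 0, new, params) == math.inf

    def test_pivot_matches_full_recompute(self, params, coil30):
        p = params.with_s_tau(9.0)
        rng = np.random.default_rng(6)
        pos = coil30.copy()
        for _ in range(200):
            k = int(rng.integers(0, len(pos) - 1))
            phi = float(rng.uniform(-math.pi, math.pi))
            de, new = pivot_delta(pos, k, phi, bool(rng.random() < 0.5), p)
            de_full = (total_energy(new, p).e_total
                       - total_energy(pos, p).e_total)
            assert de == pytest.approx(de_full, rel=1e-9, abs=1e-8)
            if de < 1e3:  # a sampler would reject hard-core smashes anyway
                pos = new

    def test_pivot_involution(self, params, helix20):
        p = params.with_s_tau(2.0)
        de1, pos1 = pivot_delta(helix20, 8, 1.1, True, p)
        de2, pos2 = pivot_delta(pos1, 8, -1.1, True, p)
        assert de1 + de2 == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(pos2, helix20, atol=1e-9)

    def test_pivot_preserves_internal_geometry(self, params, helix20):
        p = params.with_s_tau(2.0)
        _, new = pivot_delta(helix20, 9, 0.8, True, p)
        assert np.allclose(bond_lengths(new), bond_lengths(helix20), atol=1e-12)
        assert np.allclose(bending_angles(new), bending_angles(helix20),
                           atol=1e-9)
        # exactly one dihedral (the one across the pivot bond) changes
        d0, d1 = dihedral_angles(helix20), dihedral_angles(new)
        changed = np.flatnonzero(np.abs(d1 - d0) > 1e-9)
        assert changed.tolist() == [8]
        assert d1[8] - d0[8] == pytest.approx(0.8)


class TestParamsConfig:
    def test_defaults_match_model_constants(self, params):
        assert params.R == pytest.approx(3 / 7)
        assert params.sigma == pytest.approx(2 ** (-1 / 6))
        assert params.rc == pytest.approx(2.5 * params.sigma)
        assert params.s_fene == pytest.approx(98 / 5)
        assert params.s_theta == 200.0
        assert params.theta0 == 1.4 and params.tau0 == 0.873

    def test_roundtrip_file(self, tmp_path, params):
        p = params.with_s_tau(13.5)
        path = tmp_path / "params.json"
        p.to_file(path)
        q = ModelParams.from_file(path)
        assert q == p

    def test_vc_tracks_rc(self):
        p = ModelParams(rc=1.5)
        assert lj_energy(1.5, p) == 0.0
        assert lj_energy(1.5 - 1e-9, p) == pytest.approx(0.0, abs=1e-6)

    def test_negative_s_tau_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(s_tau=-1.0)
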