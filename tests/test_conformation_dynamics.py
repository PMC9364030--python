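import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_residue
from gtcore.conformation_dynamics import (
    DihedralPair,
    State,
    StateReference,
    canonicalize_chi2,
    chi_angles,
    classify_state,
    occupancy_trace,
    torsion,
    water_bridge,
)
from gtcore.structure_io import Atom, Residue, read_trajectory
from gtcore import synthetic_data as syn

REFS = syn.DEFAULT_REFS


class TestTorsion:
    def test_planar_trans(self):
        assert torsion((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_planar_cis(self):
        assert torsion((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_sign_convention(self):
        assert torsion((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)) == pytest.approx(-90.0)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            torsion((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_reversal_invariance_and_mirror_antisymmetry(self, seed):
        # the signed dihedral is unchanged by reading the quartet backwards
        # (chi is well defined either way); what flips the sign is mirror
        # reflection of the coordinates
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        try:
            fwd = torsion(*pts)
        except ValueError:
            return
        assert torsion(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(abs(fwd) - 180.0) > 1e-9 and abs(fwd) > 1e-9:
            assert torsion(*mirrored) == pytest.approx(-fwd, abs=1e-9)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 3)) * 4
        ref = torsion(*pts)
        for _ in range(10):
            r = Rotation.random(random_state=rng).as_matrix()
            moved = pts @ r.T + rng.normal(scale=10, size=3)
            assert torsion(*moved) == pytest.approx(ref, abs=1e-8)

    def test_independent_geometric_construction(self):
        # Place the fourth atom by explicit rotation about the central bond:
        # p4 = p3 + (0, cos(phi), -sin(phi)) with the p1 arm along +y gives a
        # dihedral of exactly phi under the clockwise-positive convention.
        for phi in (-150.0, -90.0, -30.0, 0.0, 45.0, 120.0, 180.0):
            p4 = (1.0, np.cos(np.radians(phi)), -np.sin(np.radians(phi)))
            assert torsion((0, 1, 0), (0, 0, 0), (1, 0, 0), p4) == pytest.approx(phi)


class TestChiAngles:
    @pytest.mark.parametrize("chi1,chi2", [(60.0, -80.0), (-175.0, 12.5), (5.0, 89.0)])
    def test_asp_round_trip(self, chi1, chi2):
        pos = syn._asp_atoms(chi1, chi2)
        res = make_residue("ASP", pos)
        d = chi_angles(res)
        assert d.chi1 == pytest.approx(chi1, abs=1e-6)
        assert d.chi2 == pytest.approx(chi2, abs=1e-6)

    def test_random_round_trips(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            chi1 = float(rng.uniform(-179, 180))
            chi2 = float(rng.uniform(-179, 180))
            res = make_residue("ASP", syn._asp_atoms(chi1, chi2))
            d = chi_angles(res)
            assert d.chi1 == pytest.approx(chi1, abs=1e-6)
            assert d.chi2 == pytest.approx(chi2, abs=1e-6)

    def test_glycine_has_no_chi(self):
        gly = make_residue("GLY", {"N": (0, 1, 0), "CA": (0, 0, 0), "C": (1, 0, 0)})
        d = chi_angles(gly)
        assert d.chi1 is None and d.chi2 is None

    def test_missing_atom_logged_absent(self, caplog):
        pos = syn._asp_atoms(60.0, 30.0)
        pos.pop("CG")
        with caplog.at_level("DEBUG", logger="gtcore.conformation_dynamics"):
            d = chi_angles(make_residue("ASP", pos))
        assert d.chi1 is None and d.chi2 is None

    def test_thr_has_chi1_only(self):
        thr = make_residue(
            "THR",
            {"N": (0, 1.4, 0), "CA": (0, 0, 0), "CB": (1.3, -0.6, 0), "OG1": (2.2, 0.3, 0.8)},
        )
        d = chi_angles(thr)
        assert d.chi1 is not None and d.chi2 is None


class TestCanonicalize:
    @pytest.mark.parametrize("raw,expected", [(40.0, 40.0), (130.0, -50.0), (-130.0, 50.0), (90.0, 90.0), (-90.0, 90.0)])
    def test_fold(self, raw, expected):
        assert canonicalize_chi2(raw) == pytest.approx(expected)


class TestClassifyState:
    def test_exact_reference_assigned(self):
        d = DihedralPair(chi1=REFS[0].chi1_ref, chi2=REFS[0].chi2_ref)
        assert classify_state(d, REFS) is State.D_IN

    def test_equidistant_tie_undefined(self):
        refs = (
            StateReference(State.D_IN, -60.0, 0.0),
            StateReference(State.D_OUT, 60.0, 0.0),
        )
        assert classify_state(DihedralPair(0.0, 0.0), refs) is State.UNDEFINED

    def test_far_from_both_undefined(self):
        refs = (
            StateReference(State.D_IN, -170.0, 0.0),
            StateReference(State.D_OUT, -100.0, 0.0),
        )
        assert classify_state(DihedralPair(30.0, 85.0), refs) is State.UNDEFINED

    def test_undefined_angles_undefined(self):
        assert classify_state(DihedralPair(None, 40.0), REFS) is State.UNDEFINED

    def test_scale_free(self):
        # labels depend only on angles: rescaling all coordinates changes nothing
        pos = syn._asp_atoms(-55.0, 35.0)
        for scale in (0.5, 1.0, 7.3):
            res = make_residue("ASP", {k: np.asarray(v) * scale for k, v in pos.items()})
            assert classify_state(chi_angles(res), REFS) is State.D_IN

    def test_close_references_rejected(self):
        refs = (
            StateReference(State.D_IN, 0.0, 0.0),
            StateReference(State.D_OUT, 10.0, 10.0),
        )
        with pytest.raises(ValueError, match="torus"):
            classify_state(DihedralPair(0.0, 0.0), refs)


class TestOccupancyTrace:
    def test_programmed_80_20_noise_free(self):
        text, truth = syn.make_trajectory(schedule=0.8, n_frames=200, sigma_angle=0.0, seed=4)
        trace = occupancy_trace(read_trajectory(text), truth["asp_selector"], REFS)
        assert trace.occupancy[State.D_IN.value] == pytest.approx(0.8)
        assert [s.value for s in trace.states] == truth["states"]

    def test_noisy_schedule_recovery(self):
        text, truth = syn.make_trajectory(schedule=0.7, n_frames=1500, sigma_angle=15.0, seed=5)
        trace = occupancy_trace(read_trajectory(text), truth["asp_selector"], REFS)
        match = np.mean([s.value == t for s, t in zip(trace.states, truth["states"])])
        assert match >= 0.97
        assert trace.occupancy[State.D_IN.value] == pytest.approx(truth["ratio_in"], abs=0.02)

    def test_bad_selector(self):
        text, _ = syn.make_trajectory(schedule=0.5, n_frames=3, seed=6)
        fs = read_trajectory(text)
        with pytest.raises(ValueError, match="matches 0"):
            occupancy_trace(fs, "A:999", REFS)
        with pytest.raises(ValueError, match="selector"):
            occupancy_trace(fs, "nonsense", REFS)


class TestWaterBridge:
    def _system(self, water_xyz):
        asp = make_residue("ASP", {"OD1": (0, 0, 0), "OD2": (1.0, 1.0, 0)})
        thr = make_residue("THR", {"OG1": (5.0, 0, 0)}, res_seq=2)
        water = Residue("A", 901, "HOH", [Atom("O", "O", np.asarray(water_xyz, float))])
        from gtcore.structure_io import StructureModel

        frame = StructureModel(pdb_id="f", chains={"A": [asp, thr, water]})
        return frame, asp, thr

    def test_bridging_water_reported(self):
        frame, asp, thr = self._system((2.5, 0, 0))  # 2.5 from OD1, 2.5 from OG1
        assert water_bridge(frame, asp, thr) == ["A:901"]

    def test_distant_water_excluded(self):
        frame, asp, thr = self._system((-4.0, 0, 0))
        assert water_bridge(frame, asp, thr) == []

    def test_partner_without_hydroxyl_rejected(self):
        frame, asp, _ = self._system((2.5, 0, 0))
        leu = make_residue("LEU", {"CB": (5, 0, 0)}, res_seq=3)
        with pytest.raises(ValueError, match="hydroxyl"):
            water_bridge(frame, asp, leu)

    def test_trajectory_bridge_in_din_frames_only(self):
        text, truth = syn.make_trajectory(schedule=0.5, n_frames=40, sigma_angle=10.0, seed=7)
        fs = read_trajectory(text)
        for frame, state in zip(fs, truth["states"]):
            asp = frame.get_residue("A", syn.ASP_RES_SEQ)
            thr = frame.get_residue("A", syn.THR_RES_SEQ)
            found = water_bridge(frame, asp, thr)
            assert bool(found) == (state == State.D_IN.value)

    def test_single_bridging_among_bulk(self):
        frame, asp, thr = self._system((2.5, 0, 0))
        rng = np.random.default_rng(8)
        for k in range(5):
            frame.chains["A"].append(
                Residue("A", 910 + k, "HOH", [Atom("O", "O", rng.uniform(20, 60, 3))])
            )
        assert water_bridge(frame, asp, thr) == ["A:901"]
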