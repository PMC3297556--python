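import numpy as np
import pytest

from tcrdyn.model_io import Selection, Trajectory
from tcrdyn.motion import (
    DirectionSummary,
    MotionSeries,
    cleft_axis,
    docking_angle_difference,
    mhc_plane_normal,
    motion_direction,
    tcr_motion_series,
)
from tcrdyn.synthetic import gen_rocking_complex

from .conftest import make_ca_chain, random_rotation

M_SEL = Selection.make(chains=["M"])
T_SEL = Selection.make(chains=["T"])


class TestCleftAxis:
    def _chain_at(self, points, chain="A"):
        base = make_ca_chain(len(points), chain_id=chain)
        return Trajectory(base.topology, np.asarray(points, float)[None])

    def test_collinear_along_x(self):
        pts = np.column_stack([np.arange(13.0) * 3.8, np.zeros(13), np.zeros(13)])
        traj = self._chain_at(pts)
        np.testing.assert_allclose(cleft_axis(traj, Selection.make(names=["CA"])), [1, 0, 0], atol=1e-9)

    def test_orientation_follows_residue_order(self):
        pts = np.column_stack([-np.arange(13.0) * 3.8, np.zeros(13), np.zeros(13)])
        traj = self._chain_at(pts)
        np.testing.assert_allclose(cleft_axis(traj, Selection.make(names=["CA"])), [-1, 0, 0], atol=1e-9)

    def test_bulged_arc_matches_covariance_eigenvector_oracle(self):
        t = np.linspace(0, np.pi, 13)
        pts = np.column_stack([np.linspace(0, 30, 13), np.zeros(13), 4 * np.sin(t)])
        traj = self._chain_at(pts)
        axis = cleft_axis(traj, Selection.make(names=["CA"]))
        centered = pts - pts.mean(0)
        w, v = np.linalg.eigh(centered.T @ centered)
        oracle = v[:, np.argmax(w)]
        if np.dot(oracle, pts[-1] - pts[0]) < 0:
            oracle = -oracle
        np.testing.assert_allclose(axis, oracle, atol=1e-9)

    def test_too_few_atoms_errors(self):
        traj = self._chain_at(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            cleft_axis(traj, Selection.make(names=["CA"]))


class TestMotionSeries:
    def test_static_trajectory_zero_angles(self):
        traj = gen_rocking_complex(0.0, n_frames=20, seed=1)
        series = tcr_motion_series(traj, M_SEL, T_SEL)
        np.testing.assert_allclose(series.angles, 0.0, atol=1e-7)

    def test_rocking_amplitude_and_axis_recovered(self):
        traj = gen_rocking_complex(12.0, axis=(0, 0, 1), period=100, n_frames=100, seed=2)
        series = tcr_motion_series(traj, M_SEL, T_SEL)
        assert series.max_angle == pytest.approx(12.0, abs=0.01)
        assert series.max_angle_frame == 25
        axis = series.axes[series.max_angle_frame]
        angle_to_z = np.degrees(np.arccos(np.clip(abs(axis @ [0, 0, 1]), -1, 1)))
        assert angle_to_z < 1.0

    def test_whole_complex_rigid_motion_gives_zero(self):
        rng = np.random.default_rng(7)
        traj = gen_rocking_complex(0.0, n_frames=10, seed=3)
        moved = traj.coords.copy()
        for f in range(traj.n_frames):
            R = random_rotation(rng)
            moved[f] = traj.coords[f] @ R.T + rng.standard_normal(3) * 15
        series = tcr_motion_series(Trajectory(traj.topology, moved), M_SEL, T_SEL)
        np.testing.assert_allclose(series.angles, 0.0, atol=1e-6)

    def test_invariant_under_uniform_rigid_transform(self):
        rng = np.random.default_rng(11)
        traj = gen_rocking_complex(8.0, period=40, n_frames=40, seed=4)
        base = tcr_motion_series(traj, M_SEL, T_SEL)
        R = random_rotation(rng)
        shift = rng.standard_normal(3) * 20
        moved = traj.coords @ R.T + shift
        series = tcr_motion_series(Trajectory(traj.topology, moved), M_SEL, T_SEL)
        np.testing.assert_allclose(series.angles, base.angles, atol=1e-6)

    def test_amplitude_recovery_across_random_axes(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            amp = rng.uniform(2.0, 30.0)
            traj = gen_rocking_complex(amp, axis=tuple(axis), period=40, n_frames=40,
                                       seed=int(rng.integers(1e6)))
            series = tcr_motion_series(traj, M_SEL, T_SEL)
            assert series.max_angle == pytest.approx(amp, abs=0.01)

    def test_shifted_pivot_changes_displacement_not_angle(self):
        t1 = gen_rocking_complex(10.0, period=40, n_frames=40, pivot=(0, 0, 0), seed=5)
        t2 = gen_rocking_complex(10.0, period=40, n_frames=40, pivot=(30, 0, 0), seed=5)
        s1 = tcr_motion_series(t1, M_SEL, T_SEL)
        s2 = tcr_motion_series(t2, M_SEL, T_SEL)
        np.testing.assert_allclose(s1.angles, s2.angles, atol=1e-7)
        assert np.abs(s1.displacements - s2.displacements).max() > 0.5

    def test_overlapping_selections_error(self):
        traj = gen_rocking_complex(5.0, n_frames=5, seed=6)
        with pytest.raises(ValueError):
            tcr_motion_series(traj, Selection.make(), T_SEL)

    def test_csv_columns(self, tmp_path):
        traj = gen_rocking_complex(5.0, period=20, n_frames=20, seed=8)
        series = tcr_motion_series(traj, M_SEL, T_SEL, cleft=np.array([1.0, 0, 0]))
        out = tmp_path / "motion.csv"
        series.to_csv(out)
        header = [l for l in out.read_text().splitlines() if not l.startswith("#")][0]
        assert header == "frame,angle_deg,axis_x,axis_y,axis_z,disp_par_A,disp_perp_A"


def _series_with_displacements(disp):
    disp = np.asarray(disp, float)
    F = disp.shape[0]
    return MotionSeries(
        angles=np.zeros(F),
        axes=np.tile([1.0, 0, 0], (F, 1)),
        displacements=disp,
    )


class TestMotionDirection:
    CLEFT = np.array([1.0, 0.0, 0.0])

    def test_pure_parallel(self):
        s = _series_with_displacements(np.outer(np.linspace(-2, 2, 9), self.CLEFT))
        out = motion_direction(s, self.CLEFT)
        assert out.parallel_fraction == pytest.approx(1.0)
        assert out.label == "parallel"

    def test_pure_orthogonal(self):
        perp = np.array([0.0, 1.0, 0.0])
        s = _series_with_displacements(np.outer(np.linspace(-2, 2, 9), perp))
        out = motion_direction(s, self.CLEFT)
        assert out.parallel_fraction == pytest.approx(0.0)
        assert out.label == "orthogonal"

    def test_static_label(self):
        s = _series_with_displacements(np.zeros((5, 3)))
        assert motion_direction(s, self.CLEFT).label == "static"

    def test_random_isotropic_is_mixed(self):
        # Monte-Carlo expectation: E|d·u| equal along any in-plane direction
        rng = np.random.default_rng(3)
        disp = rng.standard_normal((4000, 3))
        out = motion_direction(_series_with_displacements(disp), self.CLEFT,
                               plane_normal=np.array([0.0, 0.0, 1.0]))
        # in-plane isotropy: E|x| / (E|x| + E|y|) = 0.5
        assert out.parallel_fraction == pytest.approx(0.5, abs=0.05)
        assert out.label == "mixed"

    def test_out_of_plane_component_ignored(self):
        d = np.tile([0.0, 0.0, 5.0], (6, 1))
        d[:, 0] = 1.0
        out = motion_direction(_series_with_displacements(d), self.CLEFT,
                               plane_normal=np.array([0.0, 0.0, 1.0]))
        assert out.parallel_fraction == pytest.approx(1.0)


class TestDockingAngleDifference:
    def test_self_is_zero(self):
        traj = gen_rocking_complex(0.0, n_frames=1, seed=9)
        angle = docking_angle_difference(traj, traj, M_SEL, T_SEL)
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_construct_and_recover_12deg(self):
        base = gen_rocking_complex(0.0, n_frames=1, seed=10)
        theta = np.radians(12.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        coords = base.coords.copy()
        tcr_idx = T_SEL.resolve(base.topology)
        pivot = coords[0, tcr_idx].mean(axis=0)
        coords[0, tcr_idx] = (coords[0, tcr_idx] - pivot) @ R.T + pivot
        rotated = Trajectory(base.topology, coords)
        angle = docking_angle_difference(base, rotated, M_SEL, T_SEL)
        assert angle == pytest.approx(12.0, abs=1e-3)

    def test_symmetry(self):
        base = gen_rocking_complex(0.0, n_frames=1, seed=12)
        rng = np.random.default_rng(0)
        coords = base.coords.copy()
        tcr_idx = T_SEL.resolve(base.topology)
        R = random_rotation(rng)
        pivot = coords[0, tcr_idx].mean(axis=0)
        coords[0, tcr_idx] = (coords[0, tcr_idx] - pivot) @ R.T + pivot
        other = Trajectory(base.topology, coords)
        ab = docking_angle_difference(base, other, M_SEL, T_SEL)
        ba = docking_angle_difference(other, base, M_SEL, T_SEL)
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_plane_normal_is_unit_third_axis(self):
        traj = gen_rocking_complex(0.0, n_frames=1, seed=14)
        n = mhc_plane_normal(traj, M_SEL)
        assert np.linalg.norm(n) == pytest.approx(1.0)
        # MHC slab lies near z = 0, so the thin axis is ~z
        assert abs(n @ [0, 0, 1]) > 0.95
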