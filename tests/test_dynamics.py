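import numpy as np
import pytest

from mtmesh.dynamics import (
    ConstraintSet,
    SimConfig,
    SimulationDivergedError,
    build_state,
    compile_constraints,
    export_trajectory,
    simulate,
    step,
)
from mtmesh.metrics import pair_gap
from mtmesh.model import (
    Filament,
    FilamentNetworkModel,
    build_aster_network,
    build_motility_element,
)


def single_filament(mass=1.0):
    return FilamentNetworkModel(
        filaments=[Filament("F0", np.zeros(3), np.array([4.0, 0, 0]), 0.1, mass=mass)],
        units="sim",
    )


class TestCompile:
    def test_motility_element_constraint_counts(self):
        cs = compile_constraints(build_motility_element())
        assert cs.counts() == {"rod": 2, "piston": 2, "hub": 2, "joint": 0, "motor": 2}

    def test_single_filament_rod_only(self):
        cs = compile_constraints(single_filament())
        assert cs.counts() == {"rod": 1, "piston": 0, "hub": 0, "joint": 0, "motor": 0}

    def test_aster3_closed_has_three_joints(self):
        cs = compile_constraints(build_aster_network(3, "closed"))
        assert cs.counts()["joint"] == 3

    def test_body_count_guard(self):
        m = build_aster_network(10, "closed")
        with pytest.raises(Exception):
            compile_constraints(m, SimConfig(max_bodies=10))


class TestStep:
    def test_unconstrained_ballistic_advance(self):
        cfg = SimConfig(damping_filament=0.0, damping_head=0.0)
        state = build_state(single_filament(), cfg)
        state.velocities[:] = [1.0, 0.0, 0.0]
        out = step(state, ConstraintSet(), cfg, frame=0)
        expected = np.tile([1.0 / 24.0, 0.0, 0.0], (2, 1))
        np.testing.assert_allclose(out.positions - state.positions, expected, atol=1e-12)

    def test_damping_definition_over_one_second(self):
        # a head-class body coasting force-free for 1 s keeps (1-0.4) of speed
        cfg = SimConfig(damping_head=0.4, damping_filament=0.4)
        state = build_state(single_filament(), cfg)
        state.velocities[:] = [2.0, 0.0, 0.0]
        for frame in range(24):
            state = step(state, ConstraintSet(), cfg, frame)
        assert state.velocities[0, 0] == pytest.approx(2.0 * 0.6, abs=1e-9)

    def test_motor_walks_closed_form_on_pinned_filament(self):
        """Head on an immobile filament walks exactly motor_speed * t minus-ward."""
        fil = Filament("F0", np.zeros(3), np.array([4.0, 0, 0]), 0.1, mass=np.inf)
        from mtmesh.model import KinesinHead, KinesinMultimer

        start_arc = 3.0
        lk = KinesinMultimer(
            "K0",
            hub=np.array([3.0, 0.0, 0.0]),
            heads=[KinesinHead("F0", start_arc, np.array([3.0, 0.0, 0.0]))],
            arm_length=1e-9,
        )
        # free-floating hub with negligible arm: does not impede the walk
        m = FilamentNetworkModel(filaments=[fil], linkers=[lk], units="sim")
        n_frames = 200  # 200/24 s = 8.333 s
        cfg = SimConfig(n_frames=n_frames, damping_head=0.0, damping_filament=0.0)
        traj = simulate(m, cfg)
        head_idx = traj.labels.index("K0:head0")
        arc = traj.positions[-1, head_idx, 0]  # filament lies along +x from 0
        expected = start_arc - 0.3 * (n_frames / 24.0)
        assert arc == pytest.approx(expected, abs=1e-6)

    def test_divergence_names_body(self):
        cfg = SimConfig()
        state = build_state(single_filament(), cfg)
        state.velocities[0] = [np.inf, 0, 0]
        with pytest.raises(SimulationDivergedError, match="F0"):
            step(state, ConstraintSet(), cfg, frame=0)


class TestSimulate:
    @pytest.fixture(scope="class")
    def motility_traj(self):
        return simulate(build_motility_element(), SimConfig())

    def test_frame_count_includes_initial_state(self, motility_traj):
        assert motility_traj.positions.shape[0] == 201

    def test_element_contracts(self, motility_traj):
        gap = pair_gap(motility_traj, "A", "B")
        assert gap[-1] < gap[0]

    def test_gap_decreases_monotonically_while_motor_drives_approach(self, motility_traj):
        """Until the filaments come abreast (~frame 120 for the default
        overlap), each frame pulls the midpoints strictly closer."""
        gap = pair_gap(motility_traj, "A", "B")
        crossing = int(np.argmin(gap))
        assert crossing > 100
        d = np.diff(gap[5:crossing])
        assert np.all(d < 0)

    def test_structural_residuals_within_tolerance(self, motility_traj):
        res = motility_traj.residuals
        for cls in ("rod", "piston", "hub", "joint"):
            assert res[cls].max() <= 1e-6

    def test_rod_rigidity_every_frame(self, motility_traj):
        for fid, (im, ip) in motility_traj.filament_particles.items():
            lengths = np.linalg.norm(
                motility_traj.positions[:, ip] - motility_traj.positions[:, im], axis=1
            )
            np.testing.assert_allclose(lengths, 4.0, atol=1e-6)

    def test_motor_speed_zero_is_static(self):
        traj = simulate(build_motility_element(), SimConfig(motor_speed=0.0))
        np.testing.assert_allclose(
            traj.positions[-1], traj.positions[0], atol=1e-6
        )

    def test_deterministic(self):
        t1 = simulate(build_motility_element(), SimConfig(n_frames=50))
        t2 = simulate(build_motility_element(), SimConfig(n_frames=50))
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_mirror_symmetry_of_midpoint_trajectories(self, motility_traj):
        """Equal masses: the two filament midpoints approach the element
        center as mirror images."""
        ia = motility_traj.filament_particles["A"]
        ib = motility_traj.filament_particles["B"]
        ma = 0.5 * (motility_traj.positions[:, ia[0]] + motility_traj.positions[:, ia[1]])
        mb = 0.5 * (motility_traj.positions[:, ib[0]] + motility_traj.positions[:, ib[1]])
        # mirror: 180 deg rotation about z through the origin
        np.testing.assert_allclose(ma[:, :2], -mb[:, :2], atol=1e-6)

    def test_negative_control_without_piston_does_not_contract(self):
        traj = simulate(build_motility_element(), SimConfig(), disable=("piston",))
        gap = pair_gap(traj, "A", "B")
        assert gap[-1] >= gap[0] - 1e-9
        assert gap.min() >= gap[0] - 1e-9

    def test_momentum_conserved_without_damping(self):
        cfg = SimConfig(damping_head=0.0, damping_filament=0.0, n_frames=50)
        model = build_aster_network(3, "closed")
        state = build_state(model, cfg)
        rng = np.random.default_rng(3)
        state.velocities[:] = rng.normal(0, 0.2, state.velocities.shape)
        cs = compile_constraints(model, cfg)
        p0 = (state.masses[:, None] * state.velocities).sum(axis=0)
        for frame in range(50):
            state = step(state, cs, cfg, frame)
            p = (state.masses[:, None] * state.velocities).sum(axis=0)
            np.testing.assert_allclose(p, p0, atol=1e-9)

    def test_aster3_residuals_within_tolerance(self):
        traj = simulate(build_aster_network(3, "closed"), SimConfig(n_frames=60))
        for cls in ("rod", "piston", "hub", "joint"):
            assert traj.residuals[cls].max() <= 1e-6


class TestExport:
    def test_csv_round_trip(self, tmp_path):
        traj = simulate(build_motility_element(), SimConfig(n_frames=10))
        path = tmp_path / "traj.csv"
        export_trajectory(traj, path, format="csv")
        import pandas as pd

        df = pd.read_csv(path)
        n_bodies = traj.positions.shape[1]
        assert len(df) == 11 * n_bodies
        stored = df[df["frame"] == 10][["x", "y", "z"]].to_numpy()
        np.testing.assert_allclose(stored, traj.positions[10], atol=1e-9)

    def test_obj_sequence_one_file_per_frame(self, tmp_path):
        model = build_motility_element()
        traj = simulate(model, SimConfig(n_frames=4))
        outdir = tmp_path / "frames"
        export_trajectory(traj, outdir, format="obj-sequence", model=model)
        assert len(list(outdir.glob("frame_*.obj"))) == 5
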