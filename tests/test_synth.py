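import numpy as np
import pandas as pd
import pytest

from pitbind.kinetics import KineticParams
from pitbind.synth import (
    STATE_BOUND,
    STATE_FREE,
    AcquisitionSchedule,
    PitGeometry,
    SpeciesParams,
    render_video,
    simulate_gel_lane,
    simulate_population,
    simulate_trajectories,
)


@pytest.fixture
def small_scene():
    geom = PitGeometry(n_pits=2)
    sched = AcquisitionSchedule(
        frames_per_video=15, video_interval=300.0, total_duration=1800.0
    )
    sp = SpeciesParams(n_probes_per_pit=5, n_plasmids_per_pit=5)
    kin = KineticParams(P0=100.0, U0=20.0, K=1e-3)
    return geom, sched, sp, kin


class TestTypes:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            PitGeometry(diameter=0.0)
        with pytest.raises(ValueError):
            PitGeometry(pitch=2.0, diameter=3.0)
        with pytest.raises(ValueError):
            PitGeometry(n_pits=0)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule(intra_video_interval=0.01, exposure=0.05)
        with pytest.raises(ValueError):
            AcquisitionSchedule(frames_per_video=10_000, video_interval=60.0)
        assert AcquisitionSchedule().n_videos == 120

    def test_species_invariants(self):
        with pytest.raises(ValueError):
            SpeciesParams(d_free=1.0, d_bound=2.0)
        with pytest.raises(ValueError):
            SpeciesParams(psf_sigma=0.0)

    def test_pit_centers_spacing(self):
        geom = PitGeometry(n_pits=4, pitch=5.0)
        c = geom.pit_centers()
        assert c.shape == (4, 2)
        d01 = np.hypot(*(c[1] - c[0]))
        assert d01 == pytest.approx(5.0)


class TestSimulateTrajectories:
    def test_columns_and_sorting(self, small_scene):
        traj, truth = simulate_trajectories(*small_scene, seed=1)
        assert list(traj.columns) == [
            "molecule_id",
            "video_index",
            "frame",
            "t_s",
            "x_um",
            "y_um",
            "pit_id",
            "state",
        ]
        assert truth.n_probes == 10
        per_mol = traj.groupby("molecule_id")["t_s"].is_monotonic_increasing
        assert per_mol.all()

    def test_no_trajectory_exits_pit(self, small_scene):
        geom, sched, sp, kin = small_scene
        traj, _ = simulate_trajectories(geom, sched, sp, kin, seed=2)
        centers = geom.pit_centers()
        r = np.hypot(
            traj["x_um"].to_numpy() - centers[traj["pit_id"], 0],
            traj["y_um"].to_numpy() - centers[traj["pit_id"], 1],
        )
        assert np.all(r <= geom.radius + 1e-9)

    def test_bound_count_nondecreasing(self, small_scene):
        traj, _ = simulate_trajectories(*small_scene, seed=3)
        bound_per_video = (
            traj[traj["frame"] == 0]
            .groupby("video_index")["state"]
            .apply(lambda s: (s == STATE_BOUND).sum())
        )
        assert np.all(np.diff(bound_per_video.to_numpy()) >= 0)

    def test_u0_zero_no_binding(self, small_scene):
        geom, sched, sp, _ = small_scene
        kin = KineticParams(P0=100.0, U0=0.0, K=1e-3)
        traj, truth = simulate_trajectories(geom, sched, sp, kin, seed=4)
        assert truth.binding_times == {}
        assert (traj["state"] == STATE_FREE).all()

    def test_u0_above_p0_rejected(self, small_scene):
        geom, sched, sp, _ = small_scene
        with pytest.raises(ValueError):
            simulate_trajectories(
                geom, sched, sp, KineticParams(P0=100.0, U0=101.0, K=1e-3), seed=0
            )

    def test_bit_identical_under_seed(self, small_scene):
        t1, _ = simulate_trajectories(*small_scene, seed=7)
        t2, _ = simulate_trajectories(*small_scene, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self, small_scene):
        t1, _ = simulate_trajectories(*small_scene, seed=7)
        t2, _ = simulate_trajectories(*small_scene, seed=8)
        assert not t1["x_um"].equals(t2["x_um"])

    def test_ensemble_bound_fraction_matches_model(self):
        # mean bound count over many independent pits tracks
        # U0*(1-exp(-K t)) within 3 standard errors
        geom = PitGeometry(n_pits=120)
        sched = AcquisitionSchedule(
            frames_per_video=2, video_interval=600.0, total_duration=3600.0
        )
        sp = SpeciesParams(n_probes_per_pit=10, n_plasmids_per_pit=10)
        kin = KineticParams(P0=100.0, U0=20.0, K=1e-3)
        traj, truth = simulate_trajectories(geom, sched, sp, kin, seed=5)
        first = traj[traj["frame"] == 0]
        for v, grp in first.groupby("video_index"):
            t = grp["t_s"].iloc[0]
            pit_bound = grp.groupby("pit_id")["state"].apply(
                lambda s: (s == STATE_BOUND).mean()
            )
            mean = 100.0 * pit_bound.mean()
            se = 100.0 * pit_bound.std(ddof=1) / np.sqrt(len(pit_bound))
            expected = kin.bound_at(t)
            assert abs(mean - expected) <= 3.0 * se + 1e-9


class TestSimulatePopulation:
    def test_zero_diffusion_constant_positions(self):
        pos = simulate_population(5, 20, 0.05, 0.0, seed=1, radius=1.5)
        assert np.allclose(pos, pos[:, :1, :])

    def test_unconfined_msd_matches_4dt(self):
        # ensemble MSD at lag L ~ 4*D*L*dt within 3 SE
        d_true, dt, n_steps, n_mol = 1.0, 0.05, 1000, 300
        pos = simulate_population(n_mol, n_steps, dt, d_true, seed=2, radius=None)
        for lag in (1, 4):
            disp = pos[:, lag:, :] - pos[:, :-lag, :]
            per_mol = np.mean(np.sum(disp**2, axis=2), axis=1)
            mean = per_mol.mean()
            se = per_mol.std(ddof=1) / np.sqrt(n_mol)
            assert abs(mean - 4.0 * d_true * lag * dt) <= 3.0 * se

    def test_confined_msd_plateau(self):
        # long-lag ensemble MSD saturates below 2*R^2
        radius = 1.0
        pos = simulate_population(400, 200, 0.05, 5.0, seed=3, radius=radius)
        long_lag = 100
        disp = pos[:, long_lag:, :] - pos[:, :-long_lag, :]
        plateau = np.mean(np.sum(disp**2, axis=2))
        assert plateau <= 2.0 * radius**2
        assert plateau > 0.5 * radius**2  # sanity: genuinely mixed

    def test_never_exits_disc(self):
        pos = simulate_population(100, 300, 0.1, 20.0, seed=4, radius=1.5)
        r = np.hypot(pos[..., 0], pos[..., 1])
        assert np.all(r <= 1.5 + 1e-9)


class TestRenderVideo:
    def _still_scene(self, x_um, y_um, state=STATE_BOUND):
        geom = PitGeometry(n_pits=1)
        sched = AcquisitionSchedule(
            frames_per_video=5, video_interval=60.0, total_duration=60.0
        )
        sp = SpeciesParams(
            d_free=2.0, d_bound=0.0, photons_per_frame=2000.0, background_photons=5.0
        )
        traj = pd.DataFrame(
            {
                "molecule_id": 0,
                "video_index": 0,
                "frame": np.arange(5),
                "t_s": np.arange(5) * 0.05,
                "x_um": x_um,
                "y_um": y_um,
                "pit_id": 0,
                "state": state,
            }
        )
        return traj, geom, sp, sched

    def test_zero_emitters_mean_is_background(self):
        traj, geom, sp, sched = self._still_scene(2.5, 2.5)
        empty = traj.iloc[0:0]
        stack = render_video(empty, geom, sp, sched, video_index=0, seed=1)
        assert stack.mean() == pytest.approx(sp.background_photons, rel=0.05)

    def test_stationary_emitter_argmax_at_pixel(self):
        traj, geom, sp, sched = self._still_scene(2.5, 2.5)
        stack = render_video(
            traj, geom, sp, sched, video_index=0, seed=1, noise=False, n_substeps=1
        )
        iy, ix = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert ix == pytest.approx(2.5 / sp.pixel_size, abs=1)
        assert iy == pytest.approx(2.5 / sp.pixel_size, abs=1)

    def test_motion_blur_spreads_fast_emitter(self):
        from pitbind.track import DetectionParams, detect_spots

        traj, geom, sp, sched = self._still_scene(2.5, 2.5, state=STATE_FREE)
        sp_fast = SpeciesParams(
            d_free=20.0,
            d_bound=0.0,
            photons_per_frame=5000.0,
            background_photons=5.0,
        )
        still = render_video(
            traj, geom, sp_fast, sched, video_index=0, seed=2, noise=False, n_substeps=1
        )
        blurred = render_video(
            traj, geom, sp_fast, sched, video_index=0, seed=2, noise=False, n_substeps=16
        )
        params = DetectionParams(pixel_size=sp_fast.pixel_size, threshold_sd=3.0)
        w_still = detect_spots(still[:1], params)["width_um"]
        w_blur = detect_spots(blurred[:1], params)["width_um"]
        assert w_blur.mean() > w_still.mean()

    def test_uint16_output(self):
        traj, geom, sp, sched = self._still_scene(2.5, 2.5)
        stack = render_video(traj, geom, sp, sched, video_index=0, seed=3)
        assert stack.dtype == np.uint16
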