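"""Brownian simulator: diffusion law, bleach model, rendering, determinism."""

import numpy as np
import pytest

from linefrap.model import BeamParameters, InvalidParameterError, recovery_fraction
from linefrap.simulate import (
    FREE_DYE,
    IMMOBILE,
    CameraModel,
    SimulationConfig,
    Species,
    apply_line_bleach,
    bleach_survival_probability,
    brute_force_recovery,
    generate_dataset,
    make_domain_map,
    render_frames,
    simulate_trajectories,
)


def free_config(D=1.0, count=10_000, box=60.0, n_frames=11, interval=0.1,
                seed=0, **kw):
    return SimulationConfig(
        box=box, species=(Species(D=D, count=count),),
        beam=BeamParameters(K0=0.5, r0e=1.0, r0c=0.25),
        n_frames=n_frames, frame_interval=interval, bleach_after_frame=2,
        camera=CameraModel(photons_per_particle=None), seed=seed, **kw,
    )


class TestTrajectories:
    def test_msd_follows_4dt(self):
        # free 2D diffusion: MSD(t) = 4 D t within sampling tolerance
        cfg = free_config(D=1.0, count=10_000, box=60.0, seed=3)
        traj = simulate_trajectories(cfg)
        disp = traj.positions - traj.positions[0]
        msd = np.mean(np.sum(disp**2, axis=2), axis=1)
        t = cfg.times()
        slope = np.polyfit(t[1:], msd[1:], 1)[0]
        assert slope == pytest.approx(4.0, rel=0.03)

    def test_immobile_species_never_moves(self):
        cfg = SimulationConfig(
            box=12.0,
            species=(Species(D=1.0, count=100),
                     Species(D=1.0, count=50, label=IMMOBILE)),
            beam=BeamParameters(K0=0.5, r0e=1.0, r0c=0.25),
            n_frames=6, frame_interval=0.1, bleach_after_frame=2,
            camera=CameraModel(photons_per_particle=None), seed=1,
        )
        traj = simulate_trajectories(cfg)
        imm = traj.species_of == 1
        np.testing.assert_array_equal(traj.positions[0][imm],
                                      traj.positions[-1][imm])

    def test_obstacles_slow_long_time_diffusion(self):
        # effective D from the MSD slope strictly below the free value
        msds = {}
        for frac in (0.0, 0.3):
            dm = make_domain_map(12.0, frac, seed=5)
            cfg = free_config(D=1.0, count=4_000, box=12.0, n_frames=11,
                              interval=0.2, seed=7, domain_map=dm, dt=0.01)
            traj = simulate_trajectories(cfg)
            disp = traj.positions - traj.positions[0]
            msd = np.mean(np.sum(disp**2, axis=2), axis=1)
            msds[frac] = np.polyfit(cfg.times()[1:], msd[1:], 1)[0]
        assert msds[0.3] < 0.85 * msds[0.0]

    def test_obstructed_particles_stay_outside_discs(self):
        dm = make_domain_map(12.0, 0.35, seed=5)
        cfg = free_config(D=1.0, count=2_000, box=12.0, n_frames=6,
                          interval=0.2, seed=9, domain_map=dm, dt=0.01)
        traj = simulate_trajectories(cfg)
        for f in (0, 3, 5):
            assert not np.any(dm.contains(traj.positions[f]))

    def test_determinism_under_seed(self):
        a = simulate_trajectories(free_config(count=500, seed=11))
        b = simulate_trajectories(free_config(count=500, seed=11))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_coarse_dt_rejected_for_obstructed_runs(self):
        dm = make_domain_map(12.0, 0.2, seed=0)
        with pytest.raises(InvalidParameterError, match="dt"):
            free_config(D=10.0, count=100, box=12.0, domain_map=dm, dt=0.01)


class TestDomainMap:
    def test_realized_area_fraction_matches_request(self):
        for frac in (0.05, 0.2, 0.35, 0.5):
            dm = make_domain_map(12.0, frac, seed=2)
            assert dm.area_fraction == pytest.approx(frac, rel=0.02)

    def test_discs_do_not_overlap(self):
        dm = make_domain_map(12.0, 0.5, seed=3)
        centers = dm.centers.reshape(-1, 2)
        d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * dm.radius

    def test_zero_fraction_means_no_domains(self):
        assert make_domain_map(12.0, 0.0) is None


class TestLineBleach:
    def test_no_dose_no_bleach(self):
        pos = np.random.default_rng(0).uniform(0, 12, (1000, 2))
        beam = BeamParameters(K0=0.0, r0e=1.0, r0c=0.25)
        bleached, p = apply_line_bleach(pos, beam, 6.0, seed=1)
        assert not bleached.any()
        np.testing.assert_allclose(p, 1.0)

    def test_on_line_bleach_probability(self):
        beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)
        p = bleach_survival_probability(np.array([6.0]), beam, 6.0)
        assert 1 - p[0] == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_initial_dip_matches_closed_form(self):
        # ensemble ROI fluorescence right after the bleach vs Eq.-level
        # prediction at t = 0, 1e5 particles
        cfg = free_config(D=1.0, count=100_000, box=12.0, seed=13)
        traj = simulate_trajectories(cfg)
        _, p = apply_line_bleach(traj.positions[3], cfg.beam,
                                 cfg.bleach_line_y, seed=4)
        curve = brute_force_recovery(traj, p)
        expect = recovery_fraction(0.0, 1.0, cfg.beam)
        assert curve.values[0] == pytest.approx(expect, abs=0.01)


class TestBruteForceRecovery:
    def test_no_bleach_gives_constant_unity(self):
        cfg = free_config(count=5_000, box=12.0, seed=2)
        traj = simulate_trajectories(cfg)
        curve = brute_force_recovery(traj, np.ones(5_000))
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_matches_closed_form_for_free_diffusion(self):
        # the central oracle check at a single grid point
        cfg = free_config(D=1.0, count=100_000, box=12.0, n_frames=23,
                          interval=0.2, seed=17)
        traj = simulate_trajectories(cfg)
        _, p = apply_line_bleach(traj.positions[3], cfg.beam,
                                 cfg.bleach_line_y, seed=8)
        curve = brute_force_recovery(traj, p)
        pred = recovery_fraction(curve.times, 1.0, cfg.beam)
        assert np.max(np.abs(curve.values - pred)) < 0.02

    def test_immobile_fraction_limits_the_plateau(self):
        # 30% immobile: the long-time level is F_post0 + 0.7 (1 - F_post0).
        # A wide box and long horizon keep the finite-pool depletion of
        # bleached mobile dye (which the infinite-plane model ignores) and
        # the residual t^-1/2 recovery tail jointly below the tolerance.
        n_mob, n_imm = 70_000, 30_000
        cfg = SimulationConfig(
            box=40.0,
            species=(Species(D=3.0, count=n_mob),
                     Species(D=3.0, count=n_imm, label=IMMOBILE)),
            beam=BeamParameters(K0=0.5, r0e=1.0, r0c=0.25),
            frame_times=(0.0, 0.3, 0.6) + tuple(0.9 + np.geomspace(0.1, 220.0, 25)),
            bleach_after_frame=2,
            camera=CameraModel(photons_per_particle=None), seed=19,
        )
        traj = simulate_trajectories(cfg)
        _, p = apply_line_bleach(traj.positions[3], cfg.beam,
                                 cfg.bleach_line_y, seed=5)
        curve = brute_force_recovery(traj, p)
        f0 = float(recovery_fraction(0.0, 3.0, cfg.beam))
        expect = f0 + 0.7 * (1 - f0)
        assert np.mean(curve.values[-5:]) == pytest.approx(expect, abs=0.02)


class TestRendering:
    def test_noise_free_roi_mean_equals_ground_truth(self,
                                                     small_noiseless_dataset):
        _, stack, gt, gt_curve = small_noiseless_dataset
        frames = stack.frames.astype(float)
        roi = gt.roi
        trace = frames[:, roi["row"], roi["col_start"]:roi["col_end"]].mean(axis=1)
        first_post = gt.bleach_after_frame + 1
        vals = trace[first_post:] / trace[:first_post].mean()
        np.testing.assert_allclose(vals, gt_curve.values, atol=1e-6)

    def test_photon_doubling_halves_relative_noise(self):
        # sqrt(2) law on replicate seeds
        base = free_config(count=20_000, box=12.0, n_frames=5, seed=23)
        traj = simulate_trajectories(base)
        bleached = np.zeros(20_000, dtype=bool)
        noises = {}
        for photons in (50.0, 100.0):
            reps = []
            for s in range(4):
                cam = CameraModel(pixel_size=0.1, photons_per_particle=photons,
                                  read_noise=0.0)
                stack = render_frames(traj, bleached, cam, seed=100 + s)
                clean = render_frames(traj, bleached,
                                      CameraModel(photons_per_particle=None))
                rel = (stack.frames.astype(float) / photons
                       - clean.frames) / np.maximum(clean.frames, 1e-9)
                sel = clean.frames > 2.0
                reps.append(np.std(rel[sel]))
            noises[photons] = np.mean(reps)
        assert noises[100.0] == pytest.approx(noises[50.0] / np.sqrt(2),
                                              rel=0.10)

    def test_expected_photons_conserved_across_frames(self,
                                                      small_noiseless_dataset):
        _, stack, _, _ = small_noiseless_dataset
        totals = stack.frames.sum(axis=(1, 2))
        # pre-bleach frames: all particles present, total mass conserved
        assert totals[0] == pytest.approx(totals[2], rel=1e-3)


class TestGenerateDataset:
    def test_regeneration_is_bit_exact(self, tmp_path):
        cfg = free_config(count=3_000, box=12.0, n_frames=6, seed=29)
        cfg = SimulationConfig(**{**cfg.__dict__, "camera":
                                  CameraModel(pixel_size=0.1,
                                              photons_per_particle=80.0)})
        _, _, _, paths1 = generate_dataset(cfg, tmp_path / "a")
        _, _, _, paths2 = generate_dataset(cfg, tmp_path / "b")
        assert paths1["stack"].read_bytes() == paths2["stack"].read_bytes()
        assert paths1["manifest"].read_text() == paths2["manifest"].read_text()
        assert paths1["curve"].read_text() == paths2["curve"].read_text()

    def test_manifest_carries_ground_truth(self, tmp_path):
        import json
        cfg = free_config(count=2_000, box=12.0, n_frames=6, seed=31)
        _, gt, _, paths = generate_dataset(cfg, tmp_path)
        man = json.loads(paths["manifest"].read_text())
        assert man["ground_truth"]["K0"] == cfg.beam.K0
        assert man["ground_truth"]["n_bleached"] == gt.n_bleached
        assert len(man["ground_truth"]["roi_curve"]["times"]) == 3
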