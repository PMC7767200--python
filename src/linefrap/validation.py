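"""Desk-scale validation experiments.

Each function re-runs one verification experiment from scratch — closed-form
series against a high-precision reference, closed form against the Brownian
simulator, parameter recovery on noisy curves, the engineered
temperature/gel condition series, and the rendering/extraction identity —
and returns the measured quantities.  They are the backing computations for
``scripts/acceptance.py`` and the acceptance test suite.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

import math
import tempfile
from decimal import Decimal, getcontext
from pathlib import Path

import numpy as np

from .analysis import run_batch, trend_test
from .fitting import FitOptions, fit_line_frap
from .images import LineROI, extract_recovery_curve
from .model import (
    BeamParameters,
    DiffusionComponent,
    MultiComponentModel,
    recovery_fraction,
)
from .simulate import (
    CameraModel,
    SimulationConfig,
    Species,
    apply_line_bleach,
    brute_force_recovery,
    gel_series,
    generate_dataset,
    simulate_trajectories,
    synthesize_noisy_curves,
    temperature_series,
)

__all__ = [
    "high_precision_series",
    "series_vs_high_precision",
    "series_vs_simulator",
    "parameter_recovery",
    "condition_series_trends",
    "pipeline_identity",
]


def high_precision_series(t, D, K0, r0e, r0c, n_terms: int = 50) -> float:
    """Reference evaluation of the recovery series with 50-digit decimal
    arithmetic, straight from the factorial definition (independent of the
    recursive float implementation in :mod:`linefrap.model`)."""
    getcontext().prec = 50
    t, D, K0, r0e, r0c = (Decimal(str(v)) for v in (t, D, K0, r0e, r0c))
    total = Decimal(0)
    for n in range(n_terms):
        radicand = n * r0c**2 + r0e**2 + 8 * n * D * t
        total += (-K0) ** n / Decimal(math.factorial(n)) * r0e / radicand.sqrt()
    return float(total)


def series_vs_high_precision() -> dict:
    """Max |implementation - 50-term decimal reference| over a 3x3x3 grid
    of (K0, D, t)."""
    r0e, r0c = 1.0, 0.25
    worst = 0.0
    n = 0
    for K0 in (0.1, 0.5, 2.0):
        beam = BeamParameters(K0=K0, r0e=r0e, r0c=r0c)
        for D in (0.3, 1.0, 3.0):
            for t in (0.1, 1.0, 10.0):
                ref = high_precision_series(t, D, K0, r0e, r0c)
                got = recovery_fraction(t, D, beam)
                worst = max(worst, abs(got - ref))
                n += 1
    return {"max_abs_err": worst, "n": n}


def series_vs_simulator(seed: int = 0, n_particles: int = 100_000) -> dict:
    """Max |closed form - brute-force simulator| over K0 in {0.1, 0.5} x
    D in {0.3, 1, 3} um^2/s, measured on the PSF-weighted ROI recovery of
    ``n_particles`` Brownian particles (variance-reduced survival weights)."""
    rng = np.random.SeedSequence(seed)
    worst = 0.0
    for K0 in (0.1, 0.5):
        for D in (0.3, 1.0, 3.0):
            s_traj, s_bleach = [
                int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(2)
            ]
            beam = BeamParameters(K0=K0, r0e=1.0, r0c=0.25)
            cfg = SimulationConfig(
                box=12.0, species=(Species(D=D, count=n_particles),),
                beam=beam, n_frames=23, frame_interval=0.2,
                bleach_after_frame=2,
                camera=CameraModel(photons_per_particle=None), seed=s_traj,
            )
            traj = simulate_trajectories(cfg)
            _, p = apply_line_bleach(
                traj.positions[3], beam, cfg.bleach_line_y, s_bleach)
            curve = brute_force_recovery(traj, p)
            pred = recovery_fraction(curve.times, D, beam)
            worst = max(worst, float(np.max(np.abs(curve.values - pred))))
    return {"max_abs_dev": worst, "n": n_particles}


def parameter_recovery(seed: int = 0, n_replicates: int = 12) -> dict:
    """Recover D from seeded noisy curves (~2% Poisson noise per point).

    Single component: D = 1 um^2/s, 50 points.  Two components: D = 30 and
    1 um^2/s at weights 0.4/0.6 (the fast free-dye / slow membrane
    structure), 80 points with dense early sampling.  Reports the median
    fitted coefficients across replicates.
    """
    beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)

    t1 = np.concatenate([[0.0], np.geomspace(0.02, 20.0, 49)])
    m1 = MultiComponentModel(components=(DiffusionComponent(1.0),), beam=beam)
    curves = synthesize_noisy_curves(m1, t1, n_replicates, seed=seed)
    d1 = [fit_line_frap(c, beam, FitOptions(n_components=1)).components[0].D
          for c in curves]

    t2 = np.concatenate([[0.0], np.geomspace(5e-4, 20.0, 79)])
    m2 = MultiComponentModel(
        components=(DiffusionComponent(30.0, 0.4),
                    DiffusionComponent(1.0, 0.6)),
        beam=beam)
    curves2 = synthesize_noisy_curves(m2, t2, n_replicates, seed=seed + 1)
    fast, slow = [], []
    for c in curves2:
        fit = fit_line_frap(c, beam, FitOptions(n_components=2))
        fast.append(fit.components[0].D)
        slow.append(fit.components[1].D)
    return {
        "single_median_D": float(np.median(d1)),
        "single_true_D": 1.0,
        "two_comp_median_fast_D": float(np.median(fast)),
        "two_comp_true_fast_D": 30.0,
        "two_comp_median_slow_D": float(np.median(slow)),
        "two_comp_true_slow_D": 1.0,
        "n": n_replicates,
    }


def condition_series_trends(seed: int = 0, n_curves: int = 12,
                            out_dir: str | Path | None = None) -> dict:
    """Run both engineered condition series end to end.

    The cholesterol-like series (domain fractions 0.35/0.20/0.05 at nominal
    22/30/38 C) must show rising membrane D; the gel-like series
    (heterogeneous ROI placement, fractions 0.5/0.1 mixed at every
    temperature) must not.  Returns per-condition means and both verdicts.
    """
    beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)
    base = Path(out_dir) if out_dir else Path(tempfile.mkdtemp())
    out = {}

    man_t = temperature_series(base / "temperature", seed=seed,
                               n_curves=n_curves)
    batch_t = run_batch(man_t, beam)
    rep_t = trend_test(batch_t)
    for s in sorted(batch_t.summaries, key=lambda s: s.temperature_C):
        out[f"mean_membrane_D_{s.temperature_C:g}C"] = s.mean_D
        out[f"n_{s.temperature_C:g}C"] = s.n
    out["temperature_verdict"] = rep_t.verdict
    out["temperature_tau"] = rep_t.statistic
    out["means_strictly_increasing"] = rep_t.monotone_means

    man_g = gel_series(base / "gel", seed=seed + 1, n_curves=n_curves)
    batch_g = run_batch(man_g, beam)
    rep_g = trend_test(batch_g)
    out["gel_verdict"] = rep_g.verdict
    out["gel_tau"] = rep_g.statistic
    out["gel_within_condition_sd"] = float(np.mean(
        [s.sd_D for s in batch_g.summaries if s.sd_D is not None]))
    out["n_curves_per_condition"] = n_curves
    return out


def pipeline_identity(seed: int = 0, n_particles: int = 1_000_000,
                      n_replicates: int = 12) -> dict:
    """Noise-free rendering round trip.

    Renders replicate single-species stacks (D = 1 um^2/s, K0 = 1) in the
    bleach-ensemble expected-image limit and re-extracts each ROI curve with
    the production pipeline.  The extraction identity (curve equals the
    generator's ground truth to float precision) is checked on every
    replicate.  The extracted curves are then averaged — replicate bleach
    series averaged before fitting, as standard in FRAP practice — and the
    mean curve is fitted: each single acquisition carries ~2-3% realization
    noise from the bleached-region particle configuration, which the
    replicate average brings well inside the comparison band.
    """
    beam = BeamParameters(K0=1.0, r0e=1.0, r0c=0.25)
    seq = np.random.SeedSequence(seed)
    identity_dev = 0.0
    curves = []
    for sub in seq.spawn(n_replicates):
        s = int(sub.generate_state(1)[0] % 2**31)
        cfg = SimulationConfig(
            box=10.0, species=(Species(D=1.0, count=n_particles),),
            beam=beam, n_frames=33, frame_interval=0.1, bleach_after_frame=7,
            camera=CameraModel(photons_per_particle=None), seed=s,
        )
        stack, gt, gt_curve, _ = generate_dataset(cfg)
        curve = extract_recovery_curve(stack, LineROI(**gt.roi))
        identity_dev = max(identity_dev, float(
            np.max(np.abs(curve.values - gt_curve.values))))
        curves.append(curve)
    from .fitting import RecoveryCurve
    mean_curve = RecoveryCurve(
        times=curves[0].times,
        values=np.mean([c.values for c in curves], axis=0),
        meta={"n_replicates": n_replicates},
    )
    fit = fit_line_frap(mean_curve, beam, FitOptions(n_components=1))
    return {
        "identity_max_abs_dev": identity_dev,
        "fit_D": fit.components[0].D,
        "true_D": 1.0,
        "fit_D_rel_err_pct": 100.0 * abs(fit.components[0].D - 1.0),
        "n": n_particles * n_replicates,
    }
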