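"""Fit line-FRAP recovery curves and extract diffusion coefficients.

Two backends are provided and deliberately kept comparable:

* :func:`fit_line_frap` — nonlinear least squares of the closed-form
  multi-component recovery model (with mobile fraction) against a curve,
  multi-started over a log-spaced grid of diffusion coefficients.
* :func:`fit_double_exponential` — the empirical double-exponential fit
  ``F(t) = plateau - A1*exp(-l1*t) - A2*exp(-l2*t)``, whose rates are
  converted to diffusion coefficients by the line-FRAP timescale
  ``D = lambda * r0e^2 / 8`` (:func:`rates_to_diffusion`).

In membrane experiments the fitted fast component usually reflects free
fluorophore in the buffer above the membrane rather than lipid diffusion;
:func:`classify_components` separates it by a configurable threshold so that
only membrane components enter downstream aggregation.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from .model import (
    BeamParameters,
    DiffusionComponent,
    InvalidParameterError,
    MultiComponentModel,
    SeriesSettings,
    multi_component_recovery,
)

__all__ = [
    "RecoveryCurve",
    "FitResult",
    "FitOptions",
    "DoubleExpResult",
    "TooFewPointsError",
    "DegenerateCurveError",
    "fit_line_frap",
    "fit_double_exponential",
    "rates_to_diffusion",
    "classify_components",
    "MEMBRANE",
    "FREE_DYE",
]

MEMBRANE = "membrane"
FREE_DYE = "free_dye"


class TooFewPointsError(ValueError):
    """Curve has too few post-bleach samples for the requested model."""


class DegenerateCurveError(ValueError):
    """Curve carries no usable recovery signal (e.g. constant)."""


@dataclass
class RecoveryCurve:
    """A normalized recovery curve: F(t)/F_pre at post-bleach times.

    ``times`` are seconds since bleach (strictly increasing, first = 0);
    ``values`` are background-subtracted intensities divided by the
    pre-bleach mean ``F_pre``.  ``meta`` carries acquisition context
    (frame interval, condition label, source file).
    """

    times: np.ndarray
    values: np.ndarray
    F_pre: float = 1.0
    meta: dict = field(default_factory=dict)
    require_bleach: bool = True  # oracle curves may legitimately start at 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a recovery curve needs at least 2 samples")
        if self.times[0] != 0.0:
            raise ValueError("times must start at 0 (first post-bleach sample)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not (self.F_pre > 0):
            raise ValueError("F_pre must be > 0")
        if self.require_bleach and self.values[0] >= 1.0:
            raise ValueError(
                "values[0] must be < 1: no bleach detectable at t = 0"
            )

    # -- plain-text round trip -------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write the curve as CSV with header (time_s, F_norm)."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "F_norm": self.values}).to_csv(
            path, index=False, float_format="%.10g"
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "RecoveryCurve":
        """Read a curve written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        if not {"time_s", "F_norm"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns time_s, F_norm")
        m = {"source_file": str(path)}
        m.update(meta)
        return cls(df["time_s"].to_numpy(), df["F_norm"].to_numpy(), meta=m)


@dataclass
class FitOptions:
    """Controls for :func:`fit_line_frap`.

    ``init_grid`` is the log-spaced set of starting diffusion coefficients
    (crossed across components for multi-component fits); ``fix_beam`` holds
    K0/r0e/r0c at their calibration values (co-fitting K0 otherwise);
    ``seed`` drives the deterministic jitter applied to extra starts.

    ``fast_D_min`` (two-component fits only) partitions the D range at a
    known value: the fast component is bounded below and the slow component
    above by it.  This encodes an independent calibration — e.g. free dye in
    buffer is known to diffuse faster than any membrane probe — and
    stabilizes the otherwise weakly identifiable two-component
    decomposition; leave None for an unconstrained fit.
    """

    n_components: int = 1
    fix_beam: bool = True
    D_bounds: tuple[float, float] = (1e-3, 1e4)
    init_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    max_iter: int = 1000
    seed: int = 0
    fast_D_min: float | None = None

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if not (self.D_bounds[0] > 0 and self.D_bounds[1] > self.D_bounds[0]):
            raise ValueError("D_bounds must satisfy 0 < min < max")


@dataclass
class FitResult:
    """Outcome of a closed-form or double-exponential recovery fit.

    ``components`` are sorted by descending D.  ``stderr`` maps parameter
    names to standard errors from the local Gauss-Newton curvature at the
    optimum; absent entries mean the curvature was singular there.
    """

    components: list[DiffusionComponent]
    K0_hat: float
    k_hat: float
    F_post0_hat: float
    residual_rms: float
    stderr: dict[str, float]
    converged: bool
    backend: str
    n_points: int
    at_boundary: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: -c.D)
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "components": [
                {"D_um2_s": c.D, "weight": c.weight} for c in self.components
            ],
            "K0_hat": self.K0_hat,
            "k_hat": self.k_hat,
            "F_post0_hat": self.F_post0_hat,
            "residual_rms": self.residual_rms,
            "stderr": dict(sorted(self.stderr.items())),
            "converged": self.converged,
            "backend": self.backend,
            "n_points": self.n_points,
            "at_boundary": self.at_boundary,
            "meta": self.meta,
        }
        return d


def _model_values(t, params, beam: BeamParameters, n_comp: int, settings):
    v = params.valuesdict()
    comps = []
    if n_comp == 1:
        comps.append(DiffusionComponent(D=10.0 ** v["logD1"], weight=1.0))
    else:
        w1 = v["w1"]
        comps.append(DiffusionComponent(D=10.0 ** v["logD1"], weight=w1))
        comps.append(DiffusionComponent(D=10.0 ** v["logD2"], weight=1.0 - w1))
    beam_eff = BeamParameters(K0=v.get("K0", beam.K0), r0e=beam.r0e, r0c=beam.r0c)
    model = MultiComponentModel(
        components=tuple(comps), beam=beam_eff, k=v["k"], F_post0=v["F_post0"]
    )
    return multi_component_recovery(t, model, settings)


def fit_line_frap(
    curve: RecoveryCurve,
    beam: BeamParameters,
    options: FitOptions | None = None,
    settings: SeriesSettings | None = None,
) -> FitResult:
    """Weighted least-squares fit of the closed-form recovery model.

    Multi-starts over ``options.init_grid`` (crossed over components for
    two-component fits); the best objective wins, ties broken by the smaller
    total ``|log10 D|``.  Requires >= 8 samples for one component, >= 15 for
    two.  A diffusion coefficient landing on ``D_bounds`` sets
    ``at_boundary`` (the aggregation layer excludes such fits).
    """
    options = options or FitOptions()
    settings = settings or SeriesSettings()
    n_comp = options.n_components
    min_pts = 8 if n_comp == 1 else 15
    if len(curve.times) < min_pts:
        raise TooFewPointsError(
            f"{n_comp}-component fit needs >= {min_pts} samples, "
            f"got {len(curve.times)}"
        )

    t, y = curve.times, curve.values
    lo, hi = np.log10(options.D_bounds[0]), np.log10(options.D_bounds[1])
    split = None
    if options.fast_D_min is not None and n_comp == 2:
        split = np.log10(options.fast_D_min)
        if not (lo < split < hi):
            raise ValueError("fast_D_min must lie inside D_bounds")
    f0_init = float(np.clip(y[0], 1e-3, 0.999))
    plateau = float(np.clip(np.mean(y[-max(3, len(y) // 10):]), f0_init + 1e-3, 1.0))

    def make_params(logDs):
        p = lmfit.Parameters()
        p.add("logD1", value=logDs[0], min=split if split is not None else lo,
              max=hi)
        if n_comp == 2:
            p.add("logD2", value=logDs[1], min=lo,
                  max=split if split is not None else hi)
            p.add("w1", value=0.5 if split is None else 0.25, min=0.0, max=1.0)
        p.add("k", value=min(1.0, (plateau - f0_init) / max(1e-6, 1 - f0_init) + 0.1),
              min=0.0, max=1.0)
        p.add("F_post0", value=f0_init, min=1e-4, max=1.0)
        if not options.fix_beam:
            p.add("K0", value=max(beam.K0, 0.05), min=0.0, max=10.0)
        return p

    def residual(params):
        try:
            return _model_values(t, params, beam, n_comp, settings) - y
        except (InvalidParameterError, ArithmeticError):
            return np.full_like(y, 1e6)

    grid = [np.log10(g) for g in options.init_grid]
    if n_comp == 1:
        starts = [(g,) for g in grid]
    elif split is not None:
        fast = sorted({max(g, split + 0.1) for g in grid})
        slow = sorted({min(g, split - 0.1) for g in grid})
        starts = list(itertools.product(fast, slow))
    else:
        starts = [(a, b) for a, b in itertools.product(grid, grid) if a >= b]
    rng = np.random.default_rng(options.seed)
    starts = [tuple(np.clip(s + rng.normal(0, 1e-3, len(s)), lo, hi)) for s in starts]

    best = None
    for s in starts:
        try:
            res = lmfit.minimize(
                residual, make_params(list(s)), method="least_squares",
                max_nfev=options.max_iter,
            )
        except Exception:
            continue
        cost = float(np.sum(res.residual**2))
        key = (cost, sum(abs(res.params[n].value)
                         for n in res.params if n.startswith("logD")))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise RuntimeError("all fit starts failed")

    res = best[1]
    v = res.params.valuesdict()
    if n_comp == 1:
        comps = [DiffusionComponent(D=10.0 ** v["logD1"], weight=1.0)]
    else:
        comps = [
            DiffusionComponent(D=10.0 ** v["logD1"], weight=float(v["w1"])),
            DiffusionComponent(D=10.0 ** v["logD2"], weight=float(1 - v["w1"])),
        ]
    eps = 1e-6
    at_boundary = any(
        res.params[n].value <= lo + eps or res.params[n].value >= hi - eps
        for n in res.params if n.startswith("logD")
    )
    degenerate = False
    if n_comp == 2 and comps[1].D > 0 and comps[0].D / comps[1].D < 2.0:
        degenerate = True
        warnings.warn(
            "two-component fit returned coefficients within a factor 2; the "
            "decomposition is not identifiable", stacklevel=2,
        )
    stderr = {}
    for name, par in res.params.items():
        if par.stderr is not None and np.isfinite(par.stderr):
            stderr[name] = float(par.stderr)
    return FitResult(
        components=comps,
        K0_hat=float(v.get("K0", beam.K0)),
        k_hat=float(v["k"]),
        F_post0_hat=float(v["F_post0"]),
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        stderr=stderr,
        converged=bool(res.success),
        backend="closed_form",
        n_points=len(t),
        at_boundary=at_boundary,
        meta={**curve.meta, **({"degenerate_components": True} if degenerate
                               else {})},
    )


@dataclass
class DoubleExpResult:
    """Empirical double-exponential fit: ``plateau - A1 e^{-l1 t} - A2 e^{-l2 t}``.

    ``rates`` are 1/s, sorted fast-first unless the fit is degenerate, in
    which case the significant component is first and ``single_component``
    is set.
    """

    amplitudes: tuple[float, float]
    rates: tuple[float, float]
    plateau: float
    residual_rms: float
    converged: bool
    single_component: bool = False


def fit_double_exponential(curve: RecoveryCurve) -> DoubleExpResult:
    """Fit the empirical double-exponential recovery.

    Initialized from a log-linear regression of the approach to plateau on
    the tail (slow rate) and of the residual on the head (fast rate).
    Degenerate inputs (no recovery) raise :class:`DegenerateCurveError`;
    rate collapse (l1/l2 < 1.5) flags the result ``single_component``.
    """
    if len(curve.times) < 10:
        raise TooFewPointsError("double-exponential fit needs >= 10 samples")
    t, y = curve.times, curve.values
    span = float(np.max(y) - np.min(y))
    noise = float(np.std(np.diff(y))) / np.sqrt(2.0) if len(y) > 2 else 0.0
    if span < max(1e-12, 3.0 * noise) or span < 1e-4:
        raise DegenerateCurveError("curve shows no recovery to fit")

    plateau0 = float(np.mean(y[-max(3, len(y) // 5):]))
    # tail log-linear regression for the slow rate
    deficit = np.clip(plateau0 + 1e-12 - y, 1e-12, None)
    tail = slice(len(y) // 3, None)
    good = deficit[tail] > max(1e-10, 0.02 * span)
    if good.sum() >= 3:
        slope, intercept = np.polyfit(t[tail][good], np.log(deficit[tail][good]), 1)
        lam_slow = max(1e-6, -slope)
        a_slow = float(np.exp(intercept))
    else:
        lam_slow = 1.0 / max(t[-1], 1e-6)
        a_slow = span
    lam_fast0 = 10.0 * lam_slow
    a_fast0 = max(1e-6, span - a_slow)

    def model(t, A1, l1, A2, l2, plateau):
        return plateau - A1 * np.exp(-l1 * t) - A2 * np.exp(-l2 * t)

    res = None
    for factor in (3.0, 10.0, 30.0):  # multi-start over the fast-rate guess
        p = lmfit.Parameters()
        p.add("A1", value=a_fast0, min=0.0, max=2.0)
        p.add("l1", value=factor * lam_slow, min=1e-8, max=1e6)
        p.add("A2", value=min(a_slow, 2.0), min=0.0, max=2.0)
        p.add("l2", value=lam_slow, min=1e-8, max=1e6)
        p.add("plateau", value=plateau0, min=0.0, max=1.5)
        trial = lmfit.minimize(
            lambda pp: model(t, **pp.valuesdict()) - y, p,
            method="least_squares",
        )
        if res is None or np.sum(trial.residual**2) < np.sum(res.residual**2):
            res = trial
    v = res.params.valuesdict()
    pairs = [(v["A1"], v["l1"]), (v["A2"], v["l2"])]
    pairs.sort(key=lambda p_: -p_[1])  # fast rate first
    (A1, l1), (A2, l2) = pairs
    single = False
    amp_total = A1 + A2
    if amp_total > 0 and min(A1, A2) < 0.01 * amp_total:
        single = True
        if A1 < A2:  # put the significant component first
            (A1, l1), (A2, l2) = (A2, l2), (A1, l1)
    elif l2 > 0 and l1 / l2 < 1.5:
        single = True
        warnings.warn("double-exponential rates collapsed; treating as single "
                      "component", stacklevel=2)
    return DoubleExpResult(
        amplitudes=(float(A1), float(A2)),
        rates=(float(l1), float(l2)),
        plateau=float(v["plateau"]),
        residual_rms=float(np.sqrt(np.mean(res.residual**2))),
        converged=bool(res.success),
        single_component=single,
    )


def rates_to_diffusion(
    rates: float | np.ndarray,
    beam: BeamParameters,
    timescale_factor: float = 8.0,
) -> np.ndarray:
    """Convert exponential recovery rates (1/s) to diffusion coefficients.

    Uses the line-FRAP timescale ``8*D*t/r0e^2``, i.e. ``D = lambda *
    r0e^2 / timescale_factor`` with factor 8 by default.  The factor is a
    convention (the empirical exponential is not the exact closed-form
    shape) and is exposed for calibration.
    """
    r = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(r <= 0):
        raise InvalidParameterError("rates must be > 0")
    return r * beam.r0e**2 / timescale_factor


def classify_components(
    fit: FitResult, threshold_D: float = 10.0
) -> list[str]:
    """Label each fitted component ``membrane`` or ``free_dye``.

    Components with ``D > threshold_D`` (um^2/s) are attributed to free
    fluorophore in the buffer and excluded from membrane statistics
    downstream.  Warns if no membrane component remains.
    """
    if not fit.converged:
        raise ValueError("classify_components requires a converged fit")
    labels = [FREE_DYE if c.D > threshold_D else MEMBRANE for c in fit.components]
    if labels and all(lab == FREE_DYE for lab in labels):
        warnings.warn(
            "all fitted components exceed the free-dye threshold; no membrane "
            "component remains", stacklevel=2,
        )
    return labels


def write_fit_report(fit: FitResult, path: str | Path) -> Path:
    """Write a FitResult as deterministic JSON."""
    path = Path(path)
    path.write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n")
    return path
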