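"""Closed-form line-FRAP recovery model.

A line-FRAP experiment bleaches a thin line across a fluorescent membrane
with a Gaussian-profile beam and watches the fluorescence inside the line
ROI return as unbleached molecules diffuse in.  For irreversible first-order
bleaching with peak dose ``K0``, a bleach-line e^-2 radius ``r0e``, an
imaging (detection) e^-2 radius ``r0c`` and lateral diffusion coefficient
``D``, the normalized ROI recovery has the closed series form

    F(t)/F0 = sum_{n>=0} (-K0)^n / n! * r0e * (n*r0c^2 + r0e^2 + 8*n*D*t)^(-1/2)

which this module evaluates with certified truncation, together with its
small-``K0`` first-order approximation and a multi-component / mobile-fraction
extension

    F_obs(t) = F_post0 + k * (M(t) - M(0)),   M(t) = sum_j w_j * F(t; D_j)/F0

where ``k`` is the mobile fraction and ``F_post0`` the observed normalized
fluorescence immediately after the bleach.

Units: lengths in micrometres, times in seconds, D in um^2/s throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeamParameters",
    "SeriesSettings",
    "DiffusionComponent",
    "MultiComponentModel",
    "InvalidParameterError",
    "TruncationError",
    "recovery_fraction",
    "small_k0_approximation",
    "multi_component_recovery",
]


class InvalidParameterError(ValueError):
    """A model parameter is outside its physical domain."""


class TruncationError(ArithmeticError):
    """The recovery series did not converge within ``n_max`` terms.

    Attributes
    ----------
    residual_bound : float
        Magnitude of the first neglected term — an upper bound on the
        truncation error of the returned partial sum (alternating series).
    """

    def __init__(self, message: str, residual_bound: float):
        super().__init__(message)
        self.residual_bound = residual_bound


@dataclass(frozen=True)
class BeamParameters:
    """Optical constants of the bleach and imaging beams.

    Parameters
    ----------
    K0 : float
        Dimensionless peak bleach dose (>= 0).  ``K0 = 0`` means no bleach.
    r0e : float
        e^-2 radius of the Gaussian bleach line profile, um (> 0).
    r0c : float
        e^-2 radius of the imaging PSF, um (>= 0; 0 = ideal detection).
    """

    K0: float
    r0e: float
    r0c: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K0 >= 0.0):
            raise InvalidParameterError(f"K0 must be >= 0, got {self.K0}")
        if not (self.r0e > 0.0):
            raise InvalidParameterError(f"r0e must be > 0, got {self.r0e}")
        if not (self.r0c >= 0.0):
            raise InvalidParameterError(f"r0c must be >= 0, got {self.r0c}")


@dataclass(frozen=True)
class SeriesSettings:
    """Truncation control for the recovery series.

    ``rel_tol`` stops the summation once the next term's magnitude falls
    below ``rel_tol`` times the current partial sum; ``n_max`` caps the
    summation index.  The defaults certify ~1e-10 truncation error for all
    practically relevant doses (K0 <~ 5).
    """

    rel_tol: float = 1e-10
    n_max: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.rel_tol < 1.0):
            raise InvalidParameterError(f"rel_tol must be in (0, 1), got {self.rel_tol}")
        if self.n_max < 1:
            raise InvalidParameterError(f"n_max must be >= 1, got {self.n_max}")


@dataclass(frozen=True)
class DiffusionComponent:
    """One diffusing species: coefficient ``D`` (um^2/s) and its fraction of
    the mobile signal (``weight`` in [0, 1])."""

    D: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.D > 0.0):
            raise InvalidParameterError(f"D must be > 0, got {self.D}")
        if not (0.0 <= self.weight <= 1.0):
            raise InvalidParameterError(f"weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class MultiComponentModel:
    """Multi-species recovery with a mobile fraction.

    ``components`` weights must sum to 1; ``k`` is the mobile fraction
    (k = 1: full recovery; k = 0: frozen at ``F_post0``); ``F_post0`` is the
    observed normalized fluorescence at the first post-bleach sample.
    """

    components: tuple[DiffusionComponent, ...]
    beam: BeamParameters
    k: float = 1.0
    F_post0: float | None = None  # None -> use the model's own M(0)

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise InvalidParameterError("at least one diffusion component required")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"component weights must sum to 1, got {total}")
        if not (0.0 <= self.k <= 1.0):
            raise InvalidParameterError(f"mobile fraction k must be in [0, 1], got {self.k}")
        if self.F_post0 is not None and not (0.0 < self.F_post0 <= 1.0):
            raise InvalidParameterError(f"F_post0 must be in (0, 1], got {self.F_post0}")


_DEFAULT_SETTINGS = SeriesSettings()


def recovery_fraction(
    t: float | np.ndarray,
    D: float,
    beam: BeamParameters,
    settings: SeriesSettings = _DEFAULT_SETTINGS,
) -> float | np.ndarray:
    """Normalized line-FRAP recovery F(t)/F0 for a single diffusing species.

    Evaluates the alternating series term-by-term with the recursive update
    ``term_{n+1} = term_n * (-K0)/(n+1) * sqrt(rad_n / rad_{n+1})`` where
    ``rad_n = n*r0c^2 + r0e^2 + 8*n*D*t`` — no factorials or large powers are
    ever formed, so the sum is overflow-free for any practical ``K0``.

    Parameters
    ----------
    t : float or array
        Time since bleach, s (>= 0).  Vectorized.
    D : float
        Diffusion coefficient, um^2/s (> 0).
    beam, settings
        Optical constants and truncation control.

    Returns
    -------
    float or ndarray
        F(t)/F0 in (0, 1].  Exactly 1.0 when ``K0 = 0``.

    Raises
    ------
    InvalidParameterError
        Negative time, non-positive D, or a negative radicand.
    TruncationError
        The next term still exceeds ``rel_tol`` times the partial sum at
        ``n_max`` (carries the residual bound).
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise InvalidParameterError("t must be finite and >= 0")
    if not (D > 0.0) or not math.isfinite(D):
        raise InvalidParameterError(f"D must be > 0 and finite, got {D}")

    K0, r0e, r0c = beam.K0, beam.r0e, beam.r0c
    if K0 == 0.0:
        out = np.ones_like(t_arr)
        return float(out[0]) if scalar else out

    r0e2, r0c2 = r0e * r0e, r0c * r0c
    eight_dt = 8.0 * D * t_arr

    # n = 0 term: r0e * (r0e^2)^(-1/2) = 1 exactly.
    term = np.ones_like(t_arr)
    total = term.copy()
    rad = np.full_like(t_arr, r0e2)
    converged = np.zeros(t_arr.shape, dtype=bool)

    for n in range(settings.n_max):
        rad_next = (n + 1) * r0c2 + r0e2 + (n + 1) * eight_dt
        if np.any(rad_next <= 0.0):
            raise InvalidParameterError("negative radicand in recovery series")
        term = term * (-K0 / (n + 1)) * np.sqrt(rad / rad_next)
        rad = rad_next
        live = ~converged
        newly = np.abs(term) < settings.rel_tol * np.abs(total)
        total = np.where(live, total + term, total)
        converged |= newly
        if converged.all():
            break
    else:
        residual = float(np.max(np.abs(term[~converged])))
        raise TruncationError(
            f"series not converged after {settings.n_max} terms "
            f"(residual bound {residual:.3e})",
            residual_bound=residual,
        )

    # Domain check: the physical result lies in (0, 1]; allow only the
    # certified truncation slack before declaring the parameters invalid.
    slack = 10.0 * settings.rel_tol
    if np.any(total <= 0.0) or np.any(total > 1.0 + slack):
        raise InvalidParameterError(
            "recovery series evaluated outside (0, 1]; parameters are outside "
            "the model's validity domain"
        )
    total = np.minimum(total, 1.0)
    return float(total[0]) if scalar else total


def small_k0_approximation(
    t: float | np.ndarray, D: float, beam: BeamParameters
) -> float | np.ndarray:
    """First-order (n <= 1) truncation of the recovery series.

    ``F ~= 1 - K0 * r0e / sqrt(r0c^2 + r0e^2 + 8*D*t)`` — an analytic
    cross-check.  The leading neglected term is ~K0^2/2 at t = 0, so the
    relative error is ~1% for ``K0 <= 0.13`` and ~2% at ``K0 = 0.2``
    (verified against :func:`recovery_fraction`).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("t must be >= 0")
    if not (D > 0.0):
        raise InvalidParameterError(f"D must be > 0, got {D}")
    out = 1.0 - beam.K0 * beam.r0e / np.sqrt(
        beam.r0c**2 + beam.r0e**2 + 8.0 * D * t_arr
    )
    return float(out) if t_arr.ndim == 0 else out


def _mixture(t, model: MultiComponentModel, settings: SeriesSettings):
    return sum(
        c.weight * recovery_fraction(t, c.D, model.beam, settings)
        for c in model.components
    )


def multi_component_recovery(
    t: float | np.ndarray,
    model: MultiComponentModel,
    settings: SeriesSettings = _DEFAULT_SETTINGS,
) -> float | np.ndarray:
    """Observed recovery for a multi-species model with a mobile fraction.

    ``F_obs(t) = F_post0 + k * (M(t) - M(0))`` with
    ``M(t) = sum_j w_j * recovery_fraction(t, D_j)``.  ``k`` scales only the
    recovering part, so ``k = 0`` pins the signal at ``F_post0`` and ``k = 1``
    with ``F_post0 = M(0)`` reduces to the pure diffusion model.  The long-time
    plateau is ``F_post0 + k * (1 - M(0))``.
    """
    m_t = _mixture(t, model, settings)
    m_0 = _mixture(0.0, model, settings)
    f0 = m_0 if model.F_post0 is None else model.F_post0
    return f0 + model.k * (m_t - m_0)
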