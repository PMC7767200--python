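"""Ground-truthed synthetic line-FRAP data.

Brownian dynamics of labelled lipids in a 2D membrane patch with

* one or more diffusing species (a slow membrane probe, a fast free-dye
  pool standing in for unbound fluorophore in the buffer, and optionally an
  immobile fraction),
* a Gaussian-profile line bleach of peak dose ``K0`` and e^-2 radius
  ``r0e`` applied instantaneously between two frames,
* disc-shaped impermeable gel/ordered domains whose area fraction is the
  knob that emulates temperature-dependent membrane morphology,
* rendering to camera frames through a Gaussian imaging PSF of e^-2 radius
  ``r0c`` with Poisson photon noise and Gaussian read noise.

Every stochastic operation is a pure function of (config, seed), so a
dataset regenerates bit-exactly.  The module provides the *independent*
oracle for the closed-form model: :func:`brute_force_recovery` measures the
ROI recovery directly from particle positions and bleach survival, with no
closed-form expression involved.

Geometry: the box is ``[0, L] x [0, L]`` um with reflecting walls; the
bleach line runs along x at ``y = L/2``; the bleach/detection profiles vary
along y only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numba
import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .model import BeamParameters, InvalidParameterError
from .fitting import RecoveryCurve
from .images import ImageStack, LineROI, extract_recovery_curve, write_stack

__all__ = [
    "Species",
    "CameraModel",
    "SimulationConfig",
    "DomainMap",
    "GroundTruth",
    "Trajectories",
    "make_domain_map",
    "simulate_trajectories",
    "apply_line_bleach",
    "bleach_survival_probability",
    "render_frames",
    "brute_force_recovery",
    "generate_dataset",
    "paper_like_config",
    "synthesize_noisy_curves",
    "MEMBRANE",
    "FREE_DYE",
    "IMMOBILE",
]

MEMBRANE = "membrane"
FREE_DYE = "free_dye"
IMMOBILE = "immobile"


@dataclass(frozen=True)
class Species:
    """One simulated fluorophore population.

    ``label`` controls behaviour: ``membrane`` diffuses and is obstructed by
    gel domains; ``free_dye`` diffuses (fast) but ignores domains — it models
    unbound fluorophore in the buffer above the membrane, flattened into the
    simulation plane; ``immobile`` never moves.
    """

    D: float
    count: int
    label: str = MEMBRANE

    def __post_init__(self) -> None:
        if self.label not in (MEMBRANE, FREE_DYE, IMMOBILE):
            raise InvalidParameterError(f"unknown species label {self.label!r}")
        if self.label != IMMOBILE and not (self.D > 0):
            raise InvalidParameterError("mobile species need D > 0")
        if self.count < 1:
            raise InvalidParameterError("species count must be >= 1")


@dataclass(frozen=True)
class CameraModel:
    """Detector model for rendering: pixel size (um), expected photons per
    unbleached particle per frame, and Gaussian read noise (photons RMS).
    ``photons_per_particle = None`` renders noise-free float frames."""

    pixel_size: float = 0.1
    photons_per_particle: float | None = 200.0
    read_noise: float = 2.0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel_size must be > 0")


@dataclass(frozen=True)
class DomainMap:
    """Impermeable gel/ordered domains: non-overlapping discs on a jittered
    square lattice (one disc per lattice cell, so point-in-domain lookups
    only ever inspect the 3x3 neighbourhood of a cell).

    ``area_fraction`` is realized exactly as ``n_discs * pi R^2 / L^2``.
    """

    centers: np.ndarray          # (ns, ns, 2) disc centers, um
    radius: float                # common disc radius, um
    spacing: float               # lattice pitch, um
    box: float                   # box side, um
    area_fraction: float         # realized
    permeability: float = 0.0    # v1: impermeable only

    @property
    def discs(self) -> list[tuple[tuple[float, float], float]]:
        """Flat list of (center, radius) pairs."""
        flat = self.centers.reshape(-1, 2)
        return [((float(x), float(y)), self.radius) for x, y in flat]

    def _neighbour_centers(self, pts: np.ndarray) -> np.ndarray:
        """Centers of the 9 candidate discs for each point: (M, 9, 2)."""
        ns = self.centers.shape[0]
        cell = np.floor(pts / self.spacing).astype(np.int64)
        offs = np.array([[di, dj] for di in (-1, 0, 1) for dj in (-1, 0, 1)])
        idx = cell[:, None, :] + offs[None, :, :]
        np.clip(idx, 0, ns - 1, out=idx)
        return self.centers[idx[..., 0], idx[..., 1]]

    def nearest_disc(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per point: distance^2 to, and center of, the nearest disc."""
        cand = self._neighbour_centers(pts)
        d2 = np.sum((cand - pts[:, None, :]) ** 2, axis=-1)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        return d2[rows, j], cand[rows, j]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2, _ = self.nearest_disc(pts)
        return d2 < self.radius**2


def make_domain_map(
    box: float,
    area_fraction: float,
    spacing: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> DomainMap | None:
    """Build a jittered-lattice domain map of the requested area fraction.

    The box side is required to be an integer multiple of ``spacing`` so the
    realized fraction equals the request exactly.  ``area_fraction = 0``
    returns None (domain-free membrane).  Fractions up to ~0.6 are
    supported (disc radius must stay below half the pitch).
    """
    if area_fraction == 0.0:
        return None
    if not (0.0 < area_fraction < np.pi / 4):
        raise InvalidParameterError(
            f"area_fraction must be in (0, {np.pi/4:.3f}), got {area_fraction}"
        )
    n_side = int(round(box / spacing))
    if abs(n_side * spacing - box) > 1e-9:
        raise InvalidParameterError("box must be an integer multiple of spacing")
    radius = spacing * np.sqrt(area_fraction / np.pi)
    jitter_max = max(0.0, spacing / 2 - radius - 0.02 * spacing)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = (np.arange(n_side) + 0.5) * spacing
    cx, cy = np.meshgrid(grid, grid, indexing="ij")
    centers = np.stack([cx, cy], axis=-1)
    centers = centers + rng.uniform(-jitter_max, jitter_max, size=centers.shape)
    realized = n_side * n_side * np.pi * radius**2 / box**2
    return DomainMap(
        centers=centers, radius=float(radius), spacing=float(spacing),
        box=float(box), area_fraction=float(realized),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic line-FRAP acquisition.

    ``frame_times`` (s, strictly increasing, arbitrary spacing) override the
    uniform ``n_frames`` x ``frame_interval`` grid; non-uniform grids model
    fast line scanning with geometric time sampling.  The bleach is applied
    instantaneously at the acquisition time of frame ``bleach_after_frame+1``,
    so that frame is exactly t = 0 of the recovery.

    ``dt`` is the sub-step used for species that interact with domain discs;
    unobstructed species advance with a single exact Gaussian increment per
    frame interval.
    """

    box: float
    species: tuple[Species, ...]
    beam: BeamParameters
    n_frames: int = 60
    frame_interval: float = 0.1
    frame_times: tuple[float, ...] | None = None
    bleach_after_frame: int = 2
    dt: float = 0.005
    domain_map: DomainMap | None = None
    camera: CameraModel = field(default_factory=CameraModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.box >= 10.0 * self.beam.r0e):
            raise InvalidParameterError(
                f"box ({self.box} um) must be >= 10 * r0e ({self.beam.r0e} um) "
                "to bound edge effects"
            )
        if self.frame_times is not None:
            object.__setattr__(self, "frame_times", tuple(float(t) for t in self.frame_times))
            ft = np.asarray(self.frame_times)
            if np.any(np.diff(ft) <= 0):
                raise InvalidParameterError("frame_times must be strictly increasing")
            object.__setattr__(self, "n_frames", len(ft))
        if not (0 <= self.bleach_after_frame < self.n_frames - 1):
            raise InvalidParameterError(
                "bleach_after_frame must leave >= 1 pre- and >= 1 post-bleach frame"
            )
        if self.domain_map is not None:
            d_max = max(
                (s.D for s in self.species if s.label == MEMBRANE), default=0.0
            )
            if d_max > 0 and self.dt > self.beam.r0e**2 / (40.0 * d_max):
                raise InvalidParameterError(
                    f"dt = {self.dt} too coarse: obstructed species need "
                    f"dt <= r0e^2/(40 D) = {self.beam.r0e**2/(40*d_max):.4g} s"
                )

    def times(self) -> np.ndarray:
        if self.frame_times is not None:
            return np.asarray(self.frame_times, dtype=float)
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def bleach_line_y(self) -> float:
        return self.box / 2.0


@dataclass
class Trajectories:
    """Per-frame particle positions: ``positions[f, i]`` is (x, y) of
    particle ``i`` at frame ``f``.  ``species_of`` maps particle index to its
    index in ``config.species``."""

    positions: np.ndarray       # (n_frames, N, 2)
    species_of: np.ndarray      # (N,) int
    config: SimulationConfig


def _fold(x: np.ndarray, box: float) -> np.ndarray:
    """Reflect coordinates into [0, box] (method of images; exact for
    reflected Brownian motion observed at discrete times)."""
    m = np.mod(x, 2.0 * box)
    return np.where(m > box, 2.0 * box - m, m)


@numba.njit(cache=True)
def _advance_obstructed_kernel(pos, steps, box, centers, radius, spacing):
    """Sub-stepped propagation with wall folding and mirror reflection off
    impermeable discs.  ``steps`` is (n_sub, M, 2) of pre-drawn Gaussian
    increments (randomness stays outside the kernel for determinism).
    A reflection that lands in another disc or outside the box falls back
    to rejecting the sub-step."""
    n_sub, M = steps.shape[0], pos.shape[0]
    ns = centers.shape[0]
    r2 = radius * radius
    two_box = 2.0 * box
    for s in range(n_sub):
        for i in range(M):
            ox, oy = pos[i, 0], pos[i, 1]
            x = (ox + steps[s, i, 0]) % two_box
            if x > box:
                x = two_box - x
            y = (oy + steps[s, i, 1]) % two_box
            if y > box:
                y = two_box - y
            ci = int(x / spacing)
            cj = int(y / spacing)
            bd2 = 1e30
            bx = 0.0
            by = 0.0
            for di in range(-1, 2):
                ii = min(max(ci + di, 0), ns - 1)
                for dj in range(-1, 2):
                    jj = min(max(cj + dj, 0), ns - 1)
                    dx = x - centers[ii, jj, 0]
                    dy = y - centers[ii, jj, 1]
                    d2 = dx * dx + dy * dy
                    if d2 < bd2:
                        bd2 = d2
                        bx = centers[ii, jj, 0]
                        by = centers[ii, jj, 1]
            if bd2 < r2:
                d = np.sqrt(bd2)
                if d < 1e-12:
                    x, y = ox, oy
                else:
                    rx = bx + (2.0 * radius - d) * (x - bx) / d
                    ry = by + (2.0 * radius - d) * (y - by) / d
                    ok = 0.0 <= rx <= box and 0.0 <= ry <= box
                    if ok:
                        ri = int(rx / spacing)
                        rj = int(ry / spacing)
                        for di in range(-1, 2):
                            ii = min(max(ri + di, 0), ns - 1)
                            for dj in range(-1, 2):
                                jj = min(max(rj + dj, 0), ns - 1)
                                dx = rx - centers[ii, jj, 0]
                                dy = ry - centers[ii, jj, 1]
                                if dx * dx + dy * dy < r2:
                                    ok = False
                    if ok:
                        x, y = rx, ry
                    else:
                        x, y = ox, oy
            pos[i, 0] = x
            pos[i, 1] = y


def _step_obstructed(
    pos: np.ndarray, D: float, total_dt: float, dt: float,
    box: float, domains: DomainMap, rng: np.random.Generator,
) -> np.ndarray:
    """Advance obstructed particles by ``total_dt`` in sub-steps of at most
    ``dt``, reflecting off impermeable discs."""
    n_sub = max(1, int(np.ceil(total_dt / dt)))
    h = total_dt / n_sub
    sigma = np.sqrt(2.0 * D * h)
    steps = rng.normal(0.0, sigma, (n_sub, pos.shape[0], 2))
    pos = np.ascontiguousarray(pos)
    _advance_obstructed_kernel(
        pos, steps, float(domains.box), domains.centers, float(domains.radius),
        float(domains.spacing),
    )
    return pos


def simulate_trajectories(config: SimulationConfig) -> Trajectories:
    """Brownian trajectories for every species at the frame times.

    Mobile particles take 2D Gaussian steps of per-axis variance ``2 D dt``;
    reflecting box walls are applied by coordinate folding (exact at frame
    times); membrane particles additionally reflect off impermeable domain
    discs, which requires the configured sub-step ``dt``.  Species that do
    not see domains advance with one exact increment per frame interval.
    Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times()
    counts = [s.count for s in config.species]
    N = int(np.sum(counts))
    species_of = np.repeat(np.arange(len(config.species)), counts)

    # initial positions: uniform, and outside discs for obstructed species
    pos = rng.uniform(0.0, config.box, size=(N, 2))
    if config.domain_map is not None:
        obstructed = np.isin(
            species_of,
            [i for i, s in enumerate(config.species) if s.label == MEMBRANE],
        )
        bad = obstructed & config.domain_map.contains(pos)
        while np.any(bad):
            pos[bad] = rng.uniform(0.0, config.box, size=(int(bad.sum()), 2))
            bad = obstructed & config.domain_map.contains(pos)

    out = np.empty((len(times), N, 2))
    out[0] = pos
    for f in range(1, len(times)):
        lag = times[f] - times[f - 1]
        for si, sp in enumerate(config.species):
            sel = species_of == si
            if sp.label == IMMOBILE:
                continue
            if sp.label == MEMBRANE and config.domain_map is not None:
                pos[sel] = _step_obstructed(
                    pos[sel], sp.D, lag, config.dt, config.box,
                    config.domain_map, rng,
                )
            else:
                step = rng.normal(0.0, np.sqrt(2.0 * sp.D * lag), (int(sel.sum()), 2))
                pos[sel] = _fold(pos[sel] + step, config.box)
        out[f] = pos
    return Trajectories(positions=out, species_of=species_of, config=config)


def bleach_survival_probability(
    y: np.ndarray, beam: BeamParameters, line_y: float
) -> np.ndarray:
    """Probability that a fluorophore at perpendicular distance ``y - line_y``
    survives a Gaussian line bleach of peak dose ``K0`` and e^-2 radius
    ``r0e``: ``exp(-K0 * exp(-2 (y-line_y)^2 / r0e^2))``."""
    dose = beam.K0 * np.exp(-2.0 * (np.asarray(y) - line_y) ** 2 / beam.r0e**2)
    return np.exp(-dose)


def apply_line_bleach(
    positions: np.ndarray,
    beam: BeamParameters,
    line_y: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Irreversibly bleach particles according to the Gaussian line profile.

    Returns ``(bleached, survival_p)``: a boolean flag per particle (True =
    bleached) drawn Bernoulli from the survival probability, and the
    probability itself (useful as a variance-reduced oracle weight).
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p_survive = bleach_survival_probability(positions[:, 1], beam, line_y)
    bleached = rng.random(len(positions)) >= p_survive
    return bleached, p_survive


def brute_force_recovery(
    traj: Trajectories,
    survival: np.ndarray,
    normalization: str = "per_frame",
) -> RecoveryCurve:
    """ROI recovery measured directly from particle positions — the
    model-free oracle for the closed-form series.

    Each particle contributes its imaging-PSF detection weight
    ``exp(-2 (y - line_y)^2 / r0c^2)`` times its unbleached fluorescence
    ``survival`` (a Bernoulli 0/1 flag, or the survival *probability* for a
    variance-reduced estimate).  ``normalization='per_frame'`` divides each
    frame by the same-frame all-particle weight sum (cancels density shot
    noise; pre-bleach mean is exactly 1); ``'pre_bleach'`` divides by the
    mean pre-bleach signal, as a real measurement would.
    """
    cfg = traj.config
    if cfg.beam.r0c <= 0:
        raise InvalidParameterError("brute_force_recovery needs r0c > 0")
    if normalization not in ("per_frame", "pre_bleach"):
        raise ValueError(f"unknown normalization {normalization!r}")
    s = np.asarray(survival, dtype=float)
    y = traj.positions[:, :, 1]
    w = np.exp(-2.0 * (y - cfg.bleach_line_y) ** 2 / cfg.beam.r0c**2)
    first_post = cfg.bleach_after_frame + 1
    sig = np.empty(cfg.n_frames)
    sig[:first_post] = w[:first_post].sum(axis=1)         # pre-bleach: all alive
    sig[first_post:] = (w[first_post:] * s[None, :]).sum(axis=1)
    if normalization == "per_frame":
        curve = sig / w.sum(axis=1)
        curve[:first_post] = 1.0
    else:
        curve = sig / sig[:first_post].mean()
    times = cfg.times()
    rel_t = times[first_post:] - times[first_post]
    return RecoveryCurve(
        times=rel_t,
        values=curve[first_post:],
        F_pre=float(sig[:first_post].mean()),
        meta={
            "source": "brute_force_recovery",
            "normalization": normalization,
            "seed": cfg.seed,
        },
        require_bleach=False,  # a zero-dose oracle curve is constant 1
    )


def _psf_kernel(pixel_size: float, r0c: float) -> np.ndarray:
    """Pixel-integrated 2D Gaussian PSF (e^-2 radius ``r0c``), unit mass."""
    sigma = max(r0c / 2.0, 1e-6)
    half = int(np.ceil(4.0 * sigma / pixel_size)) + 1
    edges = (np.arange(-half, half + 1 + 1) - 0.5) * pixel_size
    cdf = ndtr(edges / sigma)
    k1 = np.diff(cdf)
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def render_frames(
    traj: Trajectories,
    bleached: np.ndarray,
    camera: CameraModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> ImageStack:
    """Render trajectories to camera frames through the imaging PSF.

    Unbleached particles are binned onto the pixel grid and convolved with a
    pixel-integrated Gaussian spot of e^-2 radius ``r0c``, scaled to
    ``photons_per_particle``; per-pixel Poisson sampling plus Gaussian read
    noise then quantizes to 16-bit.  With ``photons_per_particle = None``
    the noise-free expected image is returned as float32 (arbitrary units).
    Saturation above 1% of pixels is reported in ``stack.meta``.

    ``bleached`` may be a boolean array (one bleach realization: bleached
    particles vanish) or a float array of per-particle *fluorescence
    weights* — e.g. bleach survival probabilities, which render the
    bleach-ensemble expected image (the fully noise-free limit).
    """
    cfg = traj.config
    camera = camera or cfg.camera
    n_px = int(round(cfg.box / camera.pixel_size))
    if abs(n_px * camera.pixel_size - cfg.box) > 1e-9:
        raise InvalidParameterError("box must be an integer number of pixels")
    kernel = _psf_kernel(camera.pixel_size, cfg.beam.r0c)
    edges = np.arange(n_px + 1) * camera.pixel_size
    first_post = cfg.bleach_after_frame + 1
    bleached = np.asarray(bleached)
    if bleached.dtype == bool:
        weights = (~bleached).astype(float)
    else:
        weights = bleached.astype(float)

    noisy = camera.photons_per_particle is not None
    scale = camera.photons_per_particle if noisy else 1.0
    rng = None
    if noisy:
        rng = (np.random.default_rng(seed) if not isinstance(seed, np.random.Generator)
               else seed) if seed is not None else np.random.default_rng(cfg.seed + 1)

    frames = np.empty(
        (cfg.n_frames, n_px, n_px), dtype=np.uint16 if noisy else np.float32
    )
    n_saturated = 0
    for f in range(cfg.n_frames):
        pts = traj.positions[f]
        w = weights if f >= first_post else None
        # image row = y, column = x
        counts, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(edges, edges),
                                      weights=w)
        img = ndimage.convolve(counts * scale, kernel, mode="constant") if kernel.size > 1 else counts * scale
        if noisy:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            img += rng.normal(0.0, camera.read_noise, img.shape)
            img = np.clip(np.rint(img), 0, 65535)
            n_saturated += int(np.sum(img >= 65535))
            frames[f] = img.astype(np.uint16)
        else:
            frames[f] = img.astype(np.float32)

    meta = {"saturated_pixels": n_saturated}
    if noisy and n_saturated > 0.01 * frames.size:
        meta["saturation_warning"] = True
    times = cfg.times()
    interval = float(np.median(np.diff(times)))
    return ImageStack(
        frames=frames,
        frame_interval=interval,
        pixel_size=camera.pixel_size,
        bleach_frame_index=cfg.bleach_after_frame,
        frame_times=times,
        meta=meta,
    )


@dataclass
class GroundTruth:
    """Everything needed to verify — and bit-exactly regenerate — a dataset.

    ``roi_curve`` is the noise-free ROI curve obtained through the same
    rendering + extraction arithmetic as the pipeline (the pipeline-identity
    reference); ``oracle_curve`` is the rendering-free PSF-weighted
    brute-force curve (the physics oracle).
    """

    species: list[dict]
    K0: float
    r0e: float
    r0c: float
    seed: int
    bleach_after_frame: int
    n_bleached: int
    roi: dict
    roi_curve: RecoveryCurve
    oracle_curve: RecoveryCurve
    domain_area_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "K0": self.K0, "r0e": self.r0e, "r0c": self.r0c,
            "seed": self.seed,
            "bleach_after_frame": self.bleach_after_frame,
            "n_bleached": self.n_bleached,
            "roi": self.roi,
            "domain_area_fraction": self.domain_area_fraction,
            "roi_curve": {
                "times": self.roi_curve.times.tolist(),
                "values": self.roi_curve.values.tolist(),
            },
            "oracle_curve": {
                "times": self.oracle_curve.times.tolist(),
                "values": self.oracle_curve.values.tolist(),
            },
        }


def _default_roi(n_px: int, length: int = 100) -> LineROI:
    length = min(length, n_px)
    start = (n_px - length) // 2
    return LineROI(row=n_px // 2, col_start=start, col_end=start + length)


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[ImageStack, GroundTruth, RecoveryCurve, dict[str, Path] | None]:
    """One-call synthetic acquisition: stack + ground truth + noise-free curve.

    Simulates trajectories, applies the bleach, renders a noise-free stack
    (the ground-truth ROI curve is extracted from it with the production
    pipeline) and, if the camera specifies photon counts, a noisy 16-bit
    stack.  When ``out_dir`` is given, writes ``stack.tif`` (+ JSON sidecar),
    ``manifest.json`` (config echo, seed, ground truth) and
    ``curve_truth.csv``; regeneration with the same config + seed is
    bit-exact.
    """
    seq = np.random.SeedSequence(config.seed)
    s_traj, s_bleach, s_noise = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(3)]

    traj = simulate_trajectories(
        SimulationConfig(**{**_config_kwargs(config), "seed": s_traj})
    )
    traj.config = config  # keep the user's config (incl. original seed) attached
    first_post = config.bleach_after_frame + 1
    bleached, p_survive = apply_line_bleach(
        traj.positions[first_post], config.beam, config.bleach_line_y, s_bleach
    )

    # noise-free reference: the bleach-ensemble expected image (survival
    # probabilities as fluorescence weights) — no camera and no bleach shot
    # noise, only the particle configuration itself
    clean_stack = render_frames(
        traj, p_survive,
        CameraModel(pixel_size=config.camera.pixel_size,
                    photons_per_particle=None),
    )
    n_px = clean_stack.frames.shape[1]
    roi = _default_roi(n_px)
    gt_curve = extract_recovery_curve(clean_stack, roi)
    gt_curve.meta["source"] = "noise_free_rendering"
    oracle = brute_force_recovery(traj, p_survive)

    gt = GroundTruth(
        species=[asdict(s) for s in config.species],
        K0=config.beam.K0, r0e=config.beam.r0e, r0c=config.beam.r0c,
        seed=config.seed,
        bleach_after_frame=config.bleach_after_frame,
        n_bleached=int(bleached.sum()),
        roi={"row": roi.row, "col_start": roi.col_start, "col_end": roi.col_end},
        roi_curve=gt_curve,
        oracle_curve=oracle,
        domain_area_fraction=(
            config.domain_map.area_fraction if config.domain_map else 0.0
        ),
    )

    if config.camera.photons_per_particle is not None:
        stack = render_frames(traj, bleached, config.camera, seed=s_noise)
    else:
        stack = clean_stack

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stack_path = write_stack(stack, out_dir / "stack.tif")
        manifest = {
            "config": _config_json(config),
            "ground_truth": gt.to_dict(),
        }
        man_path = out_dir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        curve_path = gt_curve.to_csv(out_dir / "curve_truth.csv")
        paths = {"stack": stack_path, "manifest": man_path, "curve": curve_path}
    return stack, gt, gt_curve, paths


def _config_kwargs(config: SimulationConfig) -> dict:
    return {
        "box": config.box, "species": config.species, "beam": config.beam,
        "n_frames": config.n_frames, "frame_interval": config.frame_interval,
        "frame_times": config.frame_times,
        "bleach_after_frame": config.bleach_after_frame, "dt": config.dt,
        "domain_map": config.domain_map, "camera": config.camera,
        "seed": config.seed,
    }


def _config_json(config: SimulationConfig) -> dict:
    d = _config_kwargs(config)
    d["species"] = [asdict(s) for s in config.species]
    d["beam"] = asdict(config.beam)
    d["camera"] = asdict(config.camera)
    dm = d.pop("domain_map")
    d["domain_map"] = None if dm is None else {
        "radius": dm.radius, "spacing": dm.spacing, "box": dm.box,
        "area_fraction": dm.area_fraction,
        "n_discs": int(dm.centers.shape[0] ** 2),
    }
    return d


def paper_like_config(
    seed: int = 0,
    n_membrane: int = 80_000,
    free_dye_signal_fraction: float = 0.2,
    immobile_fraction: float = 0.0,
    K0: float = 0.5,
    box: float = 12.0,
    n_frames: int = 60,
    frame_interval: float = 0.1,
    domain_area_fraction: float = 0.0,
    camera: CameraModel | None = None,
) -> SimulationConfig:
    """The default study scenario: a slow membrane probe (D = 1 um^2/s)
    plus a fast free-dye pool (D = 30 um^2/s) carrying 20% of the signal —
    the fast-component-to-be-neglected structure — with K0 = 0.5, r0e = 1 um,
    r0c = 0.25 um, 60 frames."""
    mobile_frac = 1.0 - free_dye_signal_fraction - immobile_fraction
    if mobile_frac <= 0:
        raise InvalidParameterError("signal fractions must leave a mobile "
                                    "membrane component")
    n_total = n_membrane / mobile_frac
    n_free = int(round(n_total * free_dye_signal_fraction))
    n_imm = int(round(n_total * immobile_fraction))
    species = [Species(D=1.0, count=n_membrane, label=MEMBRANE)]
    if n_free > 0:
        species.append(Species(D=30.0, count=n_free, label=FREE_DYE))
    if n_imm > 0:
        species.append(Species(D=1.0, count=n_imm, label=IMMOBILE))
    dm = make_domain_map(box, domain_area_fraction, seed=seed + 7) \
        if domain_area_fraction > 0 else None
    return SimulationConfig(
        box=box,
        species=tuple(species),
        beam=BeamParameters(K0=K0, r0e=1.0, r0c=0.25),
        n_frames=n_frames,
        frame_interval=frame_interval,
        bleach_after_frame=2,
        domain_map=dm,
        camera=camera or CameraModel(),
        seed=seed,
    )


def synthesize_noisy_curves(
    model,
    times: np.ndarray,
    n_replicates: int,
    photons_per_point: float = 2500.0,
    seed: int = 0,
    settings=None,
) -> list[RecoveryCurve]:
    """Replicate noisy curves from a forward model via Poisson photon counts.

    Each sample draws ``Poisson(photons_per_point * F(t))`` and renormalizes,
    giving relative noise ``~1/sqrt(photons_per_point)`` per point (2500
    photons ~ 2%).  Used for desk-scale parameter-recovery experiments where
    the fit, not the forward physics, is under test.
    """
    from .model import multi_component_recovery

    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    clean = multi_component_recovery(times, model, settings) if settings \
        else multi_component_recovery(times, model)
    out = []
    for i in range(n_replicates):
        counts = rng.poisson(photons_per_point * clean)
        vals = counts / photons_per_point
        vals[0] = min(vals[0], 0.999)  # keep the bleach-happened invariant
        out.append(RecoveryCurve(times=times, values=vals,
                                 meta={"replicate": i, "seed": seed}))
    return out


# ---------------------------------------------------------------------------
# Condition-series scenarios (membrane morphology emulated by domain fraction)
# ---------------------------------------------------------------------------

def _series_frame_times(
    t_max: float = 6.0, n_post: int = 60, t_first: float = 0.002,
    n_pre: int = 3, pre_interval: float = 0.1,
) -> tuple[float, ...]:
    """Line-scan style time grid: a few uniform pre-bleach frames, then t = 0
    and geometrically spaced post-bleach samples out to ``t_max`` — dense
    early sampling resolves the fast free-dye component."""
    pre = np.arange(n_pre) * pre_interval
    t0 = n_pre * pre_interval
    post = np.concatenate([[0.0], np.geomspace(t_first, t_max, n_post - 1)])
    return tuple(np.concatenate([pre, t0 + post]))


def simulate_condition_curve(
    area_fraction: float,
    seed: int,
    n_membrane: int = 48_000,
    n_free: int = 12_000,
    D_membrane: float = 1.0,
    D_free: float = 30.0,
    K0: float = 1.0,
    box: float = 12.0,
    frame_times: tuple[float, ...] | None = None,
) -> RecoveryCurve:
    """One measured-style recovery curve from a membrane with the given
    gel-domain area fraction: Brownian simulation, Bernoulli bleach flags,
    PSF-weighted ROI signal normalized per frame by the bleach-ignored
    control signal (cancels density shot noise; the pre-bleach mean of the
    resulting series is exactly 1)."""
    seq = np.random.SeedSequence(seed)
    s_dom, s_traj, s_bleach = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(3)]
    dm = make_domain_map(box, area_fraction, seed=s_dom) if area_fraction > 0 else None
    species = [Species(D=D_membrane, count=n_membrane, label=MEMBRANE)]
    if n_free > 0:
        species.append(Species(D=D_free, count=n_free, label=FREE_DYE))
    cfg = SimulationConfig(
        box=box,
        species=tuple(species),
        beam=BeamParameters(K0=K0, r0e=1.0, r0c=0.25),
        frame_times=frame_times or _series_frame_times(),
        bleach_after_frame=2,
        dt=0.01,
        domain_map=dm,
        camera=CameraModel(photons_per_particle=None),
        seed=s_traj,
    )
    traj = simulate_trajectories(cfg)
    bleached, _ = apply_line_bleach(
        traj.positions[cfg.bleach_after_frame + 1], cfg.beam,
        cfg.bleach_line_y, s_bleach,
    )
    curve = brute_force_recovery(
        traj, (~bleached).astype(float), normalization="per_frame"
    )
    curve.meta.update({"area_fraction": area_fraction, "seed": seed})
    return curve


def make_condition_series(
    out_dir: str | Path,
    conditions: list[dict],
    seed: int = 0,
    n_curves: int = 12,
    **curve_kwargs,
) -> Path:
    """Write a condition series as curve CSVs plus a batch manifest.

    ``conditions`` entries: ``{"condition": str, "temperature_C": float,
    "area_fraction": float | list[float]}`` — a list gives each curve its own
    local domain fraction (heterogeneous ROI placement).  Returns the
    manifest path (columns file, condition, temperature_C).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(seed)
    rows = []
    for ci, cond in enumerate(conditions):
        fracs = cond["area_fraction"]
        if np.isscalar(fracs):
            fracs = [float(fracs)] * n_curves
        if len(fracs) != n_curves:
            raise InvalidParameterError(
                "per-curve area_fraction list must have n_curves entries")
        for k, frac in enumerate(fracs):
            s = int(seq.spawn(1)[0].generate_state(1)[0] % 2**31)
            curve = simulate_condition_curve(frac, seed=s, **curve_kwargs)
            name = f"{cond['condition']}_{cond['temperature_C']:g}C_{k:02d}.csv"
            name = name.replace(":", "-").replace(" ", "_")
            curve.to_csv(out_dir / name)
            rows.append({
                "file": name,
                "condition": cond["condition"],
                "temperature_C": cond["temperature_C"],
            })
    import pandas as pd
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def temperature_series(out_dir: str | Path, seed: int = 0,
                       n_curves: int = 12, **kw) -> Path:
    """The cholesterol-membrane scenario: a homogeneous domain distribution
    whose area fraction falls with temperature (0.35 / 0.20 / 0.05 at the
    nominal 22 / 30 / 38 C), producing a genuine diffusion trend."""
    conditions = [
        {"condition": "DOPC-DPPC-chol_2-2-1", "temperature_C": 22.0,
         "area_fraction": 0.35},
        {"condition": "DOPC-DPPC-chol_2-2-1", "temperature_C": 30.0,
         "area_fraction": 0.20},
        {"condition": "DOPC-DPPC-chol_2-2-1", "temperature_C": 38.0,
         "area_fraction": 0.05},
    ]
    return make_condition_series(out_dir, conditions, seed=seed,
                                 n_curves=n_curves, **kw)


def gel_series(out_dir: str | Path, seed: int = 0,
               n_curves: int = 12, **kw) -> Path:
    """The gel-membrane scenario: heterogeneous ROI placement — at every
    nominal temperature half the line scans sit in heavily obstructed
    regions (local fraction 0.5) and half in nearly free ones (0.1) — so
    within-condition scatter swamps any temperature ordering."""
    half = n_curves // 2
    fracs = [0.5] * half + [0.1] * (n_curves - half)
    conditions = [
        {"condition": "DOPC-DPPC_1-1", "temperature_C": t, "area_fraction": fracs}
        for t in (22.0, 30.0, 38.0)
    ]
    return make_condition_series(out_dir, conditions, seed=seed,
                                 n_curves=n_curves, **kw)
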