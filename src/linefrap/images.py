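"""Confocal stack handling: line-ROI extraction of recovery curves.

Coordinate conventions (stable across the package): frames are indexed
``[t, row, col]``; rows map to y, columns to x; indices are 0-based with
half-open column ranges.  The bleach line lies along x (the ROI long axis);
the bleach profile varies along y.  ``bleach_frame_index`` is the index of
the *last pre-bleach* frame; the first post-bleach frame is
``bleach_frame_index + 1`` and defines t = 0 of the recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .fitting import RecoveryCurve

__all__ = [
    "ImageStack",
    "LineROI",
    "MetadataError",
    "BleachDetectionError",
    "read_stack",
    "write_stack",
    "detect_bleach_frame",
    "extract_recovery_curve",
    "estimate_bleach_resolution",
    "BleachProfileFit",
]


class MetadataError(ValueError):
    """Required acquisition metadata is missing or inconsistent."""


class BleachDetectionError(RuntimeError):
    """No bleach event could be located in the stack."""


@dataclass
class ImageStack:
    """A time-lapse single-channel stack.

    ``frames``: (T, H, W) grayscale intensities (uint16 camera data or
    float32 noise-free renders); ``frame_interval`` in s; ``pixel_size`` in
    um/pixel; ``bleach_frame_index`` is the last pre-bleach frame (None if
    unknown).  ``frame_times`` optionally records a non-uniform acquisition
    grid (s); when absent, frames are assumed uniformly spaced.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float
    bleach_frame_index: int | None = None
    frame_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MetadataError(
                f"expected a (T, H, W) single-channel stack, got shape "
                f"{self.frames.shape}"
            )
        if self.frames.shape[0] < 3:
            raise MetadataError("a FRAP stack needs >= 3 frames")
        if not (self.pixel_size > 0):
            raise MetadataError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise MetadataError("frame_interval must be > 0")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.frames.shape[0]:
                raise MetadataError("frame_times length must match frame count")

    def times(self) -> np.ndarray:
        if self.frame_times is not None:
            return self.frame_times
        return np.arange(self.frames.shape[0]) * self.frame_interval


@dataclass(frozen=True)
class LineROI:
    """A 1-pixel-high line ROI along x: row ``row``, columns
    ``[col_start, col_end)``.  The conventional line-FRAP ROI is 100 x 1."""

    row: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.col_end - self.col_start < 1:
            raise ValueError("ROI length must be >= 1")
        if self.row < 0 or self.col_start < 0:
            raise ValueError("ROI indices must be non-negative")

    @property
    def length(self) -> int:
        return self.col_end - self.col_start

    def check_bounds(self, frames: np.ndarray) -> None:
        _, h, w = frames.shape
        if self.row >= h or self.col_end > w:
            raise ValueError(
                f"ROI (row {self.row}, cols [{self.col_start}, {self.col_end})) "
                f"outside {h}x{w} frame"
            )

    def mean_intensity(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame mean intensity over the ROI."""
        self.check_bounds(frames)
        return frames[:, self.row, self.col_start:self.col_end].mean(axis=1)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-frame TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "frame_interval_s": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
    }
    if stack.bleach_frame_index is not None:
        meta["bleach_frame"] = int(stack.bleach_frame_index)
    if stack.frame_times is not None:
        meta["frame_times_s"] = [float(t) for t in stack.frame_times]
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Read a multi-frame single-channel grayscale TIFF.

    Acquisition metadata (frame interval, pixel size, optionally the bleach
    frame and a non-uniform time grid) comes from the JSON sidecar
    (``<stack>.tif.json`` by default).  Missing metadata is an explicit
    error — there are no silent defaults.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            photometric = tif.pages[0].photometric
            frames = tif.asarray()
    except MetadataError:
        raise
    except Exception as exc:
        raise MetadataError(f"{path}: not a readable TIFF ({exc})") from exc
    if photometric not in (tifffile.PHOTOMETRIC.MINISBLACK,
                           tifffile.PHOTOMETRIC.MINISWHITE):
        raise MetadataError(
            f"{path}: photometric interpretation {photometric!r} is not "
            "single-channel grayscale — RGB/multi-channel input is not "
            "supported"
        )
    if frames.ndim == 2:
        raise MetadataError(f"{path}: single frame; a FRAP stack needs >= 3")
    if frames.ndim != 3:
        raise MetadataError(
            f"{path}: expected a single-channel (T, H, W) stack, got shape "
            f"{frames.shape} — multi-channel input is not supported"
        )

    sc = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc.exists():
        raise MetadataError(
            f"{path}: no metadata sidecar found at {sc}; frame_interval_s and "
            "pixel_size_um are required"
        )
    meta = json.loads(sc.read_text())
    for key in ("frame_interval_s", "pixel_size_um"):
        if key not in meta:
            raise MetadataError(f"{sc}: missing required key {key!r}")
    ft = meta.get("frame_times_s")
    return ImageStack(
        frames=frames,
        frame_interval=float(meta["frame_interval_s"]),
        pixel_size=float(meta["pixel_size_um"]),
        bleach_frame_index=meta.get("bleach_frame"),
        frame_times=np.asarray(ft, dtype=float) if ft is not None else None,
        meta={"source_file": str(path)},
    )


def detect_bleach_frame(stack: ImageStack, roi: LineROI) -> int:
    """Locate the bleach: index of the last pre-bleach frame.

    Finds the largest single-frame drop in mean ROI intensity (ties broken
    by the earliest frame) and requires it to exceed 3x the pre-drop
    frame-to-frame standard deviation; otherwise raises
    :class:`BleachDetectionError` (the caller may then supply the index).
    """
    trace = roi.mean_intensity(stack.frames)
    diffs = np.diff(trace)
    drop_idx = int(np.argmin(diffs))  # argmin returns the earliest tie
    drop = -diffs[drop_idx]
    if drop <= 0:
        raise BleachDetectionError("no intensity drop found in ROI trace")
    pre_diffs = diffs[:drop_idx]
    noise = float(np.std(pre_diffs)) if len(pre_diffs) >= 2 else 0.0
    if noise > 0 and drop < 3.0 * noise:
        raise BleachDetectionError(
            f"largest drop ({drop:.3g}) below 3x pre-bleach frame-to-frame "
            f"std ({noise:.3g})"
        )
    return drop_idx


def extract_recovery_curve(
    stack: ImageStack,
    roi: LineROI,
    background_roi: LineROI | None = None,
    fading_roi: LineROI | None = None,
) -> RecoveryCurve:
    """Normalized recovery curve from a stack.

    ``F_pre`` is the mean background-subtracted ROI intensity over all
    pre-bleach frames; post-bleach values are divided by it.  With a
    ``fading_roi`` (a far-field region that sees photofading but not the
    bleach), each frame is additionally divided by the fading ROI intensity
    relative to its own pre-bleach mean.  Times are measured from the first
    post-bleach frame (t = 0).
    """
    b = stack.bleach_frame_index
    if b is None:
        b = detect_bleach_frame(stack, roi)
    first_post = b + 1
    if first_post >= stack.frames.shape[0]:
        raise ValueError("no post-bleach frames after the bleach index")

    frames = stack.frames.astype(float)
    trace = roi.mean_intensity(frames)
    background = np.zeros(len(trace))
    if background_roi is not None:
        background = background_roi.mean_intensity(frames)
    trace = trace - background

    fading = np.ones(len(trace))
    if fading_roi is not None:
        ftrace = fading_roi.mean_intensity(frames) - background
        fpre = ftrace[:first_post].mean()
        if fpre <= 0:
            raise ValueError("fading ROI has non-positive pre-bleach intensity")
        fading = ftrace / fpre
    trace = trace / fading

    F_pre = float(trace[:first_post].mean())
    if F_pre <= 0:
        raise ValueError("pre-bleach ROI intensity <= 0 after background "
                         "subtraction")
    values = trace[first_post:] / F_pre
    times = stack.times()
    rel_t = times[first_post:] - times[first_post]
    return RecoveryCurve(
        times=rel_t,
        values=values,
        F_pre=F_pre,
        meta={
            "frame_interval_s": stack.frame_interval,
            "bleach_frame": int(b),
            "roi": {"row": roi.row, "col_start": roi.col_start,
                    "col_end": roi.col_end},
            **stack.meta,
        },
    )


@dataclass(frozen=True)
class BleachProfileFit:
    """Result of :func:`estimate_bleach_resolution`: the bleach-line e^-2
    radius, the apparent peak dose, the line center (um) and the fraction of
    profile variance explained (``r_squared``)."""

    r0e: float
    K0: float
    center_um: float
    r_squared: float


def estimate_bleach_resolution(
    stack: ImageStack,
    bleach_frame: int,
    roi: LineROI,
) -> BleachProfileFit:
    """Estimate the bleach-line resolution r0e from the first post-bleach frame.

    For irreversible Gaussian-profile bleaching the log intensity ratio
    across the line is itself Gaussian:
    ``-log(I_post(y)/I_pre(y)) = K0 * exp(-2 (y - y0)^2 / r0e^2)``,
    so a Gaussian is fitted to the negative log ratio of the column-averaged
    profiles (averaged over the ROI columns), which stays accurate at large
    doses where the intensity dip itself is visibly non-Gaussian.  Raises
    ``BleachDetectionError`` when the dip contrast is below the noise.
    """
    from scipy.optimize import curve_fit

    frames = stack.frames.astype(float)
    first_post = bleach_frame + 1
    if first_post >= frames.shape[0] or bleach_frame < 0:
        raise ValueError("bleach_frame must leave pre- and post-bleach frames")
    cols = slice(roi.col_start, roi.col_end)
    pre = frames[:first_post, :, cols].mean(axis=(0, 2))
    post = frames[first_post, :, cols].mean(axis=1)
    if np.any(pre <= 0):
        raise BleachDetectionError("pre-bleach profile contains empty columns")
    ratio = np.clip(post / pre, 1e-6, None)
    neglog = -np.log(ratio)

    y_um = np.arange(len(neglog)) * stack.pixel_size
    noise = float(np.median(np.abs(np.diff(neglog)))) / np.sqrt(2.0)
    peak = float(np.max(neglog))
    if peak < max(3.0 * noise, 1e-3):
        raise BleachDetectionError(
            f"bleach dip contrast ({peak:.3g}) below noise ({noise:.3g})"
        )

    def gauss(y, K0, y0, r0e, base):
        return base + K0 * np.exp(-2.0 * (y - y0) ** 2 / r0e**2)

    y0_init = float(y_um[np.argmax(neglog)])
    p0 = [peak, y0_init, 1.0, 0.0]
    try:
        popt, _ = curve_fit(
            gauss, y_um, neglog, p0=p0,
            bounds=([0, y_um[0], stack.pixel_size / 2, -1],
                    [20, y_um[-1], y_um[-1], 1]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise BleachDetectionError(f"bleach profile fit failed: {exc}") from exc
    resid = neglog - gauss(y_um, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((neglog - neglog.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BleachProfileFit(
        r0e=float(popt[2]), K0=float(popt[0]), center_um=float(popt[1]),
        r_squared=r2,
    )
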