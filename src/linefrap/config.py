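"""Plain-text ``key = value`` configuration files.

Beam parameters, fit options and the classification threshold are
expressible in a flat config so that calibration constants travel with a
dataset.  Recognized keys (units in parentheses):

    K0            dimensionless bleach dose
    r0e_um        bleach line e^-2 radius (um)
    r0c_um        imaging PSF e^-2 radius (um)
    n_components  1 or 2
    fix_beam      true/false
    D_min_um2_s, D_max_um2_s   fit bounds (um^2/s)
    threshold_D_um2_s          free-dye classification threshold (um^2/s)
    seed          integer

Lines starting with ``#`` are comments; unknown keys are an error.
"""

from __future__ import annotations

from pathlib import Path

from .fitting import FitOptions
from .model import BeamParameters

_KNOWN = {
    "K0", "r0e_um", "r0c_um", "n_components", "fix_beam",
    "D_min_um2_s", "D_max_um2_s", "threshold_D_um2_s", "seed",
}


def parse_config(path: str | Path) -> dict:
    """Parse a key = value file into a flat dict of typed values."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _KNOWN:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in ("n_components", "seed"):
            out[key] = int(val)
        elif key == "fix_beam":
            out[key] = val.lower() in ("1", "true", "yes")
        else:
            out[key] = float(val)
    return out


def beam_from_config(cfg: dict) -> BeamParameters:
    missing = {"K0", "r0e_um"} - set(cfg)
    if missing:
        raise ValueError(f"config missing beam keys: {sorted(missing)}")
    return BeamParameters(K0=cfg["K0"], r0e=cfg["r0e_um"],
                          r0c=cfg.get("r0c_um", 0.0))


def fit_options_from_config(cfg: dict) -> FitOptions:
    kwargs = {}
    if "n_components" in cfg:
        kwargs["n_components"] = cfg["n_components"]
    if "fix_beam" in cfg:
        kwargs["fix_beam"] = cfg["fix_beam"]
    if "D_min_um2_s" in cfg or "D_max_um2_s" in cfg:
        kwargs["D_bounds"] = (cfg.get("D_min_um2_s", 1e-3),
                              cfg.get("D_max_um2_s", 1e4))
    if "seed" in cfg:
        kwargs["seed"] = cfg["seed"]
    return FitOptions(**kwargs)
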