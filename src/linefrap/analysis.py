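"""Condition-series analysis of line-FRAP experiments.

Runs the fitting pipeline over batches of recovery curves (or stacks)
grouped by experimental condition — composition and temperature — discards
fitted components attributed to free dye, and reports per-condition mean
diffusion coefficient, standard deviation over line scans, and n, together
with a descriptive monotone-trend check against temperature.

The trend assessment is deliberately descriptive (rank correlation plus an
all-pairwise-means-increase flag), not a headline hypothesis test: with
only a handful of conditions the p-value enters solely as a guard against
accidentally ordered noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    MEMBRANE,
    FitOptions,
    FitResult,
    RecoveryCurve,
    classify_components,
    fit_line_frap,
)
from .images import LineROI, extract_recovery_curve, read_stack
from .model import BeamParameters

__all__ = [
    "ConditionSummary",
    "TrendReport",
    "CurveRecord",
    "BatchResult",
    "run_batch",
    "trend_test",
    "write_report",
]


@dataclass
class ConditionSummary:
    """Per-condition aggregate: mean +- SD of the membrane diffusion
    coefficient over the n contributing line scans.  ``sd_D`` is None for
    n < 2; ``excluded`` counts dropped curves by reason."""

    condition: str
    temperature_C: float
    n: int
    mean_D: float | None
    sd_D: float | None
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.condition} @ {self.temperature_C:g} C"


@dataclass
class TrendReport:
    """Descriptive temperature-trend assessment.

    ``statistic`` is the Kendall rank correlation between temperature
    (ordinal) and per-curve membrane D, curves pooled across conditions;
    ``monotone_means`` flags strictly increasing per-condition means;
    ``verdict`` is "increasing" only when the means are monotone AND the
    correlation is positive AND clearly distinguishable from zero
    (one-sided p < 0.01 — a noise guard, not a hypothesis test), else
    "none".
    """

    conditions: list[str]
    mean_D: list[float]
    statistic: float
    p_one_sided: float
    monotone_means: bool
    verdict: str
    n_curves: int


@dataclass
class CurveRecord:
    """One line scan's journey through the batch: source, condition, fit,
    component labels, the membrane D used for aggregation (None if the curve
    was excluded) and the exclusion reason."""

    file: str
    condition: str
    temperature_C: float
    fit: FitResult | None
    labels: list[str] = field(default_factory=list)
    membrane_D: float | None = None
    excluded_reason: str | None = None


@dataclass
class BatchResult:
    records: list[CurveRecord]
    summaries: list[ConditionSummary]


def _load_curve(row: pd.Series, base_dir: Path) -> RecoveryCurve:
    path = Path(row["file"])
    if not path.is_absolute():
        path = base_dir / path
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = read_stack(path)
        if {"roi_row", "roi_col_start", "roi_col_end"} <= set(row.index) and \
                not pd.isna(row["roi_row"]):
            roi = LineROI(int(row["roi_row"]), int(row["roi_col_start"]),
                          int(row["roi_col_end"]))
        else:
            _, h, w = stack.frames.shape
            length = min(100, w)
            start = (w - length) // 2
            roi = LineROI(row=h // 2, col_start=start, col_end=start + length)
        return extract_recovery_curve(stack, roi)
    return RecoveryCurve.from_csv(path)


def _membrane_D(fit: FitResult, labels: list[str]) -> float | None:
    """Weight-weighted mean D over membrane-labelled components."""
    pairs = [(c.D, c.weight) for c, lab in zip(fit.components, labels)
             if lab == MEMBRANE]
    if not pairs:
        return None
    ws = sum(w for _, w in pairs)
    if ws <= 0:
        return None
    return sum(d * w for d, w in pairs) / ws


def run_batch(
    manifest: str | Path | pd.DataFrame,
    beam: BeamParameters,
    options: FitOptions | None = None,
    threshold_D: float = 10.0,
) -> BatchResult:
    """Fit every curve in a manifest and aggregate by condition.

    ``manifest`` is a CSV (or DataFrame) with columns ``file`` (curve CSV or
    TIFF stack, relative paths resolved against the manifest directory),
    ``condition`` (composition label) and ``temperature_C``.  Per-curve
    failures are recorded with a reason and never abort the batch;
    non-converged and D-at-bounds fits are excluded from aggregation, as are
    curves with no membrane-classified component.  Fully deterministic given
    the fit options' seed.
    """
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
        base_dir = Path(".")
    else:
        mpath = Path(manifest)
        df = pd.read_csv(mpath)
        base_dir = mpath.parent
    required = {"file", "condition", "temperature_C"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    # default: two components with the fast one pinned to the free-dye range
    # (the classification threshold doubles as the calibration split)
    options = options or FitOptions(n_components=2, fast_D_min=threshold_D)

    records: list[CurveRecord] = []
    for _, row in df.iterrows():
        rec = CurveRecord(
            file=str(row["file"]), condition=str(row["condition"]),
            temperature_C=float(row["temperature_C"]), fit=None,
        )
        try:
            curve = _load_curve(row, base_dir)
            fit = fit_line_frap(curve, beam, options)
            rec.fit = fit
            if not fit.converged:
                rec.excluded_reason = "not_converged"
            elif fit.at_boundary:
                rec.excluded_reason = "parameter_at_boundary"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec.labels = classify_components(fit, threshold_D)
                rec.membrane_D = _membrane_D(fit, rec.labels)
                if rec.membrane_D is None:
                    rec.excluded_reason = "no_membrane_component"
        except Exception as exc:  # per-curve failures never abort the batch
            rec.excluded_reason = f"error: {type(exc).__name__}: {exc}"
        records.append(rec)

    summaries: list[ConditionSummary] = []
    keys = sorted({(r.condition, r.temperature_C) for r in records})
    for cond, temp in keys:
        group = [r for r in records
                 if r.condition == cond and r.temperature_C == temp]
        ds = [r.membrane_D for r in group if r.membrane_D is not None]
        excluded: dict[str, int] = {}
        for r in group:
            if r.excluded_reason is not None:
                key = r.excluded_reason.split(":")[0]
                excluded[key] = excluded.get(key, 0) + 1
        summaries.append(ConditionSummary(
            condition=cond, temperature_C=temp, n=len(ds),
            mean_D=float(np.mean(ds)) if ds else None,
            sd_D=float(np.std(ds, ddof=1)) if len(ds) >= 2 else None,
            excluded=excluded,
        ))
    return BatchResult(records=records, summaries=summaries)


def trend_test(batch: BatchResult, condition: str | None = None) -> TrendReport:
    """Rank-correlation trend of membrane D against temperature.

    Pools the per-curve membrane diffusion coefficients (condition
    temperature as the ordinal regressor) into a Kendall tau, and checks
    whether the per-condition means increase strictly with temperature.
    Requires >= 3 temperature conditions.
    """
    records = [r for r in batch.records if r.membrane_D is not None
               and (condition is None or r.condition == condition)]
    summaries = [s for s in batch.summaries if s.mean_D is not None
                 and (condition is None or s.condition == condition)]
    summaries = sorted(summaries, key=lambda s: s.temperature_C)
    temps = [s.temperature_C for s in summaries]
    if len(set(temps)) < 3:
        raise ValueError("trend_test needs >= 3 temperature conditions")

    means = [s.mean_D for s in summaries]
    monotone = all(b > a for a, b in zip(means, means[1:]))
    x = np.array([r.temperature_C for r in records])
    y = np.array([r.membrane_D for r in records])
    tau, p_two = stats.kendalltau(x, y)
    if np.isnan(tau):
        tau, p_two = 0.0, 1.0
    p_one = p_two / 2.0 if tau > 0 else 1.0 - p_two / 2.0
    verdict = "increasing" if (monotone and tau > 0 and p_one < 0.01) else "none"
    return TrendReport(
        conditions=[s.label for s in summaries],
        mean_D=[float(m) for m in means],
        statistic=float(tau),
        p_one_sided=float(p_one),
        monotone_means=monotone,
        verdict=verdict,
        n_curves=len(records),
    )


def write_report(batch: BatchResult, out_dir: str | Path) -> dict[str, Path]:
    """Write ``summary.csv`` (one row per condition, ordered by composition
    then temperature ascending) and ``report.json`` (per-curve detail with
    provenance).  Output bytes are deterministic for identical inputs."""
    if not batch.records:
        raise ValueError("write_report needs a non-empty batch")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for s in sorted(batch.summaries, key=lambda s: (s.condition, s.temperature_C)):
        rows.append({
            "condition": s.condition,
            "temperature_C": s.temperature_C,
            "n": s.n,
            "mean_D_um2_s": s.mean_D,
            "sd_D_um2_s": s.sd_D,
            "n_excluded": sum(s.excluded.values()),
            "excluded_reasons": ";".join(
                f"{k}={v}" for k, v in sorted(s.excluded.items())) or "",
        })
    csv_path = out_dir / "summary.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.8g")

    from . import __version__
    detail = {
        "software": {"name": "linefrap", "version": __version__},
        "curves": [
            {
                "file": r.file,
                "condition": r.condition,
                "temperature_C": r.temperature_C,
                "membrane_D_um2_s": r.membrane_D,
                "component_labels": r.labels,
                "excluded_reason": r.excluded_reason,
                "fit": r.fit.to_dict() if r.fit is not None else None,
            }
            for r in batch.records
        ],
        "summaries": rows,
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(detail, indent=2, sort_keys=True) + "\n")
    return {"summary_csv": csv_path, "report_json": json_path}


def read_summary(path: str | Path) -> list[ConditionSummary]:
    """Reload a ``summary.csv`` written by :func:`write_report`."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        excluded = {}
        reasons = row.get("excluded_reasons")
        if isinstance(reasons, str) and reasons:
            for part in reasons.split(";"):
                if "=" in part:
                    k, v = part.split("=")
                    excluded[k] = int(v)
        out.append(ConditionSummary(
            condition=str(row["condition"]),
            temperature_C=float(row["temperature_C"]),
            n=int(row["n"]),
            mean_D=None if pd.isna(row["mean_D_um2_s"]) else float(row["mean_D_um2_s"]),
            sd_D=None if pd.isna(row["sd_D_um2_s"]) else float(row["sd_D_um2_s"]),
            excluded=excluded,
        ))
    return out
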