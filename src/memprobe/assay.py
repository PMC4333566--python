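"""Competition radioligand-binding dose-response fitting.

Binding signal versus competitor concentration is fitted with the
variable-slope four-parameter logistic (4PL) used for competition curves:

    Y = bottom + (top - bottom) / (1 + 10^((log10(IC50) - log10(X)) * hill))

with X the molar competitor concentration. The reported potency is
pIC50 = -log10(IC50 / M); for an inhibition curve the Hill slope is
negative. Replicate experiments are fitted independently and summarised as
mean ± SD of the per-experiment pIC50 (n−1 denominator), matching how
competition assays are conventionally tabulated.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponse",
    "FitResult",
    "four_parameter_logistic",
    "fit_dose_response",
    "normalize_b0",
    "fit_experiments",
    "read_dose_response_csv",
    "write_summary_csv",
]

_HILL_BOUNDS = (-10.0, 10.0)
_JITTER_SEED = 20210 + 4  # fixed stream for the multi-start jitter


def four_parameter_logistic(
    x: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float
) -> np.ndarray:
    """Variable-slope sigmoid in molar concentration ``x``."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - np.log10(x)) * hill))


@dataclass
class DoseResponse:
    """Concentration–signal pairs for one competition experiment."""

    concentrations: np.ndarray  # molar, > 0
    signal: np.ndarray
    b0: float | None = None  # binding without competitor (normaliser)
    experiment_id: str = "exp0"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.concentrations.shape != self.signal.shape:
            raise ValueError("concentrations and signal must have the same shape")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be > 0 (molar)")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")

    def validate_for_fit(self) -> None:
        distinct = np.unique(self.concentrations)
        if distinct.size < 5:
            raise ValueError(
                f"{self.experiment_id}: need >= 5 distinct concentrations, "
                f"got {distinct.size}"
            )
        span = math.log10(distinct.max() / distinct.min())
        if span < 2.0:
            raise ValueError(
                f"{self.experiment_id}: concentrations span {span:.2f} log units, "
                "need >= 2"
            )


@dataclass
class FitResult:
    """4PL fit of one experiment."""

    pic50: float | None
    hill_slope: float | None
    top: float | None
    bottom: float | None
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    no_inhibition: bool = False
    at_bounds: bool = False
    rss: float | None = None
    experiment_id: str = "exp0"

    @property
    def ic50(self) -> float | None:
        return None if self.pic50 is None else 10.0 ** (-self.pic50)

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "pIC50": self.pic50,
            "hill_slope": self.hill_slope,
            "top": self.top,
            "bottom": self.bottom,
            "stderr": self.stderr,
            "converged": self.converged,
            "no_inhibition": self.no_inhibition,
            "at_bounds": self.at_bounds,
            "rss": self.rss,
        }


def normalize_b0(data: DoseResponse) -> DoseResponse:
    """Express the signal as percent of the no-competitor binding B0."""
    if data.b0 is None:
        raise ValueError("b0 is not set; cannot normalise")
    if data.b0 <= 0:
        raise ValueError("b0 must be > 0")
    return replace(data, signal=100.0 * data.signal / data.b0, b0=100.0)


def _initial_guesses(data: DoseResponse) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = data.signal
    x = data.concentrations
    top0, bot0 = float(y.max()), float(y.min())
    half = 0.5 * (top0 + bot0)
    ic50_0 = float(x[np.argmin(np.abs(y - half))])
    # response direction: signal falling with concentration -> negative hill
    order = np.argsort(x)
    falling = y[order][-1] < y[order][0]
    hill0 = -1.0 if falling else 1.0
    p0 = np.array([top0, bot0, math.log10(ic50_0), hill0])
    lo = np.array(
        [
            bot0 - 2.0 * (top0 - bot0) - 1.0,
            bot0 - 2.0 * (top0 - bot0) - 1.0,
            math.log10(x.min()) - 2.0,
            _HILL_BOUNDS[0],
        ]
    )
    hi = np.array(
        [
            top0 + 2.0 * (top0 - bot0) + 1.0,
            top0 + 2.0 * (top0 - bot0) + 1.0,
            math.log10(x.max()) + 2.0,
            _HILL_BOUNDS[1],
        ]
    )
    return p0, lo, hi


def fit_dose_response(
    data: DoseResponse,
    init: Sequence[float] | None = None,
    flat_rel_tol: float = 0.05,
) -> FitResult:
    """Least-squares 4PL fit with multi-start initialisation.

    Data whose signal range is below ``flat_rel_tol`` of its magnitude are
    flagged ``no_inhibition`` (pIC50 undefined) instead of being fitted —
    the behaviour of an assay where the mutation abolishes binding of the
    competitor. Non-convergence is flagged, never silently returned.
    """
    data.validate_for_fit()
    y = data.signal
    scale = max(abs(float(y.max())), abs(float(y.min())), 1e-12)
    if (y.max() - y.min()) < flat_rel_tol * scale:
        return FitResult(
            pic50=None,
            hill_slope=None,
            top=float(y.mean()),
            bottom=float(y.mean()),
            no_inhibition=True,
            experiment_id=data.experiment_id,
        )

    p0, lo, hi = _initial_guesses(data)
    if init is not None:
        p0 = np.asarray(init, dtype=float)

    def model(x, top, bottom, log_ic50, hill):
        return four_parameter_logistic(x, top, bottom, log_ic50, hill)

    rng = np.random.default_rng(_JITTER_SEED)
    starts = [p0]
    for _ in range(2):
        jitter = p0 + rng.normal(scale=[0.05 * scale, 0.05 * scale, 0.3, 0.3])
        starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for start in starts:
        try:
            popt, pcov = curve_fit(
                model,
                data.concentrations,
                y,
                p0=np.clip(start, lo + 1e-12, hi - 1e-12),
                bounds=(lo, hi),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(data.concentrations, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)

    if best is None:
        return FitResult(
            pic50=None,
            hill_slope=None,
            top=None,
            bottom=None,
            converged=False,
            experiment_id=data.experiment_id,
        )

    rss, popt, pcov = best
    top, bottom, log_ic50, hill = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    at_bounds = bool(
        np.any(np.isclose(popt, lo, atol=1e-6)) or np.any(np.isclose(popt, hi, atol=1e-6))
    )
    return FitResult(
        pic50=float(-log_ic50),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        stderr={
            "top": float(perr[0]),
            "bottom": float(perr[1]),
            "pIC50": float(perr[2]),
            "hill_slope": float(perr[3]),
        },
        converged=True,
        at_bounds=at_bounds,
        rss=rss,
        experiment_id=data.experiment_id,
    )


def fit_experiments(
    experiments: Sequence[DoseResponse], normalise: bool = True
) -> tuple[list[FitResult], dict]:
    """Fit each experiment independently and summarise pIC50 as mean ± SD."""
    fits = []
    for data in experiments:
        if normalise and data.b0 is not None:
            data = normalize_b0(data)
        fits.append(fit_dose_response(data))
    pic50s = np.array([f.pic50 for f in fits if f.pic50 is not None])
    if pic50s.size:
        summary = {
            "n": int(pic50s.size),
            "mean_pIC50": float(pic50s.mean()),
            "sd_pIC50": float(np.std(pic50s, ddof=1)) if pic50s.size > 1 else 0.0,
            "no_inhibition": False,
        }
    else:
        summary = {
            "n": 0,
            "mean_pIC50": None,
            "sd_pIC50": None,
            "no_inhibition": all(f.no_inhibition for f in fits),
        }
    return fits, summary


def read_dose_response_csv(path: str | Path) -> list[DoseResponse]:
    """Read experiments from a CSV with columns experiment_id,
    concentration_M, signal and optionally b0."""
    df = pd.read_csv(path)
    required = {"experiment_id", "concentration_M", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for eid, grp in df.groupby("experiment_id", sort=True):
        b0 = None
        if "b0" in grp.columns and grp["b0"].notna().any():
            b0 = float(grp["b0"].dropna().iloc[0])
        out.append(
            DoseResponse(
                concentrations=grp["concentration_M"].to_numpy(float),
                signal=grp["signal"].to_numpy(float),
                b0=b0,
                experiment_id=str(eid),
            )
        )
    return out


def write_summary_csv(
    summaries: Mapping[str, dict], path: str | Path
) -> None:
    rows = []
    for compound in sorted(summaries):
        s = summaries[compound]
        rows.append(
            {
                "compound": compound,
                "mean_pIC50": s["mean_pIC50"],
                "sd_pIC50": s["sd_pIC50"],
                "n": s["n"],
                "no_inhibition": s["no_inhibition"],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
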