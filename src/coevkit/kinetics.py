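"""NADH standard-curve calibration and enzyme initial-rate analysis.

An aldehyde-dehydrogenase activity assay follows NADH accumulation at
340 nm; absorbance is calibrated to concentration via an NADH standard
curve, the initial velocity of each replicate is the ordinary-least-squares
slope of concentration vs time over the early linear phase (default: the
first 6 points, i.e. 0-10 min at a 2-min cadence), and conditions are
summarised as mean +/- SD over replicates with a two-tailed t test and a
percent inhibition relative to control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .io import TimeCourse
from .stats import TestResult, two_sample_t


@dataclass
class StandardCurve:
    slope: float  # AU per µM
    intercept: float  # AU
    r_squared: float
    n_points: int


def fit_standard_curve(concentrations, readings, through_origin: bool = False) -> StandardCurve:
    """OLS fit of absorbance vs concentration (intercept fitted by default)."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(readings, dtype=float)
    if c.size != y.size or c.size < 3:
        raise ValueError("need >= 3 paired points")
    if len(np.unique(c)) < 2:
        raise ValueError("concentrations must be distinct")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance fit: readings are constant")
    if through_origin:
        slope = float((c @ y) / (c @ c))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(c, y, 1))
    fitted = slope * c + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r2, n_points=c.size)


def to_concentration(curve: StandardCurve, readings) -> np.ndarray:
    """Invert the standard curve: C = (A - intercept) / slope, elementwise."""
    y = np.asarray(readings, dtype=float)
    conc = (y - curve.intercept) / curve.slope
    if (conc < 0).any():
        warnings.warn("negative computed concentration(s) retained", stacklevel=2)
    return conc


def calibrate_timecourse(tc: TimeCourse, curve: StandardCurve) -> TimeCourse:
    """Convert an absorbance time course to concentration units."""
    if tc.reading_kind != "absorbance":
        raise ValueError("time course is not in absorbance units")
    return TimeCourse(
        replicate=tc.replicate,
        condition=tc.condition,
        times=tc.times,
        readings=to_concentration(curve, tc.readings),
        reading_kind="concentration",
    )


def initial_rate(
    tc: TimeCourse,
    window_points: int | None = 6,
    window_minutes: float | None = None,
) -> float:
    """Initial velocity (µM/min): OLS slope over the early window.

    The window is the first ``window_points`` points, or all points with
    time <= ``window_minutes`` when that is given instead. Absorbance input
    is a hard error — calibrate first, units are never mixed silently.
    """
    if tc.reading_kind != "concentration":
        raise ValueError(
            "initial_rate needs concentration units; calibrate absorbance with a standard curve"
        )
    order = np.argsort(tc.times)
    t, y = tc.times[order], tc.readings[order]
    if window_minutes is not None:
        keep = t <= window_minutes
        t, y = t[keep], y[keep]
    elif window_points is not None:
        t, y = t[:window_points], y[:window_points]
    if t.size < 3:
        raise ValueError(f"fit window has {t.size} points; need >= 3")
    slope = float(np.polyfit(t, y, 1)[0])
    return slope


@dataclass
class RateResult:
    condition: str
    slopes: list[float]  # per-replicate, µM/min
    mean_rate: float
    sd_rate: float  # n-1 denominator
    n_replicates: int
    fit_window: str


@dataclass
class RateSummary:
    results: dict[str, RateResult]
    control: str
    percent_change: dict[str, float]  # 100*(rate_ctrl - rate_cond)/rate_ctrl
    t_tests: dict[str, TestResult]  # vs control
    dose_trend: dict = field(default_factory=dict)


def summarize_rates(
    slopes_by_condition: dict[str, list[float]],
    control: str,
    concentrations: dict[str, float] | None = None,
    welch: bool = False,
    fit_window: str = "first 6 points",
) -> RateSummary:
    """Replicate summaries, percent inhibition vs control, and pairwise t tests.

    When inhibitor ``concentrations`` are supplied, a Spearman correlation of
    mean rate vs concentration is reported as a dose-monotonicity diagnostic.
    """
    if control not in slopes_by_condition:
        raise ValueError(f"control condition {control!r} not present")
    results: dict[str, RateResult] = {}
    for cond, slopes in slopes_by_condition.items():
        arr = np.asarray(slopes, dtype=float)
        results[cond] = RateResult(
            condition=cond,
            slopes=[float(s) for s in arr],
            mean_rate=float(arr.mean()),
            sd_rate=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
            n_replicates=arr.size,
            fit_window=fit_window,
        )
    ctrl_rate = results[control].mean_rate
    ctrl_slopes = slopes_by_condition[control]
    percent_change: dict[str, float] = {}
    t_tests: dict[str, TestResult] = {}
    for cond, res in results.items():
        if cond == control:
            continue
        percent_change[cond] = 100.0 * (ctrl_rate - res.mean_rate) / ctrl_rate
        if len(ctrl_slopes) >= 2 and res.n_replicates >= 2:
            t_tests[cond] = two_sample_t(ctrl_slopes, res.slopes, welch=welch)
    dose_trend: dict = {}
    if concentrations:
        conds = [c for c in results if c in concentrations]
        if len(conds) >= 3:
            doses = [concentrations[c] for c in conds]
            rates = [results[c].mean_rate for c in conds]
            rho, p = spearmanr(doses, rates)
            dose_trend = {"spearman_rho": float(rho), "p_value": float(p)}
    return RateSummary(
        results=results,
        control=control,
        percent_change=percent_change,
        t_tests=t_tests,
        dose_trend=dose_trend,
    )
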