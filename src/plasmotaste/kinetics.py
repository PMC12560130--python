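"""Kinetic on-curve fitting: dl(t) = a * (1 - exp(-k t)) per sensor.

The fitted amplitude and rate are discriminative features in their own
right: liquids whose molecules reach the sensor surface slowly (beer-like
macromolecules) show rates an order of magnitude below small-ion binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fingerprinting import (
    FingerprintMatrix,
    SENSOR_COLUMNS,
    STATUS_OK,
)

AMPLITUDE_BOUND_NM = 50.0
RATE_BOUNDS = (1e-5, 1.0)  # s^-1
#: A series whose range is below 3x the per-point noise estimate is
#: reported as flat (amplitude ~ 0) instead of being fitted.
FLAT_RANGE_FACTOR = 3.0

FLAG_CONVERGED = "converged"
FLAG_FLAT = "flat"
FLAG_FAILED = "failed"
FLAG_INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class KineticFit:
    amplitude: float  # nm, fitted equilibrium shift
    rate: float  # s^-1
    rms_residual: float  # nm
    converged: bool
    flag: str = FLAG_CONVERGED

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


def _on_curve(t, a, k):
    return a * (1.0 - np.exp(-k * t))


def _noise_estimate(series: np.ndarray) -> float:
    """Per-point noise sd from first differences (robust MAD)."""
    if len(series) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(series))) / (0.6745 * np.sqrt(2.0)))


def fit_on_curve(
    times_s: np.ndarray,
    delta_lambda_series: np.ndarray,
    *,
    with_offset: bool = False,
) -> KineticFit:
    """Nonlinear least-squares fit of the saturating on-curve.

    Initialization: amplitude from the last observation, rate from the
    reciprocal median time.  Bounded (|a| <= 50 nm, k in [1e-5, 1] s^-1)
    to stop runaway fits on flat series; series whose range is below
    3x the per-point noise estimate short-circuit to a flat result.

    ``with_offset`` adds a constant term for drifting, non-baseline-
    referenced data: dl(t) = a * (1 - exp(-k t)) + c.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(delta_lambda_series, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and series must be matching 1-D arrays")
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    noise = _noise_estimate(y)
    if np.ptp(y) < FLAT_RANGE_FACTOR * noise or np.ptp(y) == 0.0:
        resid = y - float(np.mean(y))
        return KineticFit(
            amplitude=0.0,
            rate=0.0,
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            converged=True,
            flag=FLAG_FLAT,
        )

    a0 = float(np.clip(y[-1], -AMPLITUDE_BOUND_NM, AMPLITUDE_BOUND_NM))
    k0 = float(np.clip(1.0 / np.median(t), *RATE_BOUNDS))
    if with_offset:
        model = lambda tt, a, k, c: _on_curve(tt, a, k) + c  # noqa: E731
        p0 = [a0, k0, 0.0]
        bounds = (
            [-AMPLITUDE_BOUND_NM, RATE_BOUNDS[0], -AMPLITUDE_BOUND_NM],
            [AMPLITUDE_BOUND_NM, RATE_BOUNDS[1], AMPLITUDE_BOUND_NM],
        )
    else:
        model = _on_curve
        p0 = [a0, k0]
        bounds = (
            [-AMPLITUDE_BOUND_NM, RATE_BOUNDS[0]],
            [AMPLITUDE_BOUND_NM, RATE_BOUNDS[1]],
        )
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10000)
        resid = model(t, *popt) - y
        return KineticFit(
            amplitude=float(popt[0]),
            rate=float(popt[1]),
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            converged=True,
            flag=FLAG_CONVERGED,
        )
    except RuntimeError:
        return KineticFit(
            amplitude=a0, rate=k0, rms_residual=float("inf"),
            converged=False, flag=FLAG_FAILED,
        )


def kinetic_feature_table(matrix: FingerprintMatrix) -> pd.DataFrame:
    """Fit the on-curve per (sample, replicate, sensor) time series.

    Returns a tidy table with one row per fit: sample_id, class_label,
    replicate, sensor_id, amplitude_nm, rate_per_s, rms_residual_nm,
    converged, flag.  Incomplete series (flagged rows inside them, or
    fewer than 4 points) are recorded with flag='incomplete', not fitted.
    """
    rows = []
    frame = matrix.frame
    for (sample_id, class_label, replicate), group in frame.groupby(
        ["sample_id", "class_label", "replicate"], sort=True
    ):
        group = group.sort_values("time_s")
        complete = (group["status"] == STATUS_OK).all() and len(group) >= 4
        times = group["time_s"].to_numpy(dtype=float)
        for j, col in enumerate(SENSOR_COLUMNS):
            if not complete:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "class_label": class_label,
                        "replicate": replicate,
                        "sensor_id": j + 1,
                        "amplitude_nm": np.nan,
                        "rate_per_s": np.nan,
                        "rms_residual_nm": np.nan,
                        "converged": False,
                        "flag": FLAG_INCOMPLETE,
                    }
                )
                continue
            fit = fit_on_curve(times, group[col].to_numpy(dtype=float))
            rows.append(
                {
                    "sample_id": sample_id,
                    "class_label": class_label,
                    "replicate": replicate,
                    "sensor_id": j + 1,
                    "amplitude_nm": fit.amplitude,
                    "rate_per_s": fit.rate,
                    "rms_residual_nm": fit.rms_residual,
                    "converged": fit.converged,
                    "flag": fit.flag,
                }
            )
    return pd.DataFrame(rows)
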