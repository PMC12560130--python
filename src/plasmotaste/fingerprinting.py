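"""Measurement sessions: rolling DI-water baselines, fingerprints, rinse QC.

The fingerprint of a liquid is the vector of 24 resonance shifts of the
sensor elements relative to the rolling deionized-water baseline (the
mean of the preceding ten DI readings per sensor).  A session measures
every catalog sample in 3 replicates, randomized within its liquid
class, on a per-class schedule (10 readings every 30 s; 20 for beer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .dipfind import FLAG_OK, SensorReading, find_minimum
from .readout import frame_to_spectra
from .synthetic_chip.chemistry import ChemistryProfile, default_chemistries
from .synthetic_chip.layout import default_layout
from .synthetic_chip.render import DipParams, render_frame
from .synthetic_chip.response import (
    ResponseModel,
    adsorption_shift,
    effective_rate,
    equilibrium_shift,
    kinetic_shift,
)
from .synthetic_chip.samples import CLASS_LABELS, LiquidSample

N_SENSORS = 24
BASELINE_WINDOW = 10
DEFAULT_INTERVAL_S = 30.0
DEFAULT_REVERSION_TOLERANCE_NM = 0.2

STATUS_OK = "ok"
STATUS_FLAGGED = "flagged"

SENSOR_COLUMNS = [f"s{i:02d}" for i in range(1, N_SENSORS + 1)]
METADATA_COLUMNS = ["sample_id", "class_label", "replicate", "time_s", "status"]


@dataclass(frozen=True)
class MeasurementSchedule:
    n_readings: int
    interval_s: float = DEFAULT_INTERVAL_S
    baseline_window: int = BASELINE_WINDOW

    def __post_init__(self) -> None:
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be > 0")
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")


def schedule_for_class(class_label: str) -> MeasurementSchedule:
    """Per-class schedule: beer gets 20 readings, every other class 10,
    all at 30 s intervals."""
    if class_label == "beer":
        return MeasurementSchedule(n_readings=20)
    if class_label in CLASS_LABELS or class_label == "di_water":
        return MeasurementSchedule(n_readings=10)
    raise ValueError(f"unknown class label {class_label!r}; pass a schedule explicitly")


@dataclass(frozen=True)
class Baseline:
    """Per-sensor DI-water baseline (nm) with provenance."""

    values: np.ndarray  # shape (24,)
    n_used: int
    warning: bool
    baseline_id: str = ""


def update_baseline(
    di_reading_history: list[np.ndarray], *, baseline_id: str = ""
) -> Baseline:
    """Baseline = per-sensor mean over the most recent (up to) ten DI
    readings.  With fewer than ten available, all are used and the
    result carries a warning."""
    if len(di_reading_history) == 0:
        raise ValueError("no DI readings available; cannot form a baseline")
    history = [np.asarray(r, dtype=float) for r in di_reading_history]
    for r in history:
        if r.shape != (N_SENSORS,):
            raise ValueError(f"each DI reading must have {N_SENSORS} entries")
    window = history[-BASELINE_WINDOW:]
    return Baseline(
        values=np.mean(window, axis=0),
        n_used=len(window),
        warning=len(window) < BASELINE_WINDOW,
        baseline_id=baseline_id,
    )


@dataclass(frozen=True)
class Fingerprint:
    sample_id: str
    class_label: str
    replicate: int
    time_s: float
    delta_lambda: np.ndarray  # shape (24,), nm
    baseline_id: str = ""
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        dl = np.asarray(self.delta_lambda, dtype=float)
        if dl.shape != (N_SENSORS,):
            raise ValueError(f"delta_lambda must have exactly {N_SENSORS} entries")
        if not np.all(np.isfinite(dl)):
            raise ValueError("delta_lambda entries must be finite")


def compute_fingerprint(
    readings: dict[int, SensorReading],
    baseline: Baseline,
    *,
    sample_id: str = "",
    class_label: str = "",
    replicate: int = 0,
) -> Fingerprint:
    """Subtract the baseline from one complete set of 24 sensor readings."""
    missing = [sid for sid in range(1, N_SENSORS + 1) if sid not in readings]
    if missing:
        raise ValueError(f"missing sensor readings for ids {missing}; no imputation")
    times = {readings[sid].time_s for sid in range(1, N_SENSORS + 1)}
    if len(times) != 1:
        raise ValueError("all 24 readings must share one time_s")
    delta = np.array(
        [readings[sid].lambda_min for sid in range(1, N_SENSORS + 1)]
    ) - baseline.values
    flagged = any(
        readings[sid].flag != FLAG_OK for sid in range(1, N_SENSORS + 1)
    )
    return Fingerprint(
        sample_id=sample_id,
        class_label=class_label,
        replicate=replicate,
        time_s=times.pop(),
        delta_lambda=delta,
        baseline_id=baseline.baseline_id,
        status=STATUS_FLAGGED if flagged else STATUS_OK,
    )


@dataclass
class FingerprintMatrix:
    """Labelled fingerprint rows; column order fixed to sensors 1..24.

    ``frame`` carries the metadata columns (sample_id, class_label,
    replicate, time_s, status) followed by s01..s24.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        expected = METADATA_COLUMNS + SENSOR_COLUMNS
        if list(self.frame.columns) != expected:
            raise ValueError(f"fingerprint matrix columns must be {expected}")

    @classmethod
    def from_fingerprints(cls, fingerprints: list[Fingerprint]) -> "FingerprintMatrix":
        rows = []
        for fp in fingerprints:
            row = {
                "sample_id": fp.sample_id,
                "class_label": fp.class_label,
                "replicate": fp.replicate,
                "time_s": fp.time_s,
                "status": fp.status,
            }
            row.update(dict(zip(SENSOR_COLUMNS, fp.delta_lambda)))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=METADATA_COLUMNS + SENSOR_COLUMNS))

    @property
    def values(self) -> np.ndarray:
        return self.frame[SENSOR_COLUMNS].to_numpy(dtype=float)

    def ok_rows(self) -> "FingerprintMatrix":
        return FingerprintMatrix(
            self.frame[self.frame["status"] == STATUS_OK].reset_index(drop=True)
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FingerprintMatrix":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)


def aggregate_fingerprints(
    matrix: FingerprintMatrix, *, per_replicate: bool = True
) -> FingerprintMatrix:
    """Mean fingerprint per sample (optionally per replicate).

    Collapses the reading-level rows into one row per sample[-replicate],
    averaging the 24 shift columns over the schedule; flagged rows are
    excluded from the averages.  This is the row granularity used for
    sample-level clustering displays.
    """
    frame = matrix.ok_rows().frame
    keys = ["sample_id", "class_label"] + (["replicate"] if per_replicate else [])
    agg = frame.groupby(keys, as_index=False)[SENSOR_COLUMNS].mean()
    if not per_replicate:
        agg["replicate"] = 0
    agg["time_s"] = 0.0
    agg["status"] = STATUS_OK
    return FingerprintMatrix(agg[METADATA_COLUMNS + SENSOR_COLUMNS])


class ReadingSource(Protocol):
    """Anything that can produce one 24-sensor reading of a liquid at a
    given time after introduction."""

    def measure(
        self, sample: LiquidSample, time_s: float, rng: np.random.Generator
    ) -> dict[int, SensorReading]: ...

    def end_sample(self, sample: LiquidSample) -> None:
        """Called after the last reading of a sample (rinse hook)."""


@dataclass
class SimulatedSource:
    """Simulator-backed reading source.

    ``mode='direct'`` draws resonance wavelengths from the response
    model plus Gaussian wavelength noise calibrated to the full
    pipeline; ``mode='frames'`` renders a hyperspectral frame per
    reading and runs it through the readout and spline extraction
    (slow, used to validate the fast path).
    """

    chemistries: list[ChemistryProfile] = field(default_factory=default_chemistries)
    response_model: ResponseModel = field(default_factory=ResponseModel)
    lambda_noise_sd: float = 0.02
    mode: str = "direct"
    _residual: dict[int, float] = field(default_factory=dict)  # carryover, nm

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "frames"):
            raise ValueError("mode must be 'direct' or 'frames'")
        if len(self.chemistries) != N_SENSORS:
            raise ValueError(f"need {N_SENSORS} chemistries")
        self._layout = default_layout()

    def _lambda_true(self, sample: LiquidSample, time_s: float) -> dict[int, float]:
        out = {}
        for chem in self.chemistries:
            shift = 0.0
            if not sample.composition.is_zero():
                eq = equilibrium_shift(chem, sample, self.response_model)
                rate = effective_rate(chem, sample)
                shift = kinetic_shift(eq, rate, time_s)
            out[chem.sensor_id] = (
                chem.resonance_water + shift + self._residual.get(chem.sensor_id, 0.0)
            )
        return out

    def measure(
        self, sample: LiquidSample, time_s: float, rng: np.random.Generator
    ) -> dict[int, SensorReading]:
        centers = self._lambda_true(sample, time_s)
        if self.mode == "direct":
            return {
                sid: SensorReading(
                    sensor_id=sid,
                    time_s=time_s,
                    lambda_min=center + rng.normal(0.0, self.lambda_noise_sd),
                    fit_quality=0.0,
                )
                for sid, center in centers.items()
            }
        dips = {
            ap: DipParams(
                center_nm=centers[self._layout.sensor_ids[ap]],
                depth=self.response_model.dip_depth,
                fwhm_nm=self.response_model.dip_fwhm,
            )
            for ap in self._layout.sensor_apertures
        }
        frame = render_frame(self._layout, dips, self.response_model, rng)
        spectra = frame_to_spectra(frame, time_s=time_s)
        return {sid: find_minimum(sp) for sid, sp in spectra.items()}

    def end_sample(self, sample: LiquidSample) -> None:
        """Rinse: the sensors revert to baseline except for a carryover
        residual proportional to the adsorption shift of the departing
        sample (high-affinity sensors retain the most; the bulk liquid
        itself is fully exchanged)."""
        frac = self.response_model.carryover_fraction
        if frac == 0 or sample.composition.is_zero():
            self._residual = {}
            return
        self._residual = {
            chem.sensor_id: frac * adsorption_shift(chem, sample)
            for chem in self.chemistries
        }


def _measure_di_block(
    source: ReadingSource,
    di_sample: LiquidSample,
    schedule: MeasurementSchedule,
    rng: np.random.Generator,
    baseline_id: str,
) -> Baseline:
    history = []
    for k in range(schedule.baseline_window):
        readings = source.measure(di_sample, (k + 1) * schedule.interval_s, rng)
        history.append(
            np.array([readings[sid].lambda_min for sid in range(1, N_SENSORS + 1)])
        )
    source.end_sample(di_sample)
    return update_baseline(history, baseline_id=baseline_id)


def run_session(
    catalog: list[LiquidSample],
    schedules: dict[str, MeasurementSchedule] | None = None,
    source: ReadingSource | None = None,
    seed: int = 0,
) -> FingerprintMatrix:
    """Measure every beverage in the catalog and assemble the matrix.

    Per liquid class: a fresh 10-reading DI-water baseline block, then
    every (sample, replicate) pair of the class in seeded random order,
    each producing ``n_readings`` fingerprints at 30 s spacing with the
    adsorption kinetics evaluated at each reading time.  Rows whose
    extraction was flagged are kept with ``status='flagged'``.
    """
    rng = np.random.default_rng(seed)
    source = source or SimulatedSource()
    di_samples = [s for s in catalog if s.class_label == "di_water"]
    if not di_samples:
        raise ValueError("catalog must contain a di_water standard")
    di_sample = di_samples[0]

    fingerprints: list[Fingerprint] = []
    class_order = [c for c in CLASS_LABELS if any(s.class_label == c for s in catalog)]
    for class_label in class_order:
        schedule = (
            schedules[class_label]
            if schedules and class_label in schedules
            else schedule_for_class(class_label)
        )
        baseline = _measure_di_block(
            source, di_sample, schedule, rng, baseline_id=f"baseline_{class_label}"
        )
        members = [s for s in catalog if s.class_label == class_label]
        runs = [(s, rep) for s in members for rep in range(1, 4)]
        order = rng.permutation(len(runs))
        for idx in order:
            sample, replicate = runs[idx]
            for k in range(schedule.n_readings):
                t = (k + 1) * schedule.interval_s
                readings = source.measure(sample, t, rng)
                fingerprints.append(
                    compute_fingerprint(
                        readings,
                        baseline,
                        sample_id=sample.sample_id,
                        class_label=class_label,
                        replicate=replicate,
                    )
                )
            source.end_sample(sample)
    return FingerprintMatrix.from_fingerprints(fingerprints)


def check_baseline_reversion(
    post_rinse_fingerprint: Fingerprint,
    tolerance_nm: float = DEFAULT_REVERSION_TOLERANCE_NM,
) -> tuple[dict[int, bool], bool]:
    """Rinse QC: per-sensor pass iff |delta lambda| <= tolerance on a DI
    fingerprint taken after rinsing; overall pass iff all 24 pass."""
    per_sensor = {
        sid: bool(abs(post_rinse_fingerprint.delta_lambda[sid - 1]) <= tolerance_nm)
        for sid in range(1, N_SENSORS + 1)
    }
    return per_sensor, all(per_sensor.values())
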