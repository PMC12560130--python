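"""Frame readout: combine, section, and normalize into transmission spectra.

Each sensor aperture is normalized against its adjacent light reference
(the reference immediately preceding it in aperture order), then mapped
through the affine wavelength calibration and resampled onto a uniform
0.1 nm grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .synthetic_chip.layout import ChipLayout, ROLE_REFERENCE, ROLE_SENSOR
from .synthetic_chip.render import HyperspectralFrame

OUTPUT_STEP_NM = 0.1
#: References dimmer than this fraction of the frame maximum are treated
#: as blocked/failed rather than divided by.
REFERENCE_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class TransmissionSpectrum:
    """Wavelength-resolved transmission of one sensor element.

    ``wavelengths`` is a uniform, strictly ascending grid in nm
    (0.1 nm spacing after resampling); ``transmission`` is the
    dimensionless sensor/reference intensity ratio.
    """

    wavelengths: np.ndarray
    transmission: np.ndarray
    sensor_id: int
    time_s: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        tr = np.asarray(self.transmission, dtype=float)
        if wl.shape != tr.shape or wl.ndim != 1:
            raise ValueError("wavelengths and transmission must be matching 1-D arrays")
        if len(wl) >= 2:
            steps = np.diff(wl)
            if np.any(steps <= 0):
                raise ValueError("wavelengths must be strictly ascending")
            if np.ptp(steps) > 1e-9:
                raise ValueError("wavelength grid must be uniform to within 1e-9 nm")
        if not np.all(np.isfinite(tr)) or np.any(tr <= 0):
            raise ValueError("transmission must be finite and > 0")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


def combine_frames(frames: list[HyperspectralFrame]) -> HyperspectralFrame:
    """Pixelwise mean of repeated frames; calibration must agree."""
    if not frames:
        raise ValueError("need at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if f.intensity.shape != first.intensity.shape:
            raise ValueError("frames have mismatched shapes")
        if f.calibration != first.calibration:
            raise ValueError("frames have mismatched calibrations")
    mean = np.mean([f.intensity for f in frames], axis=0)
    return HyperspectralFrame(
        intensity=mean, calibration=first.calibration, layout=first.layout
    )


def section_frame(
    frame: HyperspectralFrame, layout: ChipLayout | None = None
) -> list[np.ndarray]:
    """Average each aperture's pixel columns into one intensity-vs-row
    profile; profiles are returned in aperture order."""
    layout = layout or frame.layout
    n_cols = frame.intensity.shape[1]
    profiles = []
    for ap in range(layout.n_apertures):
        start, stop = layout.column_pixel_map[ap]
        if start < 0 or stop > n_cols or start >= stop:
            raise ValueError(
                f"aperture {ap} column range ({start}, {stop}) outside frame "
                f"width {n_cols}"
            )
        profiles.append(frame.intensity[:, start:stop].mean(axis=1))
    return profiles


def reference_for_sensor(layout: ChipLayout, sensor_aperture: int) -> int:
    """Aperture index of the light reference paired with a sensor.

    Pairing rule: the reference immediately preceding the sensor in
    aperture order; the first sensor (which follows the edge blanks) is
    paired with the reference immediately after it.
    """
    if layout.aperture_roles[sensor_aperture] != ROLE_SENSOR:
        raise ValueError(f"aperture {sensor_aperture} is not a sensor")
    if (
        sensor_aperture > 0
        and layout.aperture_roles[sensor_aperture - 1] == ROLE_REFERENCE
    ):
        return sensor_aperture - 1
    if (
        sensor_aperture + 1 < layout.n_apertures
        and layout.aperture_roles[sensor_aperture + 1] == ROLE_REFERENCE
    ):
        return sensor_aperture + 1
    raise ValueError(f"sensor aperture {sensor_aperture} has no adjacent reference")


def to_transmission(
    sensor_profile: np.ndarray,
    reference_profile: np.ndarray,
    calibration: tuple[float, float],
    *,
    sensor_id: int = 0,
    time_s: float = 0.0,
    floor: float | None = None,
) -> TransmissionSpectrum:
    """Normalize a sensor profile by its reference and resample to 0.1 nm.

    ``floor`` is the minimum acceptable reference intensity; by default
    1% of the reference maximum.  A reference below it signals a
    blocked or failed aperture and raises ``ValueError``.
    """
    sensor_profile = np.asarray(sensor_profile, dtype=float)
    reference_profile = np.asarray(reference_profile, dtype=float)
    if sensor_profile.shape != reference_profile.shape:
        raise ValueError("sensor and reference profiles must have the same length")
    if floor is None:
        floor = REFERENCE_FLOOR_FRACTION * float(reference_profile.max(initial=0.0))
    if np.any(reference_profile <= floor):
        raise ValueError("reference intensity below floor threshold")

    ratio = sensor_profile / reference_profile
    intercept, slope = calibration
    native_wl = intercept + slope * np.arange(len(ratio))

    lo = np.ceil(native_wl[0] / OUTPUT_STEP_NM) * OUTPUT_STEP_NM
    n_out = int(np.floor((native_wl[-1] - lo) / OUTPUT_STEP_NM)) + 1
    grid = lo + OUTPUT_STEP_NM * np.arange(n_out)
    resampled = CubicSpline(native_wl, ratio)(grid)
    resampled = np.clip(resampled, 1e-12, None)
    return TransmissionSpectrum(
        wavelengths=grid, transmission=resampled, sensor_id=sensor_id, time_s=time_s
    )


def frame_to_spectra(
    frame: HyperspectralFrame, *, time_s: float = 0.0
) -> dict[int, TransmissionSpectrum]:
    """Full readout of one frame: map sensor_id -> transmission spectrum."""
    layout = frame.layout
    profiles = section_frame(frame, layout)
    spectra: dict[int, TransmissionSpectrum] = {}
    for ap in layout.sensor_apertures:
        ref_ap = reference_for_sensor(layout, ap)
        sid = layout.sensor_ids[ap]
        spectra[sid] = to_transmission(
            profiles[ap],
            profiles[ref_ap],
            frame.calibration,
            sensor_id=sid,
            time_s=time_s,
        )
    return spectra


def spectra_to_csv(spectra: dict[int, TransmissionSpectrum], path: str | Path) -> None:
    """Long-format CSV export: sensor_id, time_s, wavelength_nm, transmission."""
    chunks = []
    for sid in sorted(spectra):
        sp = spectra[sid]
        chunks.append(
            pd.DataFrame(
                {
                    "sensor_id": sid,
                    "time_s": sp.time_s,
                    "wavelength_nm": sp.wavelengths,
                    "transmission": sp.transmission,
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False)
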