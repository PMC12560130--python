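"""Rendering of hyperspectral frames and synthetic transmission spectra.

A frame mimics the camera image behind the diffraction grating: each
aperture projects a column of transmitted light, rows map affinely to
wavelength, and sensor columns carry a Lorentzian plasmonic dip on the
lamp profile while reference columns carry the bare lamp profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import ChipLayout, ROLE_SENSOR
from .response import ResponseModel

DEFAULT_WAVELENGTH_MIN = 550.0
DEFAULT_WAVELENGTH_MAX = 900.0
DEFAULT_ROW_STEP_NM = 0.5
LAMP_CENTER_NM = 725.0
LAMP_SIGMA_NM = 150.0
LAMP_PEAK = 30000.0


@dataclass(frozen=True)
class DipParams:
    """Lorentzian dip of one sensor aperture: centre, depth, full width."""

    center_nm: float
    depth: float
    fwhm_nm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.depth < 1.0:
            raise ValueError("depth must be in (0, 1)")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")


@dataclass(frozen=True)
class HyperspectralFrame:
    """Camera frame: rows are the wavelength axis, columns the detector.

    ``calibration`` is the affine row->nm map ``(intercept, slope)``
    with strictly positive slope.
    """

    intensity: np.ndarray
    calibration: tuple[float, float]
    layout: ChipLayout

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        if self.calibration[1] <= 0:
            raise ValueError("calibration must be strictly increasing in row index")

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelength (nm) of each row."""
        intercept, slope = self.calibration
        return intercept + slope * np.arange(self.intensity.shape[0])


def lamp_profile(wavelengths: np.ndarray) -> np.ndarray:
    """Broad Gaussian lamp spectrum in intensity counts."""
    return LAMP_PEAK * np.exp(
        -0.5 * ((np.asarray(wavelengths) - LAMP_CENTER_NM) / LAMP_SIGMA_NM) ** 2
    )


def lorentzian_transmission(
    wavelengths: np.ndarray, center_nm: float, depth: float, fwhm_nm: float
) -> np.ndarray:
    """Transmission with a Lorentzian dip:
    ``T = 1 - d / (1 + ((l - l0) / (G/2))^2)``."""
    x = (np.asarray(wavelengths) - center_nm) / (fwhm_nm / 2.0)
    return 1.0 - depth / (1.0 + x**2)


def render_frame(
    layout: ChipLayout,
    dips: dict[int, DipParams],
    response_model: ResponseModel,
    seed: int | np.random.Generator = 0,
    *,
    wavelength_range: tuple[float, float] = (
        DEFAULT_WAVELENGTH_MIN,
        DEFAULT_WAVELENGTH_MAX,
    ),
    row_step_nm: float = DEFAULT_ROW_STEP_NM,
) -> HyperspectralFrame:
    """Render one hyperspectral frame.

    Parameters
    ----------
    dips:
        Map sensor aperture index -> dip parameters.  Every sensor
        aperture must be present; reference and blank apertures carry no
        dip.
    seed:
        Integer seed or generator; multiplicative Gaussian intensity
        noise of relative sd ``response_model.intensity_noise_sd`` is
        applied to every lit pixel.  The same seed yields a
        bit-identical frame.
    """
    sensor_aps = set(layout.sensor_apertures)
    if set(dips) != sensor_aps:
        missing = sensor_aps - set(dips)
        extra = set(dips) - sensor_aps
        raise ValueError(
            f"dips must cover exactly the sensor apertures; missing={sorted(missing)}, "
            f"non-sensor={sorted(extra)}"
        )
    lo, hi = wavelength_range
    for ap, dip in dips.items():
        if not lo <= dip.center_nm <= hi:
            raise ValueError(
                f"dip centre {dip.center_nm} nm of aperture {ap} outside "
                f"wavelength range [{lo}, {hi}] nm"
            )

    n_rows = int(round((hi - lo) / row_step_nm)) + 1
    wavelengths = lo + row_step_nm * np.arange(n_rows)
    lamp = lamp_profile(wavelengths)

    n_cols = max(stop for _, stop in layout.column_pixel_map.values())
    frame = np.zeros((n_rows, n_cols))
    for ap in range(layout.n_apertures):
        start, stop = layout.column_pixel_map[ap]
        column = lamp.copy()
        if layout.aperture_roles[ap] == ROLE_SENSOR:
            dip = dips[ap]
            column = column * lorentzian_transmission(
                wavelengths, dip.center_nm, dip.depth, dip.fwhm_nm
            )
        frame[:, start:stop] = column[:, None]

    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if response_model.intensity_noise_sd > 0:
        frame = frame * (
            1.0 + rng.normal(0.0, response_model.intensity_noise_sd, size=frame.shape)
        )
    frame = np.clip(frame, 0.0, None)
    return HyperspectralFrame(
        intensity=frame, calibration=(lo, row_step_nm), layout=layout
    )


def simulate_spectrum(
    center_nm: float,
    response_model: ResponseModel | None = None,
    seed: int | np.random.Generator = 0,
    *,
    wavelength_range: tuple[float, float] = (
        DEFAULT_WAVELENGTH_MIN,
        DEFAULT_WAVELENGTH_MAX,
    ),
    step_nm: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic transmission spectrum on a uniform grid.

    Shortcut past frame rendering: the analytic Lorentzian dip with
    multiplicative Gaussian noise of the model's relative sd.  Returns
    ``(wavelengths, transmission)``.
    """
    model = response_model or ResponseModel()
    lo, hi = wavelength_range
    n = int(round((hi - lo) / step_nm)) + 1
    wavelengths = lo + step_nm * np.arange(n)
    transmission = lorentzian_transmission(
        wavelengths, center_nm, model.dip_depth, model.dip_fwhm
    )
    if model.intensity_noise_sd > 0:
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        transmission = transmission * (
            1.0 + rng.normal(0.0, model.intensity_noise_sd, size=n)
        )
    return wavelengths, transmission
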