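"""Sensor response physics: bulk-RI shift, Langmuir adsorption, kinetics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import ANALYTE_FEATURES, ChemistryProfile
from .samples import LiquidSample, RI_WATER_25C

#: Slow on-rate for macromolecule binding: response stabilizes on the
#: ~8 minute scale (1/k = 180 s, ~95% developed after 9 min).
MACROMOLECULE_RATE = 1.0 / 180.0


@dataclass(frozen=True)
class ResponseModel:
    """Instrument/transducer parameters shared by all sensor elements.

    ``bulk_sensitivity`` converts a bulk refractive-index change into a
    resonance shift (nm/RIU).  The dip rendered on a transmission
    spectrum is a Lorentzian of fractional depth ``dip_depth`` and full
    width ``dip_fwhm``.  Noise is multiplicative Gaussian on intensity;
    drift and carryover are opt-in (default 0).
    """

    bulk_sensitivity: float = 250.0  # nm per RIU
    dip_depth: float = 0.5
    dip_fwhm: float = 80.0  # nm
    intensity_noise_sd: float = 0.005  # relative
    baseline_drift_rate: float = 0.0  # nm/hour
    carryover_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.bulk_sensitivity <= 0:
            raise ValueError("bulk_sensitivity must be > 0")
        if not 0.0 < self.dip_depth < 1.0:
            raise ValueError("dip_depth must be in (0, 1)")
        if self.dip_fwhm <= 0:
            raise ValueError("dip_fwhm must be > 0")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        if not 0.0 <= self.carryover_fraction < 1.0:
            raise ValueError("carryover_fraction must be in [0, 1)")


def equilibrium_shift(
    chemistry: ChemistryProfile,
    sample: LiquidSample,
    response_model: ResponseModel,
) -> float:
    """Equilibrium resonance shift (nm) of one sensor in one liquid.

    Sum of the bulk refractive-index term and a Langmuir occupancy term
    per analyte feature:

        dl = S_bulk * (n_sample - n_water)
             + sum_j affinity_j * c_j / (K_j + c_j)
    """
    bulk = response_model.bulk_sensitivity * (sample.refractive_index - RI_WATER_25C)
    conc = sample.composition.feature_vector()
    affinity = np.asarray(chemistry.affinity)
    half_sat = np.asarray(chemistry.half_saturation)
    adsorption = float(np.sum(affinity * conc / (half_sat + conc)))
    return bulk + adsorption


def adsorption_shift(chemistry: ChemistryProfile, sample: LiquidSample) -> float:
    """Adsorption-only part of the equilibrium shift (no bulk-RI term).

    This is what can survive a rinse: molecules retained on the surface,
    not the bulk liquid (which is exchanged)."""
    conc = sample.composition.feature_vector()
    affinity = np.asarray(chemistry.affinity)
    half_sat = np.asarray(chemistry.half_saturation)
    return float(np.sum(affinity * conc / (half_sat + conc)))


def kinetic_shift(delta_lambda_eq: float, rate: float, t: float | np.ndarray):
    """First-order saturating development toward the equilibrium shift.

    ``dl(t) = dl_eq * (1 - exp(-rate * t))``; monotone in ``t``.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = delta_lambda_eq * (1.0 - np.exp(-rate * t))
    return float(out) if out.ndim == 0 else out


def effective_rate(chemistry: ChemistryProfile, sample: LiquidSample) -> float:
    """Observed on-rate for one sensor in one liquid.

    Small molecules and ions bind at the chemistry's base rate;
    macromolecules diffuse to the surface slowly.  The observed time
    constant is the mix of the two routes' time constants, weighted by
    each route's share of the adsorption shift, so macromolecule-rich
    liquids (beer-like) develop their fingerprint over minutes rather
    than seconds.
    """
    conc = sample.composition.feature_vector()
    affinity = np.asarray(chemistry.affinity)
    half_sat = np.asarray(chemistry.half_saturation)
    contributions = affinity * conc / (half_sat + conc)
    total = float(contributions.sum())
    if total <= 0:
        return chemistry.kinetic_rate
    macro_idx = ANALYTE_FEATURES.index("macromolecules")
    w_slow = float(contributions[macro_idx]) / total
    tau = (1.0 - w_slow) / chemistry.kinetic_rate + w_slow / MACROMOLECULE_RATE
    return 1.0 / tau
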