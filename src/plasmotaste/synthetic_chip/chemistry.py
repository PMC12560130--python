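"""Per-sensor surface-chemistry profiles that make the array cross-reactive.

The affinity table below is synthetic: it is hand-set so that the
qualitative behaviour of the real chip holds (carboxylate and
cation-receptor elements respond strongly to divalent cations,
cyclodextrin cavitands to aroma compounds, hydrophobic/neutral elements
bind beer-like macromolecules slowly), not measured from any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Analyte feature axes, fixed order shared by compositions and affinities.
ANALYTE_FEATURES = (
    "sugars",
    "divalent_cations",
    "monovalent_cations",
    "macromolecules",
    "organic_acids",
    "aroma_compounds",
)

NOMINAL_RESONANCE_NM = 709.0
#: The per-element resonance spread is quoted as +/- 4 nm; a Gaussian with
#: sd 4/sqrt(2) nm puts ~95% of elements inside that band.
RESONANCE_SPREAD_NM = 4.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class ChemistryProfile:
    """Affinity and kinetics of one functionalized sensor element.

    ``affinity[j]`` is the saturation resonance shift (nm) contributed by
    analyte feature ``ANALYTE_FEATURES[j]``; ``half_saturation[j]`` is the
    Langmuir half-saturation concentration of that feature (same units as
    the composition, g/L except ABV).
    """

    sensor_id: int
    label: str
    affinity: tuple[float, ...]
    half_saturation: tuple[float, ...]
    kinetic_rate: float  # base first-order on-rate, s^-1
    resonance_water: float  # nominal dip centre in water, nm

    def __post_init__(self) -> None:
        if not 1 <= self.sensor_id <= 24:
            raise ValueError("sensor_id must be in 1..24")
        if len(self.affinity) != len(ANALYTE_FEATURES):
            raise ValueError("affinity must have one entry per analyte feature")
        if len(self.half_saturation) != len(ANALYTE_FEATURES):
            raise ValueError("half_saturation must have one entry per analyte feature")
        if not all(np.isfinite(self.affinity)):
            raise ValueError("affinity entries must be finite")
        if any(k <= 0 for k in self.half_saturation):
            raise ValueError("half_saturation entries must be > 0")
        if self.kinetic_rate <= 0:
            raise ValueError("kinetic_rate must be > 0")


# label, (sugars, Ca/Mg, Na/K, macromolecules, organic acids, aroma) saturation
# shifts in nm.  Sensors 13-15 and 22 carry the divalent-cation response,
# 23/24 the cavitand aroma response, 3 hides a fixed positive charge behind a
# hydrophobic chain, 16 is a long neutral ester.
_AFFINITY_TABLE: list[tuple[str, tuple[float, ...]]] = [
    ("hydroxyl-terminated thiol", (1.2, 0.05, 0.05, 0.2, 0.2, 0.05)),
    ("ethylene-glycol thiol", (1.0, 0.05, 0.05, 0.1, 0.1, 0.05)),
    ("hydrophobic chain, hidden cation", (0.1, 0.1, 0.3, 1.0, 1.2, 0.9)),
    ("short alkanethiol", (0.1, 0.05, 0.05, 1.1, 0.2, 0.6)),
    ("long alkanethiol", (0.05, 0.05, 0.05, 1.4, 0.1, 0.8)),
    ("aromatic pi-stacking thiol", (0.1, 0.1, 0.05, 0.8, 0.5, 1.3)),
    ("perfluorinated thiol", (0.05, 0.05, 0.05, 0.6, 0.1, 0.4)),
    ("amine-terminated thiol", (0.3, 0.1, 0.2, 0.5, 1.5, 0.2)),
    ("quaternary ammonium thiol", (0.2, 0.1, 0.4, 0.4, 1.8, 0.1)),
    ("pyridinium thiol", (0.2, 0.2, 0.3, 0.5, 1.4, 0.3)),
    ("sulfonate thiol", (0.2, 1.0, 0.5, 0.3, 0.2, 0.1)),
    ("phosphonate thiol", (0.2, 1.3, 0.4, 0.3, 0.2, 0.1)),
    ("short-chain carboxylate", (0.1, 2.2, 0.6, 0.2, 0.3, 0.1)),
    ("mid-chain carboxylate", (0.1, 2.0, 0.5, 0.3, 0.3, 0.1)),
    ("long-chain carboxylate", (0.1, 1.8, 0.4, 0.5, 0.3, 0.2)),
    ("long-chain neutral ester", (0.2, 0.1, 0.05, 1.2, 0.3, 1.1)),
    ("thioether podand", (0.3, 0.6, 0.3, 0.3, 0.3, 0.4)),
    ("crown-ether thiol", (0.2, 0.8, 1.2, 0.2, 0.2, 0.2)),
    ("boronic-acid thiol", (1.8, 0.2, 0.1, 0.3, 0.4, 0.1)),
    ("diol-terminated thiol", (1.5, 0.1, 0.1, 0.2, 0.3, 0.1)),
    ("imidazole thiol", (0.3, 0.7, 0.3, 0.4, 1.0, 0.3)),
    ("strong cation receptor", (0.1, 2.5, 0.9, 0.2, 0.3, 0.2)),
    ("alpha-cyclodextrin", (0.4, 0.5, 0.2, 0.5, 0.2, 2.2)),
    ("beta-cyclodextrin", (0.4, 0.5, 0.2, 0.6, 0.2, 2.6)),
]

#: Half-saturation concentrations per feature (g/L; ABV-free features only
#: enter adsorption, ethanol acts through the bulk refractive index).
_HALF_SATURATION = (25.0, 0.15, 0.8, 1.5, 2.0, 0.30)

#: Global scale on the affinity table: keeps differential (adsorption)
#: shifts small against the bulk-RI term so the first principal
#: component stays bulk-dominated, while staying far above the ~0.02 nm
#: wavelength noise floor.
_AFFINITY_SCALE = 0.5

#: Base on-rate for small molecules and ions: saturates well inside the
#: first 30 s reading interval.
_BASE_RATE = 0.12


def default_chemistries(seed: int = 0) -> list[ChemistryProfile]:
    """Return the 24 default sensor chemistries for one simulated chip.

    Per-element water resonances are drawn once (seeded) around the
    709 nm nominal centre and are fixed for the life of the chip.
    """
    rng = np.random.default_rng(seed)
    resonances = NOMINAL_RESONANCE_NM + rng.normal(0.0, RESONANCE_SPREAD_NM, size=24)
    profiles = []
    for i, (label, affinity) in enumerate(_AFFINITY_TABLE):
        profiles.append(
            ChemistryProfile(
                sensor_id=i + 1,
                label=label,
                affinity=tuple(_AFFINITY_SCALE * a for a in affinity),
                half_saturation=_HALF_SATURATION,
                kinetic_rate=_BASE_RATE,
                resonance_water=float(resonances[i]),
            )
        )
    return profiles
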