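"""Liquid samples: compositions, refractive indices, and the default catalog.

The catalog mirrors a six-class beverage roster (mineral water, beer,
white wine, whiskey, vodka, gin) measured against a deionized-water
standard.  Compositions are drawn from class-conditional lognormal
distributions with hand-set medians; they are synthetic stand-ins, not
assay results.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .chemistry import ANALYTE_FEATURES

#: Refractive index of pure water at 25 C (sodium D line).
RI_WATER_25C = 1.33250

# Ethanol-water refractive index at 25 C versus % v/v ethanol.
# Values follow published 25 C mixture data up to ~80% v/v; the shallow
# physical decrease above ~80% is clipped to a plateau so that the
# interpolant is monotone nondecreasing (no beverage in the catalog
# exceeds 50% ABV, so the clipped region is never exercised).
_ABV_NODES = np.array(
    [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0,
     60.0, 70.0, 80.0, 90.0, 100.0]
)
_RI_NODES = np.array(
    [1.33250, 1.33530, 1.33830, 1.34140, 1.34430, 1.34700, 1.34950,
     1.35180, 1.35400, 1.35580, 1.35740, 1.35980, 1.36130, 1.36200,
     1.36200, 1.36200]
)
_RI_OF_ABV = PchipInterpolator(_ABV_NODES, _RI_NODES)

#: Linear refractive-index increment per g/L of each dissolved-solid
#: feature (order = ANALYTE_FEATURES); magnitudes follow typical
#: solute dn/dc values (sucrose ~1.4e-4, salts ~1.7-2.0e-4, protein ~1.8e-4).
RI_INCREMENTS = {
    "sugars": 1.44e-4,
    "divalent_cations": 2.0e-4,
    "monovalent_cations": 1.7e-4,
    "macromolecules": 1.8e-4,
    "organic_acids": 1.5e-4,
    "aroma_compounds": 1.5e-4,
}

CLASS_LABELS = (
    "mineral_water", "beer", "white_wine", "whiskey", "vodka", "gin",
)
#: Number of distinct beverage examples per class in the default catalog.
CLASS_COUNTS = {
    "mineral_water": 6,
    "beer": 6,
    "white_wine": 8,
    "whiskey": 5,
    "vodka": 4,
    "gin": 6,
}


@dataclass(frozen=True)
class AnalyteComposition:
    """Analyte content of a liquid: ABV (% v/v) plus dissolved-solid
    feature concentrations in g/L."""

    abv: float = 0.0
    sugars: float = 0.0
    divalent_cations: float = 0.0
    monovalent_cations: float = 0.0
    macromolecules: float = 0.0
    organic_acids: float = 0.0
    aroma_compounds: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abv <= 100.0:
            raise ValueError(f"abv must be in [0, 100], got {self.abv}")
        for name in ANALYTE_FEATURES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be >= 0")

    def feature_vector(self) -> np.ndarray:
        """Concentrations in ``ANALYTE_FEATURES`` order (excludes ABV)."""
        return np.array([getattr(self, name) for name in ANALYTE_FEATURES])

    def is_zero(self) -> bool:
        return self.abv == 0.0 and not self.feature_vector().any()


@dataclass(frozen=True)
class LiquidSample:
    sample_id: str
    class_label: str
    composition: AnalyteComposition
    refractive_index: float

    def __post_init__(self) -> None:
        if self.refractive_index < RI_WATER_25C - 1e-12:
            raise ValueError("refractive_index below that of pure water at 25 C")
        if self.class_label == "di_water" and not self.composition.is_zero():
            raise ValueError("di_water must have an all-zero composition")


def composition_to_ri(composition: AnalyteComposition) -> float:
    """Refractive index of a liquid from its composition.

    Interpolates the embedded 25 C ethanol-water table at the sample's
    ABV (monotone PCHIP) and adds a linear increment per g/L of each
    dissolved-solid feature.  Monotone nondecreasing in every feature.
    """
    ri = float(_RI_OF_ABV(composition.abv))
    for name in ANALYTE_FEATURES:
        ri += RI_INCREMENTS[name] * getattr(composition, name)
    return ri


def di_water_sample(sample_id: str = "di_water") -> LiquidSample:
    comp = AnalyteComposition()
    return LiquidSample(sample_id, "di_water", comp, composition_to_ri(comp))


# Class-conditional generators: ABV ~ clipped Normal(mean, sd);
# solids ~ lognormal(median, sigma) per feature, exactly zero where the
# median is zero.  Medians in g/L.
_CLASS_ABV = {
    "mineral_water": (0.0, 0.0),
    "beer": (4.8, 0.8),
    "white_wine": (12.0, 1.0),
    "whiskey": (41.0, 2.0),
    "vodka": (40.0, 0.8),
    "gin": (41.0, 2.0),
}
_CLASS_SOLIDS = {
    # feature: (median g/L, lognormal sigma)
    "mineral_water": {
        "divalent_cations": (0.08, 0.8),
        "monovalent_cations": (0.02, 1.0),
    },
    "beer": {
        "sugars": (28.0, 0.35),
        "divalent_cations": (0.05, 0.5),
        "monovalent_cations": (0.03, 0.5),
        "macromolecules": (4.0, 0.4),
        "organic_acids": (1.5, 0.4),
        "aroma_compounds": (0.05, 0.5),
    },
    "white_wine": {
        "sugars": (6.0, 0.9),
        "divalent_cations": (0.08, 0.5),
        "monovalent_cations": (0.05, 0.5),
        "macromolecules": (0.3, 0.5),
        "organic_acids": (6.0, 0.3),
        "aroma_compounds": (0.10, 0.5),
    },
    "whiskey": {
        "sugars": (1.0, 0.6),
        "divalent_cations": (0.002, 0.5),
        "monovalent_cations": (0.002, 0.5),
        "macromolecules": (0.02, 0.5),
        "organic_acids": (0.60, 0.5),
        "aroma_compounds": (0.25, 0.4),
    },
    "vodka": {
        "sugars": (0.05, 0.5),
        "divalent_cations": (0.001, 0.5),
        "monovalent_cations": (0.001, 0.5),
        "macromolecules": (0.002, 0.5),
        "organic_acids": (0.01, 0.5),
        "aroma_compounds": (0.003, 0.5),
    },
    "gin": {
        "sugars": (0.10, 0.6),
        "divalent_cations": (0.001, 0.5),
        "monovalent_cations": (0.001, 0.5),
        "macromolecules": (0.01, 0.5),
        "organic_acids": (0.05, 0.5),
        "aroma_compounds": (0.60, 0.4),
    },
}

_CLASS_PREFIX = {
    "mineral_water": "MW",
    "beer": "Beer",
    "white_wine": "Wine",
    "whiskey": "Whiskey",
    "vodka": "Vodka",
    "gin": "Gin",
}


def _draw_composition(class_label: str, rng: np.random.Generator) -> AnalyteComposition:
    abv_mean, abv_sd = _CLASS_ABV[class_label]
    abv = 0.0 if abv_sd == 0 else float(np.clip(rng.normal(abv_mean, abv_sd), 0, 100))
    solids = {}
    for feature in ANALYTE_FEATURES:
        median, sigma = _CLASS_SOLIDS[class_label].get(feature, (0.0, 0.0))
        if median > 0:
            solids[feature] = float(median * rng.lognormal(0.0, sigma))
        else:
            solids[feature] = 0.0
    return AnalyteComposition(abv=abv, **solids)


def default_catalog(seed: int = 42) -> list[LiquidSample]:
    """The default synthetic sample roster.

    Returns the DI-water standard followed by 35 beverages with class
    counts (6, 6, 8, 5, 4, 6).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    samples = [di_water_sample()]
    for class_label in CLASS_LABELS:
        prefix = _CLASS_PREFIX[class_label]
        for k in range(CLASS_COUNTS[class_label]):
            comp = _draw_composition(class_label, rng)
            samples.append(
                LiquidSample(
                    sample_id=f"{prefix}{k + 1}",
                    class_label=class_label,
                    composition=comp,
                    refractive_index=composition_to_ri(comp),
                )
            )
    return samples


def catalog_to_csv(samples: list[LiquidSample], path: str | Path) -> None:
    """Export a catalog as CSV with one row per sample."""
    fields = ["sample_id", "class_label", "abv", *ANALYTE_FEATURES, "refractive_index"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for s in samples:
            writer.writerow(
                [s.sample_id, s.class_label, s.composition.abv]
                + [getattr(s.composition, f) for f in ANALYTE_FEATURES]
                + [s.refractive_index]
            )
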