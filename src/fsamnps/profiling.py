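"""FSAm-NPS scoring of individual foods and beverages.

The score of a product is built from its composition per 100 g (solids) or
100 ml (drinks): up to 40 "A" points for nutrients to limit (energy, sugars,
saturated fat, sodium; 0-10 each) minus up to 15 "C" points for components
to encourage (fiber, protein, and the percentage of fruits, vegetables,
legumes, nuts and rapeseed/walnut/olive oils; 0-5 each).  The total runs on
a discrete scale from -15 (healthiest) to 40 (least healthy) for general
foods.  Category exceptions follow the 2015 French HCSP modification:

* **cheese** -- protein points always count, even when the A subtotal is high;
* **added fats** -- saturated fat is scored as the ratio of saturates to total
  fat, on a dedicated grid;
* **beverages** -- steeper energy and sugar grids, and a fruit/vegetable
  component worth up to 10 points.

Protein-cap rule: for any non-cheese food with A subtotal >= 11 whose
fruit/vegetable/legume component is below its maximum, protein points are
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .bands import A_COMPONENTS, C_COMPONENTS, BandConfigError, ScoringBands, default_bands

__all__ = [
    "NutrientProfile", "FoodScore", "component_points", "a_subtotal",
    "c_subtotal", "score_food", "score_table", "reclassify_olive_oil",
    "load_composition", "CATEGORIES",
]

CATEGORIES = ("general", "beverage", "cheese", "added_fat")

#: conversion factors used by the loaders
KCAL_TO_KJ = 4.184
SALT_G_TO_SODIUM_MG = 1000.0 / 2.5


@dataclass(frozen=True)
class NutrientProfile:
    """Composition of one food or beverage per 100 g/ml.

    ``fvln_pct`` is the percentage (0-100) of fruits, vegetables, legumes,
    nuts and rapeseed/walnut/olive oil in the product.  ``total_fat`` is
    used only for the added-fat saturated-fat ratio.
    """

    item_id: str
    energy: float          # kJ per 100 g/ml
    sugars: float          # g
    satfat: float          # g
    sodium: float          # mg
    fiber: float           # g
    protein: float         # g
    fvln_pct: float        # %
    total_fat: float = 0.0  # g; only consulted for category == "added_fat"
    category: str = "general"

    def __post_init__(self) -> None:
        for f in ("energy", "sugars", "satfat", "sodium", "fiber",
                  "protein", "total_fat"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0 for item {self.item_id!r}")
        if not 0 <= self.fvln_pct <= 100:
            raise ValueError(f"fvln_pct must lie in [0, 100] "
                             f"(item {self.item_id!r})")
        if self.total_fat > 0 and self.satfat > self.total_fat + 1e-9:
            raise ValueError(f"satfat exceeds total fat (item {self.item_id!r})")
        if self.category not in CATEGORIES:
            raise BandConfigError(f"unknown scoring category "
                                  f"{self.category!r} (item {self.item_id!r})")


@dataclass(frozen=True)
class FoodScore:
    """Component point breakdown and total FSAm-NPS for one item."""

    item_id: str
    a_energy: int
    a_sugars: int
    a_satfat: int
    a_sodium: int
    c_fvln: int
    c_fiber: int
    c_protein: int
    a_total: int
    c_total: int
    total: int
    protein_counted: bool
    #: True when the total was overridden (olive-oil sensitivity analysis),
    #: in which case total no longer equals a_total - c_total.
    override: bool = False


def component_points(value: float, component: str, category: str,
                     bands: ScoringBands | None = None) -> int:
    """Points for one component: the step-function value of the band table.

    Equal to the number of (non-skipping) thresholds strictly exceeded; with
    non-unit point steps (the fvln grids) it is the points attached to the
    highest threshold strictly exceeded.
    """
    if value < 0:
        raise ValueError(f"negative {component} value {value}")
    bands = bands or default_bands()
    pts = 0
    for threshold, points in bands.table(component, category):
        if value > threshold:
            pts = points
        else:
            break
    return pts


def a_subtotal(profile: NutrientProfile,
               bands: ScoringBands | None = None) -> int:
    """Sum of the four A-component points (0-40).

    For added fats the saturated-fat component is scored on
    ``100 * satfat / total_fat`` using the ratio grid; an added fat declaring
    zero total fat scores 0 on that component (with a warning).
    """
    bands = bands or default_bands()
    pts = 0
    for comp in A_COMPONENTS:
        if comp == "satfat" and profile.category == "added_fat":
            if profile.total_fat <= 0:
                warnings.warn(
                    f"added fat {profile.item_id!r} has zero total fat; "
                    "saturated-fat ratio scored as 0 points", stacklevel=2)
                continue
            ratio = 100.0 * profile.satfat / profile.total_fat
            pts += component_points(ratio, "satfat_ratio", "added_fat", bands)
        else:
            pts += component_points(getattr(profile, comp), comp,
                                    profile.category, bands)
    return pts


def c_subtotal(profile: NutrientProfile, a_total: int,
               bands: ScoringBands | None = None) -> tuple[int, bool]:
    """C-component subtotal and whether protein was counted.

    Protein points are discarded when the A subtotal reaches the cap
    (default 11) while the fruit/vegetable/legume component is below its
    maximum -- except for cheese, which always counts protein.
    """
    bands = bands or default_bands()
    fvln_pts = component_points(profile.fvln_pct, "fvln", profile.category, bands)
    fiber_pts = component_points(profile.fiber, "fiber", profile.category, bands)
    protein_pts = component_points(profile.protein, "protein",
                                   profile.category, bands)
    fvln_max = bands.max_points("fvln", profile.category)
    protein_counted = (a_total < bands.protein_cap_threshold
                       or fvln_pts >= fvln_max
                       or profile.category == "cheese")
    c_total = fvln_pts + fiber_pts + (protein_pts if protein_counted else 0)
    return c_total, protein_counted


def score_food(profile: NutrientProfile,
               bands: ScoringBands | None = None) -> FoodScore:
    """Full FSAm-NPS of one item: ``total = A subtotal - C subtotal``."""
    bands = bands or default_bands()
    a = {comp: component_points(getattr(profile, comp), comp,
                                profile.category, bands)
         for comp in A_COMPONENTS if not (comp == "satfat"
                                          and profile.category == "added_fat")}
    if profile.category == "added_fat":
        if profile.total_fat <= 0:
            warnings.warn(
                f"added fat {profile.item_id!r} has zero total fat; "
                "saturated-fat ratio scored as 0 points", stacklevel=2)
            a["satfat"] = 0
        else:
            a["satfat"] = component_points(
                100.0 * profile.satfat / profile.total_fat,
                "satfat_ratio", "added_fat", bands)
    a_total = sum(a.values())
    fvln_pts = component_points(profile.fvln_pct, "fvln", profile.category, bands)
    fiber_pts = component_points(profile.fiber, "fiber", profile.category, bands)
    protein_pts = component_points(profile.protein, "protein",
                                   profile.category, bands)
    c_total, protein_counted = c_subtotal(profile, a_total, bands)
    return FoodScore(
        item_id=profile.item_id,
        a_energy=a["energy"], a_sugars=a["sugars"],
        a_satfat=a["satfat"], a_sodium=a["sodium"],
        c_fvln=fvln_pts, c_fiber=fiber_pts,
        c_protein=protein_pts if protein_counted else 0,
        a_total=a_total, c_total=c_total,
        total=a_total - c_total, protein_counted=protein_counted,
    )


def score_table(composition: pd.DataFrame,
                bands: ScoringBands | None = None) -> pd.DataFrame:
    """Score every row of a composition table (see :func:`load_composition`).

    Returns a DataFrame indexed like the input with the FoodScore fields as
    columns.
    """
    bands = bands or default_bands()
    records = []
    for row in composition.itertuples(index=False):
        profile = NutrientProfile(
            item_id=str(row.item_id), energy=row.energy_kj,
            sugars=row.sugars_g, satfat=row.satfat_g, sodium=row.sodium_mg,
            fiber=row.fiber_g, protein=row.protein_g, fvln_pct=row.fvln_pct,
            total_fat=getattr(row, "fat_g", 0.0), category=row.category,
        )
        records.append(score_food(profile, bands))
    return pd.DataFrame([vars(s) for s in records])


def reclassify_olive_oil(scores: Iterable[FoodScore],
                         olive_oil_ids: Sequence[str] | set[str],
                         value: int = -8) -> list[FoodScore]:
    """Sensitivity reclassification: set designated items' totals to -8.

    Olive oil is treated as maximally healthy (the score of fruits,
    vegetables or legumes); every other item is returned unchanged.
    """
    ids = set(olive_oil_ids)
    scored_ids = {s.item_id for s in scores}
    missing = ids - scored_ids
    if missing:
        raise KeyError(f"olive-oil ids not among scored items: "
                       f"{sorted(missing)}")
    return [replace(s, total=value, override=True) if s.item_id in ids else s
            for s in scores]


def load_composition(path) -> pd.DataFrame:
    """Read a tidy composition CSV and normalise units for scoring.

    Expected columns: ``item_id, name, category, energy_kj`` (or
    ``energy_kcal``), ``sugars_g, satfat_g, fat_g, sodium_mg`` (or
    ``salt_g``), ``fiber_g, protein_g, fvln_pct``.  kcal are converted to kJ
    (x 4.184) and salt to sodium (x 400 mg/g).
    """
    df = pd.read_csv(path)
    if "energy_kj" not in df.columns:
        if "energy_kcal" not in df.columns:
            raise BandConfigError("composition table needs energy_kj or "
                                  "energy_kcal")
        df["energy_kj"] = df["energy_kcal"] * KCAL_TO_KJ
    if "sodium_mg" not in df.columns:
        if "salt_g" not in df.columns:
            raise BandConfigError("composition table needs sodium_mg or salt_g")
        df["sodium_mg"] = df["salt_g"] * SALT_G_TO_SODIUM_MG
    if "fat_g" not in df.columns:
        df["fat_g"] = 0.0
    required = ["item_id", "category", "energy_kj", "sugars_g", "satfat_g",
                "sodium_mg", "fiber_g", "protein_g", "fvln_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BandConfigError(f"composition table missing columns: {missing}")
    df["item_id"] = df["item_id"].astype(str)
    return df
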