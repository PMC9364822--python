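"""Point-allocation grids for the FSAm-NPS scoring engine.

The scoring bands are shipped as a versioned YAML data file
(``data/bands_hcsp2015.yaml``) so the engine is auditable and the grids can
be swapped for other vintages of the nutrient profiling system without code
changes.  Each component is a step function given as ordered
``(threshold, points)`` pairs; a food earns the points of the highest
threshold its content strictly exceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ScoringBands", "load_bands", "default_bands", "BandConfigError"]

#: components whose points count against a food ("negative"/A side)
A_COMPONENTS = ("energy", "sugars", "satfat", "sodium")
#: components whose points count in a food's favour ("positive"/C side)
C_COMPONENTS = ("fvln", "fiber", "protein")

_A_MAX = 10
_C_MAX_GENERAL = 5
_C_MAX_BEVERAGE_FVLN = 10


class BandConfigError(ValueError):
    """Raised when a band table is missing or malformed."""


@dataclass(frozen=True)
class ScoringBands:
    """Validated set of step-function tables for every component/category.

    Parameters
    ----------
    general, beverage, added_fat
        Mapping of component name to a list of ``(threshold, points)``
        pairs.  ``beverage`` entries override the general grid for drinks;
        ``added_fat`` carries the saturated-fat-to-total-fat ratio grid used
        in place of the absolute saturated-fat grid.
    protein_cap_threshold
        A-subtotal at which protein points are conditionally discarded.
    version
        Identifier of the grid vintage, carried through for provenance.
    """

    general: dict[str, list[tuple[float, int]]]
    beverage: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    added_fat: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    protein_cap_threshold: int = 11
    version: str = "unversioned"

    def __post_init__(self) -> None:
        for cat_name, table in (("general", self.general),
                                ("beverage", self.beverage),
                                ("added_fat", self.added_fat)):
            for comp, pairs in table.items():
                self._validate_pairs(cat_name, comp, pairs)

    @staticmethod
    def _validate_pairs(cat: str, comp: str, pairs) -> None:
        if not pairs:
            raise BandConfigError(f"empty band table for {cat}/{comp}")
        thresholds = [t for t, _ in pairs]
        points = [p for _, p in pairs]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise BandConfigError(
                f"thresholds not strictly increasing for {cat}/{comp}")
        if any(b < a for a, b in zip(points, points[1:])) or points[0] < 0:
            raise BandConfigError(
                f"points not non-decreasing for {cat}/{comp}")
        cap = _A_MAX
        if comp in C_COMPONENTS:
            cap = _C_MAX_BEVERAGE_FVLN if (cat == "beverage" and comp == "fvln") \
                else _C_MAX_GENERAL
        if points[-1] > cap:
            raise BandConfigError(
                f"maximum points {points[-1]} exceed cap {cap} for {cat}/{comp}")

    def table(self, component: str, category: str) -> list[tuple[float, int]]:
        """Resolve the band table for one component in one scoring category.

        Beverages fall back to the general grid for components without a
        beverage-specific override; cheese uses the general grid throughout
        (its exception is in the protein-counting rule, not the bands).
        """
        if category in ("general", "cheese"):
            src = self.general
        elif category == "beverage":
            src = {**self.general, **self.beverage}
        elif category == "added_fat":
            src = {**self.general, **self.added_fat}
        else:
            raise BandConfigError(f"unknown scoring category {category!r}")
        try:
            return src[component]
        except KeyError:
            raise BandConfigError(
                f"no band table for component {component!r} in category "
                f"{category!r}") from None

    def max_points(self, component: str, category: str) -> int:
        return self.table(component, category)[-1][1]


def _as_pairs(table: dict) -> dict[str, list[tuple[float, int]]]:
    return {comp: [(float(t), int(p)) for t, p in pairs]
            for comp, pairs in table.items()}


def load_bands(path: str | Path) -> ScoringBands:
    """Load a band-table YAML file (see the bundled default for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_mapping(raw)


def _from_mapping(raw: dict) -> ScoringBands:
    if "general" not in raw:
        raise BandConfigError("band config must define a 'general' table")
    return ScoringBands(
        general=_as_pairs(raw["general"]),
        beverage=_as_pairs(raw.get("beverage", {})),
        added_fat=_as_pairs(raw.get("added_fat", {})),
        protein_cap_threshold=int(raw.get("protein_cap_threshold", 11)),
        version=str(raw.get("version", "unversioned")),
    )


def default_bands() -> ScoringBands:
    """The bundled 2015 HCSP grids (Nutri-Score vintage)."""
    ref = resources.files("fsamnps").joinpath("data/bands_hcsp2015.yaml")
    return _from_mapping(yaml.safe_load(ref.read_text()))
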