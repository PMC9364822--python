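"""Food-frequency-questionnaire processing.

Converts semi-quantitative FFQ reports (item x nine-level frequency
category, with a standard portion per item) into daily gram and nutrient
intakes, and applies the cohort exclusion rules: participants must have a
complete FFQ at both timepoints and a total energy intake within
sex-specific plausibility limits (women 500-3,500 kcal/day, men 800-4,000
kcal/day; values strictly outside are excluded, values exactly at a limit
are retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiling import KCAL_TO_KJ

__all__ = [
    "FrequencyMap", "DEFAULT_FREQUENCY_MAP", "ENERGY_LIMITS_KCAL",
    "TIMEPOINTS", "daily_grams", "nutrient_intake", "intake_table",
    "apply_exclusions",
]

TIMEPOINTS = ("baseline", "year1")

#: nutrients summed by :func:`nutrient_intake`, mapping output name ->
#: (composition column, per-100g divisor)
_NUTRIENT_COLUMNS = {
    "energy_kcal": ("energy_kj", 100.0 * KCAL_TO_KJ),
    "sugars_g": ("sugars_g", 100.0),
    "satfat_g": ("satfat_g", 100.0),
    "sodium_mg": ("sodium_mg", 100.0),
    "fiber_g": ("fiber_g", 100.0),
    "protein_g": ("protein_g", 100.0),
}

#: (lower, upper) total-energy plausibility limits in kcal/day, by sex
ENERGY_LIMITS_KCAL: Mapping[str, tuple[float, float]] = {
    "female": (500.0, 3500.0),
    "male": (800.0, 4000.0),
}


@dataclass(frozen=True)
class FrequencyMap:
    """Ordered mapping of the nine FFQ frequency categories to servings/day.

    Category 1 is "never or almost never" (0 servings); category 9 is "more
    than six times a day".  The instrument prints only the endpoint labels;
    the interior values are the usual Willett-style midpoints and can be
    overridden.
    """

    servings_per_day: tuple[float, ...] = (
        0.0,        # 1 never / almost never
        2.0 / 30,   # 2 one to three times a month
        1.0 / 7,    # 3 once a week
        3.0 / 7,    # 4 two to four times a week
        5.5 / 7,    # 5 five or six times a week
        1.0,        # 6 once a day
        2.5,        # 7 two or three times a day
        5.0,        # 8 four to six times a day
        7.0,        # 9 more than six times a day
    )

    def __post_init__(self) -> None:
        if len(self.servings_per_day) != 9:
            raise ValueError("frequency map must have exactly 9 entries")
        if self.servings_per_day[0] != 0:
            raise ValueError("category 1 ('never') must map to 0")
        if any(b < a for a, b in zip(self.servings_per_day,
                                     self.servings_per_day[1:])):
            raise ValueError("frequency map must be monotone non-decreasing")
        if any(v < 0 for v in self.servings_per_day):
            raise ValueError("servings/day must be non-negative")

    def __call__(self, category: int) -> float:
        if not 1 <= int(category) <= 9:
            raise KeyError(f"frequency category {category} outside 1..9")
        return self.servings_per_day[int(category) - 1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.servings_per_day)


DEFAULT_FREQUENCY_MAP = FrequencyMap()


def daily_grams(frequency_category: int, portion_size: float,
                fmap: FrequencyMap = DEFAULT_FREQUENCY_MAP) -> float:
    """Average g (or ml) per day: servings/day x portion size per serving."""
    if portion_size <= 0:
        raise ValueError("portion_size must be positive")
    return fmap(frequency_category) * portion_size


def nutrient_intake(responses: pd.DataFrame, items: pd.DataFrame,
                    composition: pd.DataFrame,
                    fmap: FrequencyMap = DEFAULT_FREQUENCY_MAP,
                    ) -> tuple[dict[str, float], pd.Series]:
    """Daily nutrient totals for one participant-timepoint.

    Parameters
    ----------
    responses
        Rows ``item_id, frequency_category`` for a single participant and
        timepoint (at most one row per item).
    items
        FFQ item list with ``item_id, portion_g``.
    composition
        Normalised composition table (see ``load_composition``).

    Returns
    -------
    totals
        ``{nutrient: amount/day}`` including ``energy_kcal``.
    item_energy
        kcal/day contributed by each consumed item (the ``Ei`` of the
        dietary index), indexed by ``item_id``.
    """
    if responses.empty:
        warnings.warn("participant has zero FFQ responses; intakes are zero",
                      stacklevel=2)
        zero = {name: 0.0 for name in _NUTRIENT_COLUMNS}
        return zero, pd.Series(dtype=float, name="energy_kcal")
    if responses["item_id"].duplicated().any():
        dup = responses.loc[responses["item_id"].duplicated(), "item_id"]
        raise ValueError(f"duplicate FFQ responses for items {list(dup)}")
    merged = responses.merge(items[["item_id", "portion_g"]], on="item_id",
                             how="left", validate="one_to_one")
    merged = merged.merge(composition, on="item_id", how="left",
                          suffixes=("", "_comp"))
    unresolved = merged.loc[merged["portion_g"].isna()
                            | merged["energy_kj"].isna(), "item_id"]
    if len(unresolved):
        raise KeyError(f"unresolvable FFQ items: {sorted(set(unresolved))}")
    servings = fmap.as_array()[merged["frequency_category"].astype(int) - 1]
    grams = servings * merged["portion_g"].to_numpy()
    totals = {}
    for name, (col, divisor) in _NUTRIENT_COLUMNS.items():
        totals[name] = float(np.sum(grams * merged[col].to_numpy() / divisor))
    item_energy = pd.Series(
        grams * merged["energy_kj"].to_numpy() / (100.0 * KCAL_TO_KJ),
        index=pd.Index(merged["item_id"], name="item_id"), name="energy_kcal")
    return totals, item_energy


def intake_table(responses: pd.DataFrame, items: pd.DataFrame,
                 composition: pd.DataFrame,
                 fmap: FrequencyMap = DEFAULT_FREQUENCY_MAP,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised intakes for a long response table of many participants.

    ``responses`` has columns ``participant_id, timepoint, item_id,
    frequency_category``.  Returns ``(totals, item_energy)`` where *totals*
    has one row per participant-timepoint with the nutrient columns and
    *item_energy* is long format with an ``energy_kcal`` column per item
    (used as the dietary-index weights).
    """
    bad = ~responses["frequency_category"].astype(int).between(1, 9)
    if bad.any():
        raise KeyError("frequency categories outside 1..9 for rows "
                       f"{responses.index[bad].tolist()[:5]}")
    merged = responses.merge(items[["item_id", "portion_g"]], on="item_id",
                             how="left")
    merged = merged.merge(composition, on="item_id", how="left",
                          suffixes=("", "_comp"))
    if merged["portion_g"].isna().any() or merged["energy_kj"].isna().any():
        missing = merged.loc[merged["portion_g"].isna()
                             | merged["energy_kj"].isna(), "item_id"]
        raise KeyError(f"unresolvable FFQ items: {sorted(set(missing))}")
    servings = fmap.as_array()[merged["frequency_category"].astype(int) - 1]
    grams = servings * merged["portion_g"].to_numpy()
    out = merged[["participant_id", "timepoint", "item_id"]].copy()
    for name, (col, divisor) in _NUTRIENT_COLUMNS.items():
        out[name] = grams * merged[col].to_numpy() / divisor
    out["grams"] = grams
    totals = (out.groupby(["participant_id", "timepoint"], sort=False)
              [list(_NUTRIENT_COLUMNS)].sum().reset_index())
    item_energy = out[["participant_id", "timepoint", "item_id",
                       "energy_kcal"]].copy()
    return totals, item_energy


def apply_exclusions(participants: pd.DataFrame, intakes: pd.DataFrame,
                     limits: Mapping[str, tuple[float, float]] = ENERGY_LIMITS_KCAL,
                     timepoints: Sequence[str] = TIMEPOINTS,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the FFQ-completeness and energy-plausibility exclusions.

    A participant is excluded when an FFQ is missing at either timepoint or
    total energy at either timepoint lies strictly outside the sex-specific
    limits.  Idempotent; retained + excluded partition the input.

    Parameters
    ----------
    participants
        One row per participant with ``participant_id`` and ``sex``
        ("female"/"male").
    intakes
        Totals table from :func:`intake_table` (``participant_id, timepoint,
        energy_kcal``); a missing participant-timepoint row means no FFQ.

    Returns
    -------
    retained
        Subset of ``participants`` passing all screens.
    log
        ``participant_id, reason`` with one row per excluded participant
        (first failing reason).
    """
    unknown_sex = set(participants["sex"]) - set(limits)
    if unknown_sex:
        raise ValueError(f"unknown sex codes: {sorted(unknown_sex)}")
    energy = intakes.pivot_table(index="participant_id", columns="timepoint",
                                 values="energy_kcal", aggfunc="first")
    reasons: list[tuple[object, str]] = []
    lo = participants["sex"].map(lambda s: limits[s][0]).to_numpy()
    hi = participants["sex"].map(lambda s: limits[s][1]).to_numpy()
    pid = participants["participant_id"].to_numpy()
    keep = np.ones(len(participants), dtype=bool)
    for tp in timepoints:
        col = energy[tp] if tp in energy.columns else pd.Series(dtype=float)
        e = participants["participant_id"].map(col).to_numpy(dtype=float)
        missing = np.isnan(e)
        out_of_range = (~missing) & ((e < lo) | (e > hi))
        for i in np.flatnonzero(keep & missing):
            reasons.append((pid[i], f"missing_ffq_{tp}"))
        for i in np.flatnonzero(keep & ~missing & out_of_range):
            reasons.append((pid[i], f"energy_outside_limits_{tp}"))
        keep &= ~(missing | out_of_range)
    retained = participants.loc[keep].copy()
    log = pd.DataFrame(reasons, columns=["participant_id", "reason"])
    return retained, log
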