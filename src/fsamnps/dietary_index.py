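"""Individual-level FSAm-NPS dietary index.

The index is the energy-weighted mean of the FSAm-NPS scores of everything
a participant consumes::

    DI = sum_i FS_i * E_i / sum_i E_i

where ``FS_i`` is the food/beverage score and ``E_i`` the mean daily energy
intake from item *i*.  A higher index reflects lower overall nutritional
quality.  Zero-energy items (water, some drinks) are scored but carry no
weight by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["UndefinedIndexError", "compute_di", "compute_di_table",
           "assign_tertiles", "di_change"]


class UndefinedIndexError(ValueError):
    """Raised when the dietary index is requested with zero total energy."""


def compute_di(scores, energies) -> float:
    """Energy-weighted mean score of one participant's consumed items.

    Parameters
    ----------
    scores
        Food score ``FS_i`` per item (aligned with ``energies``).
    energies
        Daily energy ``E_i`` per item, kcal/day (any common energy unit —
        the index is invariant to unit rescaling).
    """
    fs = np.asarray(scores, dtype=float)
    e = np.asarray(energies, dtype=float)
    if fs.shape != e.shape:
        raise ValueError("scores and energies must align")
    if (e < 0).any():
        raise ValueError("item energies must be non-negative")
    total = e.sum()
    if total <= 0:
        raise UndefinedIndexError("total energy is zero; index undefined")
    return float(fs @ e / total)


def compute_di_table(item_energy: pd.DataFrame, scores: pd.Series,
                     ) -> pd.DataFrame:
    """Dietary index per participant-timepoint from long item energies.

    Parameters
    ----------
    item_energy
        Long table ``participant_id, timepoint, item_id, energy_kcal``
        (from ``ffq.intake_table``).
    scores
        Food score per item, indexed by ``item_id`` (``FoodScore.total``
        values; pass the reclassified totals for the olive-oil sensitivity
        analysis).

    Returns
    -------
    DataFrame ``participant_id, timepoint, di``.  Participants with zero
    total energy get ``di = NaN`` and are flagged in the ``undefined``
    column rather than dropped.
    """
    missing = set(item_energy["item_id"]) - set(scores.index)
    if missing:
        raise KeyError(f"no food score for items: {sorted(missing)[:5]}")
    fs = item_energy["item_id"].map(scores).to_numpy(dtype=float)
    e = item_energy["energy_kcal"].to_numpy(dtype=float)
    df = item_energy[["participant_id", "timepoint"]].copy()
    df["fse"] = fs * e
    df["e"] = e
    agg = df.groupby(["participant_id", "timepoint"], sort=False).sum(
        numeric_only=True).reset_index()
    undefined = agg["e"] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["di"] = np.where(undefined, np.nan, agg["fse"] / agg["e"])
    agg["undefined"] = undefined
    return agg[["participant_id", "timepoint", "di", "undefined"]]


def assign_tertiles(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based thirds of a cohort vector of dietary-index values.

    T1 holds the lowest third (best nutritional quality), T3 the highest.
    With distinct values group sizes differ by at most one (remainder items
    go to the lower tertiles, e.g. 5,921 values split 1,974/1,974/1,973).
    Tied values at a cut point all take the lower tertile label, with
    stable input order otherwise.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if np.isnan(v).any():
        raise ValueError("tertiles undefined with missing values")
    if n < 3:
        raise ValueError("need at least 3 values for tertiles")
    if np.all(v == v[0]):
        raise ValueError("all values identical; tertiles undefined")
    order = np.argsort(v, kind="stable")
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n), 3)]
    labels_sorted = np.repeat([1, 2, 3], sizes)
    # ties spanning a boundary share the lower label
    sv = v[order]
    for i in range(1, n):
        if sv[i] == sv[i - 1] and labels_sorted[i] != labels_sorted[i - 1]:
            labels_sorted[i] = labels_sorted[i - 1]
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def di_change(baseline: float | pd.Series, year1: float | pd.Series,
              orientation: str = "year1_minus_baseline"):
    """Signed 1-year change in the dietary index.

    The default orientation is ``year1 - baseline`` so a positive change
    means the score rose, i.e. nutritional quality worsened.  The opposite
    convention is available via ``orientation="baseline_minus_year1"``.
    Missing values propagate.
    """
    if orientation == "year1_minus_baseline":
        return year1 - baseline
    if orientation == "baseline_minus_year1":
        return baseline - year1
    raise ValueError(f"unknown orientation {orientation!r}")
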