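"""End-to-end assembly: composition + FFQ + measurements -> analysis table.

Chains the scoring engine, intake computation, exclusion screens, dietary
index, and outcome derivation into the single wide per-participant table the
regression grids consume.
"""

from __future__ import annotations

import pandas as pd

from . import ffq
from .bands import ScoringBands
from .dietary_index import assign_tertiles, compute_di_table, di_change
from .outcomes import derive_outcomes
from .profiling import reclassify_olive_oil, score_table

__all__ = ["build_analysis_table"]


def build_analysis_table(composition: pd.DataFrame,
                         responses: pd.DataFrame,
                         participants: pd.DataFrame,
                         measurements: pd.DataFrame,
                         bands: ScoringBands | None = None,
                         fmap: ffq.FrequencyMap = ffq.DEFAULT_FREQUENCY_MAP,
                         olive_oil_minus8: bool = False,
                         olive_oil_ids: list[str] | None = None,
                         ) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline and return the analysis-ready wide table.

    Parameters
    ----------
    composition
        Normalised composition table including ``portion_g``.
    responses
        Long FFQ table ``participant_id, timepoint, item_id,
        frequency_category`` at both timepoints.
    participants
        One row per participant with covariates (``sex, age, education,
        smoking, marital, pa_met_min_week, med_* , center_size, arm,
        cluster_id``).
    measurements
        Raw outcome fields per participant x timepoint (see
        ``outcomes.derive_outcomes``).
    olive_oil_minus8
        Apply the sensitivity reclassification (olive-oil items scored -8)
        before computing the dietary index.

    Returns
    -------
    table
        Wide per-participant DataFrame restricted to retained participants,
        with ``di_baseline, di_change`` (+ tertiles), outcome columns, and
        covariates.
    info
        Dict with the exclusion log, imputation log, and food scores used.
    """
    scores_df = score_table(composition, bands)
    if olive_oil_minus8:
        if olive_oil_ids is None:
            olive_oil_ids = [i for i in composition["item_id"]
                             if "olive_oil" in str(i)]
        totals = scores_df.set_index("item_id")["total"].copy()
        totals.loc[list(olive_oil_ids)] = -8
    else:
        totals = scores_df.set_index("item_id")["total"]

    intakes, item_energy = ffq.intake_table(responses, composition,
                                            composition, fmap)
    retained, exclusion_log = ffq.apply_exclusions(participants, intakes)
    keep = retained["participant_id"]

    di = compute_di_table(item_energy, totals)
    di_wide = di.pivot(index="participant_id", columns="timepoint",
                       values="di")
    out_wide, imputation_log = derive_outcomes(
        measurements[measurements["participant_id"].isin(keep)])

    table = retained.merge(out_wide, on="participant_id", validate="one_to_one")
    table["di_baseline"] = table["participant_id"].map(di_wide["baseline"])
    table["di_year1"] = table["participant_id"].map(di_wide["year1"])
    table["di_change"] = di_change(table["di_baseline"], table["di_year1"])
    energy_b = intakes[intakes["timepoint"] == "baseline"].set_index(
        "participant_id")["energy_kcal"]
    table["energy_kcal"] = table["participant_id"].map(energy_b)
    table["di_baseline_tertile"] = assign_tertiles(table["di_baseline"])
    table["di_change_tertile"] = assign_tertiles(table["di_change"])
    info = {"exclusion_log": exclusion_log, "imputation_log": imputation_log,
            "scores": scores_df}
    return table, info
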