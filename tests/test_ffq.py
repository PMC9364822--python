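"""FFQ intake arithmetic and cohort exclusion screens."""

import numpy as np
import pandas as pd
import pytest

from fsamnps import (DEFAULT_FREQUENCY_MAP, FrequencyMap, apply_exclusions,
                     daily_grams, intake_table, nutrient_intake)


@pytest.fixture
def basket():
    composition = pd.DataFrame({
        "item_id": ["bread", "milk", "apple"],
        "category": ["general", "beverage", "general"],
        "energy_kj": [1046.0, 272.0, 218.0],
        "sugars_g": [2.0, 4.8, 10.0],
        "satfat_g": [0.3, 1.1, 0.0],
        "sodium_mg": [450.0, 40.0, 1.0],
        "fiber_g": [3.5, 0.0, 2.4],
        "protein_g": [8.0, 3.3, 0.3],
        "fvln_pct": [0.0, 0.0, 100.0],
        "portion_g": [50.0, 200.0, 150.0],
    })
    responses = pd.DataFrame({
        "item_id": ["bread", "milk", "apple"],
        "frequency_category": [7, 6, 4],  # 2.5/day, 1/day, 3/7 per day
    })
    return composition, responses


@pytest.mark.parametrize("category,portion,expected", [
    (1, 123.0, 0.0),        # never
    (6, 30.0, 30.0),        # once a day
    (7, 200.0, 500.0),      # 2-3 a day -> 2.5 servings
    (2, 30.0, 2.0),         # 1-3 a month -> 2/30 servings
])
def test_daily_grams(category, portion, expected):
    assert daily_grams(category, portion) == pytest.approx(expected)


def test_frequency_map_validation():
    with pytest.raises(ValueError, match="9 entries"):
        FrequencyMap(servings_per_day=(0.0, 1.0))
    with pytest.raises(ValueError, match="monotone"):
        FrequencyMap(servings_per_day=(0, 1, 0.5, 1, 1, 1, 2, 5, 7))
    with pytest.raises(KeyError):
        DEFAULT_FREQUENCY_MAP(10)


class TestNutrientIntake:
    def test_unit_case(self):
        comp = pd.DataFrame({
            "item_id": ["x"], "category": ["general"], "energy_kj": [418.4],
            "sugars_g": [0.0], "satfat_g": [0.0], "sodium_mg": [0.0],
            "fiber_g": [0.0], "protein_g": [8.0], "fvln_pct": [0.0],
            "portion_g": [100.0],
        })
        resp = pd.DataFrame({"item_id": ["x"], "frequency_category": [6]})
        totals, item_e = nutrient_intake(resp, comp, comp)
        assert totals["protein_g"] == pytest.approx(8.0)
        assert totals["energy_kcal"] == pytest.approx(100.0)
        assert item_e.loc["x"] == pytest.approx(100.0)

    def test_matches_spreadsheet_oracle(self, basket):
        """Totals equal an independent item-by-item recomputation."""
        composition, responses = basket
        totals, item_e = nutrient_intake(responses, composition, composition)
        servings = {1: 0, 2: 2 / 30, 3: 1 / 7, 4: 3 / 7, 5: 5.5 / 7,
                    6: 1.0, 7: 2.5, 8: 5.0, 9: 7.0}
        expected = {k: 0.0 for k in totals}
        for _, r in responses.iterrows():
            row = composition.set_index("item_id").loc[r["item_id"]]
            g = servings[r["frequency_category"]] * row["portion_g"]
            expected["energy_kcal"] += g * row["energy_kj"] / 100 / 4.184
            for nut in ("sugars_g", "satfat_g", "sodium_mg", "fiber_g",
                        "protein_g"):
                expected[nut] += g * row[nut] / 100
        for k, v in expected.items():
            assert totals[k] == pytest.approx(v), k
        assert item_e.sum() == pytest.approx(totals["energy_kcal"])

    def test_additivity_and_linearity(self, basket):
        composition, responses = basket
        totals, _ = nutrient_intake(responses, composition, composition)
        t1, _ = nutrient_intake(responses.iloc[:1], composition, composition)
        t2, _ = nutrient_intake(responses.iloc[1:], composition, composition)
        for k in totals:
            assert totals[k] == pytest.approx(t1[k] + t2[k])
        doubled = FrequencyMap(servings_per_day=tuple(
            2 * v for v in DEFAULT_FREQUENCY_MAP.servings_per_day))
        t2x, _ = nutrient_intake(responses, composition, composition, doubled)
        for k in totals:
            assert t2x[k] == pytest.approx(2 * totals[k])

    def test_unresolvable_item_errors(self, basket):
        composition, responses = basket
        responses = pd.concat([responses, pd.DataFrame(
            {"item_id": ["ghost"], "frequency_category": [6]})])
        with pytest.raises(KeyError, match="ghost"):
            nutrient_intake(responses, composition, composition)

    def test_zero_responses_warns_with_zero_totals(self, basket):
        composition, _ = basket
        empty = pd.DataFrame(columns=["item_id", "frequency_category"])
        with pytest.warns(UserWarning, match="zero FFQ"):
            totals, _ = nutrient_intake(empty, composition, composition)
        assert all(v == 0 for v in totals.values())


class TestExclusions:
    @staticmethod
    def cohort(energies):
        """energies: {pid: (sex, baseline kcal, year1 kcal or None)}"""
        participants = pd.DataFrame(
            [{"participant_id": pid, "sex": sex}
             for pid, (sex, _, _) in energies.items()])
        rows = []
        for pid, (_, e_b, e_1) in energies.items():
            rows.append({"participant_id": pid, "timepoint": "baseline",
                         "energy_kcal": e_b})
            if e_1 is not None:
                rows.append({"participant_id": pid, "timepoint": "year1",
                             "energy_kcal": e_1})
        return participants, pd.DataFrame(rows)

    def test_limit_rules(self):
        participants, intakes = self.cohort({
            "w_low": ("female", 450, 2000),     # below 500 -> out
            "w_edge": ("female", 500, 2000),    # exactly at limit -> kept
            "m_high": ("male", 2000, 3900),     # within male 4000 -> kept
            "m_over": ("male", 2000, 4001),     # above -> out
            "no_y1": ("male", 2000, None),      # missing year-1 FFQ -> out
        })
        retained, log = apply_exclusions(participants, intakes)
        assert set(retained["participant_id"]) == {"w_edge", "m_high"}
        reasons = dict(zip(log["participant_id"], log["reason"]))
        assert reasons["w_low"] == "energy_outside_limits_baseline"
        assert reasons["m_over"] == "energy_outside_limits_year1"
        assert reasons["no_y1"] == "missing_ffq_year1"

    def test_idempotent_and_partition(self):
        participants, intakes = self.cohort({
            "a": ("female", 450, 2000), "b": ("male", 2500, 2500),
            "c": ("female", 2000, 3600),
        })
        retained, log = apply_exclusions(participants, intakes)
        assert set(retained["participant_id"]) | set(log["participant_id"]) \
            == set(participants["participant_id"])
        assert not set(retained["participant_id"]) & set(log["participant_id"])
        again, log2 = apply_exclusions(retained, intakes)
        pd.testing.assert_frame_equal(again, retained)
        assert log2.empty

    def test_unknown_sex_errors(self):
        participants, intakes = self.cohort({"a": ("unknown", 2000, 2000)})
        with pytest.raises(ValueError, match="unknown"):
            apply_exclusions(participants, intakes)


def test_intake_table_matches_per_participant_path(basket):
    composition, responses = basket
    long = pd.concat([
        responses.assign(participant_id="p1", timepoint="baseline"),
        responses.assign(participant_id="p2", timepoint="baseline",
                         frequency_category=[9, 1, 6]),
    ])
    totals, item_e = intake_table(long, composition, composition)
    for pid, freq in (("p1", responses),
                      ("p2", responses.assign(frequency_category=[9, 1, 6]))):
        expected, _ = nutrient_intake(freq, composition, composition)
        got = totals[totals["participant_id"] == pid].iloc[0]
        for k, v in expected.items():
            assert got[k] == pytest.approx(v), (pid, k)
    assert np.isclose(item_e["energy_kcal"].sum(),
                      totals["energy_kcal"].sum())
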