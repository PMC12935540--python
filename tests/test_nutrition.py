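"""Yield-to-nutrient conversion, forage scenarios and rotation aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rotanutri.diversity import UnknownCropError
from rotanutri.nutrition import (
    ForageScenario,
    build_output_table,
    crop_output,
    default_scenario,
    forage_output,
    rotation_output,
)


class TestCropOutput:
    def test_hand_arithmetic_oracle(self, toy_crop_catalog):
        # 1000/0.88 * 0.75 * 1.0 * 0.70
        m = crop_output(1000.0, toy_crop_catalog["wheat"], "carbohydrate")
        assert m == pytest.approx(1000.0 / 0.88 * 0.75 * 0.70, rel=1e-12)
        assert m == pytest.approx(596.6, abs=0.05)

    def test_zero_yield_zero_output(self, toy_crop_catalog):
        assert crop_output(0.0, toy_crop_catalog["pea"], "calorie") == 0.0

    def test_zero_gamma_zero_output(self, toy_crop_catalog):
        assert crop_output(5000.0, toy_crop_catalog["sugar_beet"], "fat") == 0.0

    def test_forage_only_crop_rejected(self, toy_crop_catalog):
        with pytest.raises(ValueError, match="forage-only"):
            crop_output(1000.0, toy_crop_catalog["ley"], "calorie")


class TestForageOutput:
    def test_milk_product_mass(self):
        milk = default_scenario("milk")
        assert milk.dm_to_product == pytest.approx(1.05)
        # 1 kg DM -> 1.05 l whole milk before nutrient conversion
        m = forage_output(1.0, milk, "protein")
        p = milk.product_profile
        assert m == pytest.approx(1.05 * p.f_ref * p.gamma["protein"])

    def test_beef_product_mass(self):
        beef = default_scenario("beef")
        assert beef.dm_to_product == pytest.approx(0.047)
        m = forage_output(1.0, beef, "fat")
        p = beef.product_profile
        assert m == pytest.approx(0.047 * p.f_ref * p.gamma["fat"])

    def test_biofuel_always_zero(self):
        biofuel = default_scenario("biofuel")
        for n in ("calorie", "carbohydrate", "protein", "fat"):
            assert forage_output(12345.0, biofuel, n) == 0.0

    def test_negative_dm_to_product_rejected(self):
        with pytest.raises(ValueError):
            ForageScenario(name="milk", dm_to_product=-1.0, product_profile=None)


class TestRotationOutput:
    def test_single_crop(self):
        assert rotation_output([42.0], [1.0]) == pytest.approx(42.0)

    def test_two_crop_mean(self):
        assert rotation_output([100.0, 300.0], [0.5, 0.5]) == pytest.approx(200.0)

    def test_linearity(self):
        m = [10.0, 20.0, 30.0]
        w = [1 / 3] * 3
        assert rotation_output([2 * x for x in m], w) == pytest.approx(
            2 * rotation_output(m, w)
        )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            rotation_output([1.0, 2.0], [0.5, 0.6])


def _toy_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "calendar_year",
            "time_since_start",
            "rotation_id",
            "fr_label",
            "rotation_length",
            "group",
            "crop",
            "use",
            "yield_dry",
        ],
    )


class TestBuildOutputTable:
    def _two_rotation_table(self):
        rows = []
        for year, t in [(2000, 0), (2001, 1)]:
            rows.append(("S", year, t, "mono", "1M", 1, "A1", "wheat", "food", 4000.0))
            rows.append(("S", year, t, "wp", "2", 2, "A1", "wheat", "food", 4200.0))
            rows.append(("S", year, t, "wp", "2", 2, "A1", "pea", "food", 2500.0))
        return _toy_table(rows)

    def test_combinatorial_row_count(self, toy_crop_catalog):
        out = build_output_table(
            self._two_rotation_table(), crop_catalog=toy_crop_catalog, scenario="milk"
        )
        # 1 site x 2 years x 2 rotations x 1 group x 4 nutrients
        assert len(out) == 16
        assert set(out["unit"]) == {"Gcal ha-1 yr-1", "kg ha-1 yr-1"}

    def test_aggregation_matches_hand_computation(self, toy_crop_catalog):
        out = build_output_table(
            self._two_rotation_table(), crop_catalog=toy_crop_catalog, scenario="milk"
        )
        got = out[
            (out["rotation_id"] == "wp")
            & (out["calendar_year"] == 2000)
            & (out["nutrient"] == "protein")
        ]["O"].iloc[0]
        m_wheat = crop_output(4200.0, toy_crop_catalog["wheat"], "protein")
        m_pea = crop_output(2500.0, toy_crop_catalog["pea"], "protein")
        assert got == pytest.approx((m_wheat + m_pea) / 2.0)

    def test_scenarios_differ_only_for_forage_rotations(self, toy_crop_catalog):
        rows = []
        for year, t in [(2000, 0), (2001, 1)]:
            rows.append(("S", year, t, "mono", "1M", 1, "A1", "wheat", "food", 4000.0))
            rows.append(("S", year, t, "wl", "3", 2, "A1", "wheat", "food", 4000.0))
            rows.append(("S", year, t, "wl", "3", 2, "A1", "ley", "forage", 6000.0))
        t = _toy_table(rows)
        milk = build_output_table(t, crop_catalog=toy_crop_catalog, scenario="milk")
        bio = build_output_table(t, crop_catalog=toy_crop_catalog, scenario="biofuel")
        key = ["rotation_id", "calendar_year", "nutrient"]
        merged = milk.merge(bio, on=key, suffixes=("_milk", "_bio"))
        mono = merged[merged["rotation_id"] == "mono"]
        assert np.allclose(mono["O_milk"], mono["O_bio"])
        ley_rows = merged[merged["rotation_id"] == "wl"]
        assert (ley_rows["O_milk"] > ley_rows["O_bio"]).any()

    def test_fallow_contributes_zero(self, toy_crop_catalog):
        rows = [
            ("S", 2000, 0, "wf", "1M", 2, "A1", "wheat", "food", 4000.0),
            ("S", 2000, 0, "wf", "1M", 2, "A1", "fallow", "none", 0.0),
        ]
        out = build_output_table(
            _toy_table(rows), crop_catalog=toy_crop_catalog, scenario="milk"
        )
        cal = out[out["nutrient"] == "calorie"]["O"].iloc[0]
        assert cal == pytest.approx(
            crop_output(4000.0, toy_crop_catalog["wheat"], "calorie") / 2.0
        )

    def test_missing_crop_year_raises(self, toy_crop_catalog):
        rows = [("S", 2000, 0, "wp", "2", 2, "A1", "wheat", "food", 4000.0)]
        with pytest.raises(ValueError, match="missing crop-years"):
            build_output_table(
                _toy_table(rows), crop_catalog=toy_crop_catalog, scenario="milk"
            )

    def test_unknown_crop_names_rotation(self, toy_crop_catalog):
        rows = [("S", 2000, 0, "m", "1M", 1, "A1", "quinoa", "food", 1000.0)]
        with pytest.raises(UnknownCropError, match="quinoa"):
            build_output_table(
                _toy_table(rows), crop_catalog=toy_crop_catalog, scenario="milk"
            )

    def test_crop_order_within_year_irrelevant(self, toy_crop_catalog):
        t = self._two_rotation_table()
        shuffled = t.sample(frac=1.0, random_state=0)
        a = build_output_table(t, crop_catalog=toy_crop_catalog, scenario="milk")
        b = build_output_table(shuffled, crop_catalog=toy_crop_catalog, scenario="milk")
        key = ["rotation_id", "calendar_year", "nutrient"]
        m = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert np.allclose(m["O_a"], m["O_b"])


@given(
    y=st.floats(min_value=0.0, max_value=20000.0),
    f=st.floats(min_value=0.0, max_value=0.95),
    a=st.floats(min_value=0.0, max_value=2.0),
    r=st.floats(min_value=0.0, max_value=1.0),
    g=st.floats(min_value=0.0, max_value=1.0),
)
def test_conversion_identity_property(y, f, a, r, g):
    """Engine output equals the independent arithmetic chain for random factors."""
    from rotanutri.diversity import CropProfile

    profile = CropProfile(
        crop_name="x",
        functional_type="cereal",
        edible=True,
        forage_only=False,
        f_H2O=f,
        alpha=a,
        f_ref=r,
        gamma={"calorie": g, "carbohydrate": g, "protein": g, "fat": g},
    )
    expected = y / (1.0 - f) * a * r * g  # hand-written chain
    assert crop_output(y, profile, "calorie") == pytest.approx(expected, rel=1e-12)
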