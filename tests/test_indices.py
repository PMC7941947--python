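"""Diet-index scoring: component rules, totals, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietcohort.indices import (
    CDQIScorer,
    PDQI_RULES,
    PDQIScorer,
    UPFIScorer,
    cdqi_diversity,
    cdqi_equilibrium,
    cdqi_quality,
    pdqi_component,
    pdqi_total,
    standardize,
    upfi,
)


@pytest.mark.parametrize(
    "rule,intake,expected",
    [
        ("fruits", 250.0, 10.0),          # at the recommendation
        ("fruits", 400.0, 10.0),          # capped above it
        ("fruits", 125.0, 5.0),           # linear ramp
        ("fruits", 0.0, 0.0),
        ("trans_fat", 0.0, 10.0),         # below the 1%-energy limit
        ("trans_fat", 0.01, 10.0),        # exactly at the limit
        ("trans_fat", 0.02, 0.0),         # twice the limit
        ("red_meat", 500.0 / 7.0, 10.0),
        ("red_meat", 1000.0 / 7.0, 0.0),
        ("salt", 2.4, 10.0),              # 6 g salt = 2.4 g sodium
        ("total_fish", 300.0 / 7.0, 5.0),
        ("total_fish", 500.0 / 7.0, 5.0),  # no penalty above the band
        ("dairy", 1.5, 5.0),              # servings ramp
        ("diversity", 4.0, 5.0),          # half the item ceiling
    ],
)
def test_component_scoring_curves(rule, intake, expected):
    assert pdqi_component(intake, PDQI_RULES[rule]) == pytest.approx(expected)


def test_component_rejects_negative_intake():
    with pytest.raises(ValueError):
        pdqi_component(-1.0, PDQI_RULES["fruits"])


def test_component_maxima_sum_to_110():
    assert sum(r.max_score for r in PDQI_RULES.values()) == 110.0


def test_guideline_intake_scores_110(guideline_intake, toy_maternal_metadata):
    scores = pdqi_total(guideline_intake.iloc[0], toy_maternal_metadata)
    assert scores["pdqi_total"] == pytest.approx(110.0)


def test_minimal_energy_intake_component_breakdown(toy_maternal_metadata):
    """No intake from any scored group: adequacy components 0, limit
    components maximal, so the total is exactly the 50 limit points."""
    row = {c: 0.0 for c in toy_maternal_metadata["item_id"]}
    row["water"] = 1000.0  # tiny positive energy, no nutrients
    scores = pdqi_total(pd.Series(row), toy_maternal_metadata)
    for comp in ("fruits", "vegetables", "whole_grain", "total_fish",
                 "fatty_fish", "dairy", "diversity"):
        assert scores[f"pdqi_{comp}"] == 0.0
    for comp in ("red_meat", "sat_fat", "trans_fat", "salt", "added_sugar"):
        assert scores[f"pdqi_{comp}"] == 10.0
    assert scores["pdqi_total"] == pytest.approx(50.0)


def test_zero_energy_errors(toy_maternal_metadata):
    empty = pd.DataFrame(
        [{c: 0.0 for c in toy_maternal_metadata["item_id"]}], index=["s0"]
    )
    with pytest.raises(ValueError, match="energy"):
        PDQIScorer(toy_maternal_metadata).fit(None).transform(empty)
    with pytest.raises(ValueError, match="energy"):
        UPFIScorer(toy_maternal_metadata).fit(None).transform(empty)


class TestUpfi:
    def test_no_ultraprocessed_intake_scores_zero(self, toy_maternal_metadata):
        row = pd.Series({c: 0.0 for c in toy_maternal_metadata["item_id"]})
        row["fruit_a"] = 300.0
        assert upfi(row, toy_maternal_metadata) == 0.0

    def test_all_energy_ultraprocessed_scores_100(self, toy_maternal_metadata):
        row = pd.Series({c: 0.0 for c in toy_maternal_metadata["item_id"]})
        row["candy"] = 100.0
        assert upfi(row, toy_maternal_metadata) == pytest.approx(100.0)

    def test_energy_share_hand_computation(self, toy_maternal_metadata):
        # candy: 3 MJ of NOVA-4 energy; fruit_a: 6 MJ of unprocessed energy
        row = pd.Series({c: 0.0 for c in toy_maternal_metadata["item_id"]})
        row["candy"] = 3000.0 / 17.0
        row["fruit_a"] = 6000.0 / 2.0
        assert upfi(row, toy_maternal_metadata) == pytest.approx(100 * 3 / 9, rel=1e-9)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, toy_maternal_metadata, guideline_intake):
        """UPFI is an energy ratio: uniform intake rescaling leaves it fixed."""
        mixed = guideline_intake.copy()
        mixed["candy"] = 30.0
        base = UPFIScorer(toy_maternal_metadata).fit(None).transform(mixed)["upfi"]
        scaled = UPFIScorer(toy_maternal_metadata).fit(None).transform(mixed * scale)["upfi"]
        assert scaled.iloc[0] == pytest.approx(base.iloc[0], rel=1e-9)


class TestCdqi:
    def _row(self, md, **grams):
        row = {c: 0.0 for c in md["item_id"]}
        row.update(grams)
        return pd.Series(row)

    def test_diversity_counts_groups_with_a_daily_serving(self, toy_child_metadata):
        all6 = self._row(toy_child_metadata, c_dairy=300, c_fruit=150, c_veg=150,
                         c_meat=40, c_fish=30, c_grain=90)
        assert cdqi_diversity(all6, toy_child_metadata) == 100.0
        three = self._row(toy_child_metadata, c_dairy=300, c_fruit=150, c_veg=150,
                          c_sweet=10.0)
        assert cdqi_diversity(three, toy_child_metadata) == pytest.approx(50.0)
        none = self._row(toy_child_metadata, c_sweet=10.0)
        assert cdqi_diversity(none, toy_child_metadata) == 0.0

    def test_quality_signed_gram_share(self, toy_child_metadata):
        only_preferred = self._row(toy_child_metadata, c_fruit=100.0)
        assert cdqi_quality(only_preferred, toy_child_metadata) == 100.0
        only_low = self._row(toy_child_metadata, c_sweet=50.0)
        assert cdqi_quality(only_low, toy_child_metadata) == -100.0
        mixed = self._row(toy_child_metadata, c_fruit=300.0, c_sweet=100.0, c_meat=100.0)
        assert cdqi_quality(mixed, toy_child_metadata) == pytest.approx(40.0)

    def test_equilibrium_adequacy_minus_moderation(self, toy_child_metadata):
        at_minimum = self._row(toy_child_metadata, c_dairy=300, c_fruit=150,
                               c_veg=150, c_meat=30, c_fish=20, c_grain=80)
        assert cdqi_equilibrium(at_minimum, toy_child_metadata) == pytest.approx(100.0)
        one_at_half = self._row(toy_child_metadata, c_dairy=300, c_fruit=150,
                                c_veg=150, c_meat=30, c_fish=10, c_grain=80)
        assert cdqi_equilibrium(one_at_half, toy_child_metadata) == pytest.approx(
            (5 * 100 + 50) / 6
        )

    def test_zero_intake_errors_on_quality(self, toy_child_metadata):
        empty = pd.DataFrame([{c: 0.0 for c in toy_child_metadata["item_id"]}])
        with pytest.raises(ValueError):
            CDQIScorer(toy_child_metadata).fit(None).transform(empty)

    def test_total_is_mean_of_components(self, toy_child_metadata, rng):
        grams = pd.DataFrame(
            rng.lognormal(3.0, 1.0, size=(40, len(toy_child_metadata))),
            columns=toy_child_metadata["item_id"],
        )
        out = CDQIScorer(toy_child_metadata).fit(None).transform(grams)
        expected = out[["cdqi_diversity", "cdqi_quality", "cdqi_equilibrium"]].mean(axis=1)
        np.testing.assert_allclose(out["cdqi_total"], expected, rtol=1e-12)

    def test_missing_recommendation_errors(self, toy_child_metadata):
        from dietcohort.indices import CdqiRecommendations

        rec = CdqiRecommendations(minimum={"dairy": 300.0}, upper={"dairy": 600.0})
        with pytest.raises(ValueError, match="recommendation"):
            CDQIScorer(toy_child_metadata, rec).fit(None)


@given(
    data=st.lists(
        st.lists(st.floats(min_value=0.0, max_value=2000.0), min_size=18, max_size=18),
        min_size=1,
        max_size=8,
    )
)
@settings(max_examples=40, deadline=None)
def test_pdqi_total_bounded_on_random_intakes(data, toy_maternal_metadata):
    """PDQI totals stay in [0, 110] for arbitrary non-negative intakes."""
    grams = pd.DataFrame(np.asarray(data) + 1e-6, columns=toy_maternal_metadata["item_id"])
    out = PDQIScorer(toy_maternal_metadata).fit(None).transform(grams)
    assert (out["pdqi_total"] >= 0).all()
    assert (out["pdqi_total"] <= 110 + 1e-9).all()


@pytest.mark.parametrize("item,component,direction", [
    ("fruit_a", "pdqi_fruits", 1),       # more fruit never lowers the fruit score
    ("veg_a", "pdqi_vegetables", 1),
    ("beef", "pdqi_red_meat", -1),       # more red meat never raises its score
])
def test_component_monotonicity(item, component, direction,
                                toy_maternal_metadata, guideline_intake):
    scorer = PDQIScorer(toy_maternal_metadata).fit(None)
    grid = [0.0, 10.0, 50.0, 120.0, 300.0, 800.0]
    rows = pd.concat([guideline_intake] * len(grid), ignore_index=True)
    rows[item] = grid
    vals = scorer.transform(rows)[component].to_numpy()
    diffs = np.diff(vals) * direction
    assert (diffs >= -1e-9).all()


def test_more_nova4_energy_never_lowers_upfi(toy_maternal_metadata, guideline_intake):
    scorer = UPFIScorer(toy_maternal_metadata).fit(None)
    grid = [0.0, 5.0, 20.0, 100.0, 500.0]
    rows = pd.concat([guideline_intake] * len(grid), ignore_index=True)
    rows["candy"] = grid
    vals = scorer.transform(rows)["upfi"].to_numpy()
    assert (np.diff(vals) >= -1e-9).all()


class TestStandardize:
    def test_simple_example(self):
        z, sd = standardize([1.0, 2.0, 3.0])
        assert sd == pytest.approx(1.0)
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self, rng):
        z, sd = standardize(rng.normal(83.1, 9.3, size=500))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_one_sd_shift_equals_raw_sd(self, rng):
        """A +1 move in z corresponds to exactly `sd` raw score points."""
        x = rng.normal(83.1, 9.3, size=2000)
        z, sd = standardize(x)
        raw_back = z * sd + x.mean()
        np.testing.assert_allclose(raw_back, x)
        assert (z + 1.0)[0] * sd + x.mean() - x[0] == pytest.approx(sd)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            standardize([5.0, 5.0, 5.0])
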