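import numpy as np
import pandas as pd
import pytest

from dietcohort import GeneratorConfig, generate_cohort


def _md_row(item_id, group, subtype="", nova=1, cdqi=0, ed=1.0,
            sat=0.0, trans=0.0, sugar=0.0, sodium=0.0):
    return {
        "item_id": item_id, "food_group": group, "subtype": subtype,
        "nova_group": nova, "cdqi_class": cdqi, "energy_density_kj_g": ed,
        "frac_energy_sat_fat": sat, "frac_energy_trans_fat": trans,
        "frac_energy_added_sugar": sugar, "sodium_mg_g": sodium,
    }


@pytest.fixture(scope="session")
def toy_maternal_metadata():
    """Hand-built maternal food list with known, simple properties.

    Nine items in the four diversity groups so a guideline-meeting
    intake can hit the diversity ceiling; limit-relevant nutrients are
    concentrated in dedicated items so energy fractions are easy to
    compute by hand.
    """
    rows = [
        _md_row("fruit_a", "fruits", cdqi=1, ed=2.0),
        _md_row("fruit_b", "fruits", cdqi=1, ed=2.0),
        _md_row("fruit_c", "fruits", cdqi=1, ed=2.0),
        _md_row("veg_a", "vegetables", cdqi=1, ed=1.5),
        _md_row("veg_b", "vegetables", cdqi=1, ed=1.5),
        _md_row("veg_c", "vegetables", cdqi=1, ed=1.5),
        _md_row("grain_whole_a", "grains", subtype="whole_grain", cdqi=1, ed=10.0),
        _md_row("grain_whole_b", "grains", subtype="whole_grain", cdqi=1, ed=10.0),
        _md_row("grain_refined", "grains", subtype="refined_grain", ed=10.0),
        _md_row("milk", "dairy", subtype="milk", cdqi=1, ed=2.0),
        _md_row("cheese", "dairy", subtype="cheese", ed=15.0, sat=0.5),
        _md_row("fish_fatty", "fish", subtype="fatty_fish", cdqi=1, ed=8.0),
        _md_row("fish_lean", "fish", subtype="lean_fish", cdqi=1, ed=4.0),
        _md_row("beef", "meat", subtype="red_meat", ed=8.0, sat=0.3),
        _md_row("soda", "beverages", nova=4, cdqi=-1, ed=1.8, sugar=1.0),
        _md_row("candy", "sweets-snacks", nova=4, cdqi=-1, ed=17.0,
                sat=0.2, trans=0.05, sugar=0.5, sodium=2.0),
        _md_row("salty_snack", "sweets-snacks", nova=4, cdqi=-1, ed=20.0, sodium=15.0),
        _md_row("water", "beverages", ed=0.001),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def guideline_intake(toy_maternal_metadata):
    """One subject meeting every recommendation exactly (PDQI = 110)."""
    zero = {c: 0.0 for c in toy_maternal_metadata["item_id"]}
    row = dict(
        zero,
        fruit_a=100.0, fruit_b=100.0, fruit_c=50.0,        # 250 g fruit
        veg_a=100.0, veg_b=100.0, veg_c=50.0,              # 250 g vegetables
        grain_whole_a=35.0, grain_whole_b=35.0,            # 70 g whole grain
        milk=600.0,                                        # 3 servings dairy
        fish_fatty=200.0 / 7.0, fish_lean=20.0,            # fish in band, fatty at min
    )
    return pd.DataFrame([row], index=["s0"])


@pytest.fixture(scope="session")
def toy_child_metadata():
    rows = [
        _md_row("c_dairy", "dairy", cdqi=1, ed=2.5),
        _md_row("c_fruit", "fruits", cdqi=1, ed=2.0),
        _md_row("c_veg", "vegetables", cdqi=1, ed=1.5),
        _md_row("c_meat", "meat", cdqi=0, ed=8.0),
        _md_row("c_fish", "fish", cdqi=1, ed=6.0),
        _md_row("c_grain", "grains", cdqi=1, ed=9.0),
        _md_row("c_sweet", "sweets-snacks", nova=4, cdqi=-1, ed=16.0),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort reused across model/ipw/validity tests."""
    return generate_cohort(GeneratorConfig(n_population=6000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
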