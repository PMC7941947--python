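"""Diet-quality index computation.

Three indices are computed from item-level intake tables (grams/day per
food item per subject) plus per-item metadata:

* **PDQI** — a 12-component adherence score to the Norwegian food-based
  dietary guidelines for pregnant women (range 0-110).  Adequacy
  components (fruit, vegetables, whole grain, fish, dairy, diversity)
  ramp linearly from 0 at zero intake to the component maximum at the
  recommended intake; moderation components (red meat, saturated/trans
  fat, salt, added sugar) hold the maximum at or below the limit and
  decline linearly to 0 at twice the limit.
* **UPFI** — percent of total energy intake contributed by NOVA group-4
  (ultra-processed) items, range 0-100.
* **CDQI** — child diet-quality index for pre-schoolers: the arithmetic
  mean of a diversity component (share of 6 main food groups with at
  least one daily serving), a quality component (signed gram-share of
  preferred vs low-nutrient-energy-dense foods) and an equilibrium
  component (adequacy minus moderation against per-group
  recommendations).

Scorers follow the sklearn transformer protocol: construct with the food
metadata, ``fit`` validates, ``transform`` maps an intake table
(subjects x items, grams/day) to a score table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ComponentRule",
    "PDQI_RULES",
    "PDQIScorer",
    "UPFIScorer",
    "CDQIScorer",
    "CdqiRecommendations",
    "pdqi_component",
    "pdqi_total",
    "dietary_diversity_score",
    "upfi",
    "cdqi_diversity",
    "cdqi_quality",
    "cdqi_equilibrium",
    "standardize",
    "score_indices",
]

MAIN_FOOD_GROUPS = ("dairy", "fruits", "vegetables", "meat", "fish", "grains")

#: grams per serving of each dairy subtype (1 serving = 20 g cheese,
#: 2 dl milk, 125 g yoghurt); "other" covers residual dairy items.
DAIRY_SERVING_G: dict[str, float] = {
    "cheese": 20.0,
    "milk": 200.0,
    "yoghurt": 125.0,
    "other": 150.0,
}

METADATA_COLUMNS = (
    "item_id",
    "food_group",
    "subtype",
    "nova_group",
    "cdqi_class",
    "energy_density_kj_g",
    "frac_energy_sat_fat",
    "frac_energy_trans_fat",
    "frac_energy_added_sugar",
    "sodium_mg_g",
)


@dataclass(frozen=True)
class ComponentRule:
    """Scoring rule for one PDQI component.

    ``kind="minimum"``: score = max_score * min(1, x / threshold).
    ``kind="maximum"``: max_score at x <= threshold, linear decline to 0
    at 2 * threshold.
    ``kind="band"``: adequacy ramp up to the lower band edge, full score
    from there on (no penalty above the upper edge).
    Thresholds are g/day for gram-based components, fractions of energy
    for energy-share components, g/day sodium for salt, servings/day for
    dairy and item counts for diversity.
    """

    name: str
    kind: str  # "minimum" | "maximum" | "band"
    threshold: float
    max_score: float
    upper: float | None = None


PDQI_RULES: dict[str, ComponentRule] = {
    "fruits": ComponentRule("fruits", "minimum", 250.0, 10.0),
    "vegetables": ComponentRule("vegetables", "minimum", 250.0, 10.0),
    "whole_grain": ComponentRule("whole_grain", "minimum", 70.0, 10.0),
    "total_fish": ComponentRule("total_fish", "band", 300.0 / 7.0, 5.0, upper=450.0 / 7.0),
    "fatty_fish": ComponentRule("fatty_fish", "band", 200.0 / 7.0, 5.0, upper=450.0 / 7.0),
    "red_meat": ComponentRule("red_meat", "maximum", 500.0 / 7.0, 10.0),
    "dairy": ComponentRule("dairy", "minimum", 3.0, 10.0),
    "sat_fat": ComponentRule("sat_fat", "maximum", 0.10, 10.0),
    "trans_fat": ComponentRule("trans_fat", "maximum", 0.01, 10.0),
    "salt": ComponentRule("salt", "maximum", 2.4, 10.0),  # g sodium/day (= 6 g salt)
    "added_sugar": ComponentRule("added_sugar", "maximum", 0.10, 10.0),
    "diversity": ComponentRule("diversity", "minimum", 8.0, 10.0),
}

PDQI_COMPONENT_ORDER = tuple(PDQI_RULES)


def pdqi_component(intake, rule: ComponentRule):
    """Score a single PDQI component value (vectorised over ``intake``)."""
    x = np.asarray(intake, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"negative intake passed to component {rule.name!r}")
    if rule.kind in ("minimum", "band"):
        score = rule.max_score * np.minimum(1.0, x / rule.threshold)
    elif rule.kind == "maximum":
        score = rule.max_score * np.clip(2.0 - x / rule.threshold, 0.0, 1.0)
    else:  # pragma: no cover - rules are module constants
        raise ValueError(f"unknown rule kind {rule.kind!r}")
    return score if score.ndim else float(score)


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = set(METADATA_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    md = metadata.set_index("item_id") if metadata.index.name != "item_id" else metadata
    if (md["energy_density_kj_g"] <= 0).any():
        raise ValueError("energy density must be positive for every item")
    if not md["nova_group"].isin([1, 2, 3, 4]).all():
        raise ValueError("NOVA group must be in 1-4")
    if not md["cdqi_class"].isin([-1, 0, 1]).all():
        raise ValueError("CDQI class must be -1, 0 or +1")
    return md


def _align(intake: pd.DataFrame, md: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    items = [c for c in intake.columns if c in md.index]
    if not items:
        raise ValueError("no intake columns match metadata item ids")
    grams = intake[items].to_numpy(dtype=float)
    if np.any(grams < 0):
        raise ValueError("intakes must be non-negative")
    return grams, md.loc[items]


def _energy_kj(grams: np.ndarray, md: pd.DataFrame) -> np.ndarray:
    return grams @ md["energy_density_kj_g"].to_numpy()


class PDQIScorer(TransformerMixin, BaseEstimator):
    """Prenatal diet-quality index scorer (transformer).

    Parameters
    ----------
    metadata : DataFrame
        Per-item metadata (see :data:`METADATA_COLUMNS`).
    diversity_ceiling : int
        Number of distinct daily-eaten items (within grains, vegetables,
        fruits and dairy) at which the diversity component saturates.
    diversity_threshold_g : float
        Minimum grams/day for an item to count as "eaten daily".
    dairy_serving_g : mapping
        Grams per serving for each dairy subtype.
    """

    def __init__(
        self,
        metadata: pd.DataFrame | None = None,
        diversity_ceiling: int = 8,
        diversity_threshold_g: float = 20.0,
        dairy_serving_g: Mapping[str, float] | None = None,
    ):
        self.metadata = metadata
        self.diversity_ceiling = diversity_ceiling
        self.diversity_threshold_g = diversity_threshold_g
        self.dairy_serving_g = dairy_serving_g

    def fit(self, X: pd.DataFrame, y=None):
        if self.metadata is None:
            raise ValueError("PDQIScorer requires item metadata")
        self.metadata_ = _validate_metadata(self.metadata)
        self.serving_map_ = dict(DAIRY_SERVING_G)
        if self.dairy_serving_g:
            self.serving_map_.update(self.dairy_serving_g)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "metadata_"):
            self.fit(X)
        grams, md = _align(X, self.metadata_)
        group = md["food_group"].to_numpy()
        subtype = md["subtype"].astype(str).to_numpy()

        energy = _energy_kj(grams, md)  # kJ/day
        if np.any(energy <= 0):
            raise ValueError("total energy must be positive for every subject")

        def gsum(mask):
            return grams[:, mask].sum(axis=1)

        comps: dict[str, np.ndarray] = {}
        comps["fruits"] = pdqi_component(gsum(group == "fruits"), PDQI_RULES["fruits"])
        comps["vegetables"] = pdqi_component(
            gsum(group == "vegetables"), PDQI_RULES["vegetables"]
        )
        comps["whole_grain"] = pdqi_component(
            gsum(subtype == "whole_grain"), PDQI_RULES["whole_grain"]
        )
        comps["total_fish"] = pdqi_component(gsum(group == "fish"), PDQI_RULES["total_fish"])
        comps["fatty_fish"] = pdqi_component(
            gsum(subtype == "fatty_fish"), PDQI_RULES["fatty_fish"]
        )
        comps["red_meat"] = pdqi_component(gsum(subtype == "red_meat"), PDQI_RULES["red_meat"])

        servings = np.zeros(len(grams))
        dairy_mask = group == "dairy"
        for j in np.flatnonzero(dairy_mask):
            per_serving = self.serving_map_.get(subtype[j], self.serving_map_["other"])
            servings += grams[:, j] / per_serving
        comps["dairy"] = pdqi_component(servings, PDQI_RULES["dairy"])

        ed = md["energy_density_kj_g"].to_numpy()
        for comp, col in (
            ("sat_fat", "frac_energy_sat_fat"),
            ("trans_fat", "frac_energy_trans_fat"),
            ("added_sugar", "frac_energy_added_sugar"),
        ):
            frac = (grams * ed * md[col].to_numpy()).sum(axis=1) / energy
            comps[comp] = pdqi_component(frac, PDQI_RULES[comp])

        sodium_g = grams @ md["sodium_mg_g"].to_numpy() / 1000.0
        comps["salt"] = pdqi_component(sodium_g, PDQI_RULES["salt"])

        div_mask = np.isin(group, ("grains", "vegetables", "fruits", "dairy"))
        n_items = (grams[:, div_mask] >= self.diversity_threshold_g).sum(axis=1)
        comps["diversity"] = pdqi_component(
            n_items.astype(float) / 1.0, PDQI_RULES["diversity"]
        )

        out = pd.DataFrame(
            {f"pdqi_{k}": comps[k] for k in PDQI_COMPONENT_ORDER}, index=X.index
        )
        out.insert(0, "pdqi_total", out.sum(axis=1))
        return out


class UPFIScorer(TransformerMixin, BaseEstimator):
    """Ultra-processed food index: percent of energy from NOVA group 4."""

    def __init__(self, metadata: pd.DataFrame | None = None):
        self.metadata = metadata

    def fit(self, X: pd.DataFrame, y=None):
        if self.metadata is None:
            raise ValueError("UPFIScorer requires item metadata")
        self.metadata_ = _validate_metadata(self.metadata)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "metadata_"):
            self.fit(X)
        grams, md = _align(X, self.metadata_)
        total = _energy_kj(grams, md)
        if np.any(total <= 0):
            raise ValueError("total energy must be positive for every subject")
        nova4 = (md["nova_group"] == 4).to_numpy()
        ed = md["energy_density_kj_g"].to_numpy()
        upf_energy = (grams[:, nova4] * ed[nova4]).sum(axis=1)
        return pd.DataFrame({"upfi": 100.0 * upf_energy / total}, index=X.index)


@dataclass(frozen=True)
class CdqiRecommendations:
    """Per-food-group recommendations for 3-year-olds.

    ``minimum``/``upper`` are g/day bounds used by the equilibrium
    component; ``serving_g`` is one daily serving for the diversity
    component.  Defaults are guideline-scale values for pre-schoolers.
    """

    minimum: Mapping[str, float] = field(
        default_factory=lambda: {
            "dairy": 300.0, "fruits": 150.0, "vegetables": 150.0,
            "meat": 30.0, "fish": 20.0, "grains": 80.0,
        }
    )
    upper: Mapping[str, float] = field(
        default_factory=lambda: {
            "dairy": 600.0, "fruits": 400.0, "vegetables": 400.0,
            "meat": 90.0, "fish": 80.0, "grains": 300.0,
        }
    )
    serving_g: Mapping[str, float] = field(
        default_factory=lambda: {
            "dairy": 150.0, "fruits": 75.0, "vegetables": 75.0,
            "meat": 30.0, "fish": 30.0, "grains": 40.0,
        }
    )


class CDQIScorer(TransformerMixin, BaseEstimator):
    """Child diet-quality index: mean of diversity, quality, equilibrium."""

    def __init__(
        self,
        metadata: pd.DataFrame | None = None,
        recommendations: CdqiRecommendations | None = None,
    ):
        self.metadata = metadata
        self.recommendations = recommendations

    def fit(self, X: pd.DataFrame, y=None):
        if self.metadata is None:
            raise ValueError("CDQIScorer requires item metadata")
        self.metadata_ = _validate_metadata(self.metadata)
        self.recommendations_ = self.recommendations or CdqiRecommendations()
        present = set(self.metadata_["food_group"]) & set(MAIN_FOOD_GROUPS)
        rec = self.recommendations_
        missing = [g for g in present if g not in rec.minimum or g not in rec.upper]
        if missing:
            raise ValueError(f"missing recommendation for food groups: {missing}")
        return self

    def _group_grams(self, grams, md):
        group = md["food_group"].to_numpy()
        return {
            g: grams[:, group == g].sum(axis=1)
            for g in MAIN_FOOD_GROUPS
        }

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "metadata_"):
            self.fit(X)
        grams, md = _align(X, self.metadata_)
        rec = self.recommendations_
        by_group = self._group_grams(grams, md)

        # diversity: share of the 6 main groups with >= 1 daily serving
        served = np.zeros(len(grams))
        for g, tot in by_group.items():
            served += (tot >= rec.serving_g[g]).astype(float)
        diversity = 100.0 * served / len(MAIN_FOOD_GROUPS)

        # quality: signed gram share of preferred (+1) vs low-nutrient (-1)
        total_g = grams.sum(axis=1)
        if np.any(total_g <= 0):
            raise ValueError("total food intake must be positive for every subject")
        factor = md["cdqi_class"].to_numpy(dtype=float)
        quality = 100.0 * (grams @ factor) / total_g

        # equilibrium: mean over groups of adequacy minus moderation
        eq = np.zeros(len(grams))
        for g, tot in by_group.items():
            adequacy = 100.0 * np.minimum(1.0, tot / rec.minimum[g])
            with np.errstate(divide="ignore", invalid="ignore"):
                moderation = np.where(
                    tot > 0, 100.0 * np.maximum(0.0, tot - rec.upper[g]) / np.maximum(tot, 1e-12), 0.0
                )
            eq += adequacy - moderation
        equilibrium = np.clip(eq / len(MAIN_FOOD_GROUPS), 0.0, 100.0)

        out = pd.DataFrame(
            {
                "cdqi_diversity": diversity,
                "cdqi_quality": quality,
                "cdqi_equilibrium": equilibrium,
            },
            index=X.index,
        )
        out.insert(0, "cdqi_total", out.mean(axis=1))
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers


def _one_row(intake_row, metadata) -> pd.DataFrame:
    if isinstance(intake_row, pd.Series):
        return intake_row.to_frame().T
    return intake_row


def pdqi_total(intake_row, metadata: pd.DataFrame, **kwargs) -> pd.Series:
    """PDQI component scores and total for one subject."""
    df = PDQIScorer(metadata, **kwargs).fit(None).transform(_one_row(intake_row, metadata))
    return df.iloc[0]


def dietary_diversity_score(intake_row, metadata: pd.DataFrame, **kwargs) -> float:
    return float(pdqi_total(intake_row, metadata, **kwargs)["pdqi_diversity"])


def upfi(intake_row, metadata: pd.DataFrame) -> float:
    return float(UPFIScorer(metadata).fit(None).transform(_one_row(intake_row, metadata))["upfi"].iloc[0])


def _cdqi_row(intake_row, metadata, recommendations=None) -> pd.Series:
    scorer = CDQIScorer(metadata, recommendations)
    return scorer.fit(None).transform(_one_row(intake_row, metadata)).iloc[0]


def cdqi_diversity(intake_row, metadata, recommendations=None) -> float:
    return float(_cdqi_row(intake_row, metadata, recommendations)["cdqi_diversity"])


def cdqi_quality(intake_row, metadata, recommendations=None) -> float:
    return float(_cdqi_row(intake_row, metadata, recommendations)["cdqi_quality"])


def cdqi_equilibrium(intake_row, metadata, recommendations=None) -> float:
    return float(_cdqi_row(intake_row, metadata, recommendations)["cdqi_equilibrium"])


def standardize(scores) -> tuple[np.ndarray, float]:
    """Standardise a score vector; returns ``(z, sd)``.

    The SD is the sample (ddof=1) standard deviation of the analysis
    sample, so a one-unit change in ``z`` is a 1-SD change on the raw
    scale.  Raises on (near-)constant input.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two observations to standardize")
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd, sd


def score_indices(
    intake_maternal: pd.DataFrame | None,
    intake_child: pd.DataFrame | None,
    metadata_maternal: pd.DataFrame | None = None,
    metadata_child: pd.DataFrame | None = None,
    which: Sequence[str] = ("pdqi", "upfi", "cdqi"),
) -> pd.DataFrame:
    """Score any subset of the three indices; returns one table per subject."""
    parts = []
    if "pdqi" in which:
        parts.append(PDQIScorer(metadata_maternal).fit(None).transform(intake_maternal))
    if "upfi" in which:
        parts.append(UPFIScorer(metadata_maternal).fit(None).transform(intake_maternal))
    if "cdqi" in which:
        parts.append(CDQIScorer(metadata_child).fit(None).transform(intake_child))
    if not parts:
        raise ValueError("no index selected")
    return pd.concat(parts, axis=1)
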