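"""Inverse probability of participation weighting.

Cohort participation and attrition are typically not random but depend
on maternal education, age and parity.  Weights here are built from
simple participation probabilities: the number of mothers in a
population subgroup (education level x maternal age band x parity) that
appear in the study sample, divided by the number of mothers in the same
subgroup in the target population.  Each sampled subject is weighted by
the reciprocal of their subgroup's probability; weights are then
renormalized to mean 1 over the analysis sample so weighted likelihoods
keep an interpretable effective sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AGE_BAND_EDGES",
    "age_band",
    "participation_probabilities",
    "weights",
    "InverseProbabilityWeighter",
]

SUBGROUP_KEYS = ["education", "age_band", "parity"]

#: default 5-year maternal age bands: <=19, 20-24, ..., 35-39, >=40
AGE_BAND_EDGES = (20, 25, 30, 35, 40)


def age_band(age, edges=AGE_BAND_EDGES) -> np.ndarray:
    """Map continuous maternal age to ordinal band indices 0..len(edges)."""
    return np.digitize(np.asarray(age, dtype=float), bins=edges)


def participation_probabilities(margins: pd.DataFrame) -> pd.Series:
    """Per-subgroup participation probability p_g = sample_g / population_g.

    ``margins`` must have the subgroup key columns plus ``sample_count``
    and ``population_count``.
    """
    required = set(SUBGROUP_KEYS + ["sample_count", "population_count"])
    missing = required - set(margins.columns)
    if missing:
        raise ValueError(f"margins missing columns: {sorted(missing)}")
    m = margins.set_index(SUBGROUP_KEYS)
    if (m["sample_count"] < 0).any() or (m["population_count"] < 0).any():
        raise ValueError("subgroup counts must be non-negative")
    in_sample = m["sample_count"] > 0
    if (m.loc[in_sample, "population_count"] <= 0).any():
        raise ValueError("subgroup present in sample but absent from population")
    if (m["sample_count"] > m["population_count"]).any():
        raise ValueError("sample count exceeds population count in a subgroup")
    p = m["sample_count"] / m["population_count"].where(m["population_count"] > 0, np.nan)
    p.name = "participation_probability"
    return p


def weights(probabilities: pd.Series, subjects: pd.DataFrame, normalize: bool = True) -> pd.Series:
    """Per-subject weight w_i = 1 / p_{g(i)}, optionally renormalized to mean 1.

    ``subjects`` must carry the subgroup key columns.
    """
    keys = pd.MultiIndex.from_frame(subjects[SUBGROUP_KEYS])
    unknown = ~keys.isin(probabilities.index)
    if unknown.any():
        bad = subjects.loc[unknown, SUBGROUP_KEYS].drop_duplicates().to_records(index=False)
        raise ValueError(f"subjects in subgroups with no participation probability: {list(bad)[:5]}")
    p = probabilities.reindex(keys).to_numpy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("participation probability must be positive for every subject")
    w = 1.0 / p
    if normalize:
        w = w / w.mean()
    return pd.Series(w, index=subjects.index, name="weight")


class InverseProbabilityWeighter(TransformerMixin, BaseEstimator):
    """Transformer adding a participation ``weight`` column to a cohort table.

    Parameters
    ----------
    population_margins : DataFrame
        Subgroup rows with ``population_count`` (and optionally
        ``sample_count``, ignored: sample counts are recomputed from the
        cohort passed to ``fit`` so the weights always reflect the
        analysis sample actually used).
    normalize : bool
        Renormalize weights to mean 1 over the sample.
    """

    def __init__(self, population_margins: pd.DataFrame | None = None, normalize: bool = True):
        self.population_margins = population_margins
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        if self.population_margins is None:
            raise ValueError("population margins are required")
        sample = (
            X.groupby(SUBGROUP_KEYS, observed=True).size().rename("sample_count").reset_index()
        )
        pop = self.population_margins[SUBGROUP_KEYS + ["population_count"]]
        margins = pop.merge(sample, on=SUBGROUP_KEYS, how="outer")
        margins["sample_count"] = margins["sample_count"].fillna(0)
        if margins["population_count"].isna().any():
            raise ValueError("sample subgroup missing from population margins")
        self.margins_ = margins
        self.probabilities_ = participation_probabilities(margins)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["weight"] = weights(self.probabilities_, X, normalize=self.normalize)
        return out
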