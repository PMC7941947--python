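"""Construct validity and reliability metrics for diet-quality indices.

* :func:`hedges_g` — known-groups validity as a standardized mean
  difference (mean difference over pooled SD, no small-sample
  correction).
* :func:`omega_total` — internal-consistency reliability from a common
  factor model: principal-axis extraction, promax (oblique) rotation,
  then a Schmid-Leiman transformation to separate a general factor from
  group factors.  With the general loadings g and group loadings f,

      omega_t = [ (sum g)^2 + sum_f (sum lambda_f)^2 ] / V_t

  where V_t is the total variance (the sum of the observed correlation
  matrix for standardized items).
* :func:`index_correlations` — Pearson correlations among index scores
  and energy-adjusted nutrient intakes (nutrient per MJ).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hedges_g",
    "principal_axis",
    "promax",
    "schmid_leiman",
    "omega_total",
    "index_correlations",
    "KnownGroupsResult",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class KnownGroupsResult:
    labels: tuple[str, str]
    means: tuple[float, float]
    pooled_sd: float
    g: float


def hedges_g(x, y, labels: tuple[str, str] = ("group1", "group2")) -> KnownGroupsResult:
    """Standardized mean difference (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("pooled variance is zero")
    pooled = float(np.sqrt(s2))
    return KnownGroupsResult(
        labels=labels,
        means=(float(x.mean()), float(y.mean())),
        pooled_sd=pooled,
        g=float((x.mean() - y.mean()) / pooled),
    )


def principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 200, tol: float = 1e-7) -> np.ndarray:
    """Iterated principal-axis factor loadings of a correlation matrix."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R)) if p > n_factors else np.full(p, 0.5)
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        vals, vecs = np.linalg.eigh(Rh)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
        h2_new = np.clip((lam**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    Rh = R.copy()
    np.fill_diagonal(Rh, h2)
    vals, vecs = np.linalg.eigh(Rh)
    order = np.argsort(vals)[::-1][:n_factors]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    # orient each factor so its loading sum is positive
    sign = np.sign(lam.sum(axis=0))
    sign[sign == 0] = 1.0
    return lam * sign


def _varimax(L: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    p, k = L.shape
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        T = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ T


def promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation; returns (pattern, factor correlation Phi)."""
    V = _varimax(np.asarray(L, dtype=float))
    P = V * np.abs(V) ** (power - 1)
    U = np.linalg.lstsq(V, P, rcond=None)[0]
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    Phi = np.linalg.inv(U.T @ U)
    return pattern, Phi


def schmid_leiman(pattern: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """General and group loadings from an oblique solution.

    The factor correlation matrix is itself factored with one general
    factor (loadings gamma); then the general loadings are
    ``pattern @ gamma`` and the residualized group loadings
    ``pattern * sqrt(1 - gamma^2)`` column-wise.
    """
    Phi = np.asarray(Phi, dtype=float)
    k = Phi.shape[0]
    if k == 1:
        gamma = np.ones(1)
    elif k == 2:
        r = np.clip(Phi[0, 1], 0.0, 1.0)
        gamma = np.full(2, np.sqrt(r))
    else:
        gamma = principal_axis(Phi, 1).ravel()
    gamma = np.clip(np.abs(gamma), 0.0, 1.0)
    general = np.asarray(pattern) @ gamma
    group = np.asarray(pattern) * np.sqrt(1.0 - gamma**2)
    return general, group


def _default_n_factors(p: int) -> int:
    if p >= 9:
        return 3
    if p >= 6:
        return 2
    return 1


def omega_total(X, n_factors: int | None = None) -> float:
    """Omega total reliability of a component/item matrix.

    ``X`` is either a subjects-by-components data matrix (DataFrame or
    2-D array) or a correlation matrix (square, unit diagonal).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[0] == X.shape[1] and np.allclose(np.diag(X), 1.0) and np.all(np.abs(X) <= 1 + 1e-9):
        R = X.copy()
    else:
        if X.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        R = np.corrcoef(X, rowvar=False)
    p = R.shape[0]
    if p < 3:
        raise ValueError("omega needs at least 3 components")
    if np.linalg.eigvalsh(R).min() <= 1e-10:
        raise ValueError("correlation matrix is not positive definite")
    k = n_factors if n_factors is not None else _default_n_factors(p)
    k = min(k, p // 3) or 1
    if k == 1:
        lam = principal_axis(R, 1).ravel()
        general, group = lam, np.zeros((p, 1))
    else:
        pattern, Phi = promax(principal_axis(R, k))
        general, group = schmid_leiman(pattern, Phi)
    total_var = float(R.sum())
    omega = (general.sum() ** 2 + float((group.sum(axis=0) ** 2).sum())) / total_var
    return float(np.clip(omega, 0.0, 1.0))


def index_correlations(
    scores: pd.DataFrame,
    nutrients: pd.DataFrame | None = None,
    energy_mj: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation matrix among index scores and nutrients.

    Nutrient columns are energy-adjusted (divided by total energy in
    MJ/day) before correlating when ``energy_mj`` is given.  Pairwise
    complete observations are used; fewer than 3 pairs raises.
    """
    cols = scores.copy()
    if nutrients is not None:
        nut = nutrients.copy()
        if energy_mj is not None:
            nut = nut.div(energy_mj, axis=0)
            nut.columns = [f"{c}_per_mj" for c in nut.columns]
        cols = pd.concat([cols, nut], axis=1)
    n_pairs = cols.notna().astype(int).T @ cols.notna().astype(int)
    if (n_pairs.to_numpy() < 3).any():
        raise ValueError("need at least 3 paired complete observations")
    return cols.corr(method="pearson")
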