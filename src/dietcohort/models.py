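"""Weighted outcome models and marginal effect estimation.

The symptom outcome is an 18-item parent-rated sum score (each item
0-3, so a bounded count in [0, 54]) modelled with a beta-binomial
likelihood: logit-linear mean, a scalar precision ``phi`` shared across
subjects, and normal(0, 2) priors on the slope coefficients.  The
diagnosis outcome (0/1 registry diagnosis) is modelled with weighted
logistic regression under the same prior.  Both are fitted by maximum a
posteriori / penalized likelihood; uncertainty is propagated through a
Laplace (normal) approximation of the posterior, from which effect
estimates draw.

Effect summaries follow the marginal-standardization convention:

* absolute AME  = mean_i [ 54*mu(x_i + delta) - 54*mu(x_i) ]
* relative AME  = 100 * absolute AME / mean predicted score
* marginal RR   = mean_i p(x_i + delta) / mean_i p(x_i)

with ``delta`` a one-standard-deviation shift of the exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "EffectEstimate",
    "loglik_betabinomial",
    "BetaBinomialRegression",
    "BayesLogisticRegression",
    "ame",
    "marginal_rr",
    "prevalence_curve",
    "stratified_fit",
]

N_TRIALS = 54  # 18 symptom items scored 0-3


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate with a 95% interval and a scale tag."""

    estimate: float
    lower: float
    upper: float
    scale: str  # "absolute_ame" | "relative_ame_pct" | "rr" | "sd_ame"

    def __post_init__(self):
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("interval must bracket the point estimate")

    def overlaps(self, other: "EffectEstimate") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "scale": self.scale,
        }


def loglik_betabinomial(y, n, mu, phi):
    """Beta-binomial log density, mean-precision parameterization.

    Shapes are ``a = mu*phi`` and ``b = (1-mu)*phi``; the density is
    ``C(n, y) * B(y+a, n-y+b) / B(a, b)``.  Vectorised over all
    arguments.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("y must lie in [0, n]")
    if np.any((mu <= 0) | (mu >= 1)) or np.any(phi <= 0):
        raise ValueError("mu must be in (0,1) and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(n + 1)
        - special.gammaln(y + 1)
        - special.gammaln(n - y + 1)
        + special.betaln(y + a, n - y + b)
        - special.betaln(a, b)
    )


def _expit(x):
    return special.expit(x)


class _MapModel(BaseEstimator):
    """Shared MAP machinery: weighted penalized likelihood, Laplace cov.

    Parameters are the intercept, slope coefficients and (subclass
    specific) extra parameters; normal(0, prior_sd) penalty on slopes
    only, matching the convention of leaving the intercept unpenalized.
    """

    def __init__(self, prior_sd: float = 2.0, max_iter: int = 500, tol: float = 1e-8):
        self.prior_sd = prior_sd
        self.max_iter = max_iter
        self.tol = tol

    _n_extra = 0

    def _neg_logpost(self, params, X, y, w):
        raise NotImplementedError

    def _neg_grad(self, params, X, y, w):
        raise NotImplementedError

    def _prepare(self, X, y, sample_weight):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per outcome")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite (complete cases only)")
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w <= 0) or len(w) != len(y):
            raise ValueError("weights must be positive, one per subject")
        # mean-1 normalization keeps the effective sample size at n, so a
        # constant weight vector reproduces the unweighted fit exactly
        return X, y, w / w.mean()

    def _penalty(self, beta):
        # slopes only (beta excludes intercept here)
        return 0.5 * np.sum(beta**2) / self.prior_sd**2

    def _fit_map(self, X, y, w, x0):
        res = optimize.minimize(
            self._neg_logpost,
            x0,
            args=(X, y, w),
            jac=self._neg_grad,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-7},
        )
        if not res.success and res.status != 1:
            raise RuntimeError(f"optimizer failed to converge: {res.message}")
        self.params_ = res.x
        self.optimize_result_ = res
        self.cov_params_ = self._laplace_cov(res.x, X, y, w)
        self.n_obs_ = len(y)
        return self

    def _laplace_cov(self, params, X, y, w):
        # Hessian of the negative log posterior by central differences of
        # the analytic gradient; cheap at p ~ 20.
        p = len(params)
        H = np.empty((p, p))
        h = 1e-5 * np.maximum(1.0, np.abs(params))
        for j in range(p):
            up = params.copy()
            dn = params.copy()
            up[j] += h[j]
            dn[j] -= h[j]
            H[:, j] = (self._neg_grad(up, X, y, w) - self._neg_grad(dn, X, y, w)) / (2 * h[j])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RuntimeError("singular Hessian at the MAP estimate") from err
        return cov

    def posterior_draws(self, n_draws: int = 1000, rng=None) -> np.ndarray:
        """Draws from the Laplace approximation N(MAP, cov)."""
        rng = np.random.default_rng(rng)
        return rng.multivariate_normal(self.params_, self.cov_params_, size=n_draws)

    def get_feature_index(self, name: str) -> int:
        try:
            return self.feature_names_in_.index(name)
        except ValueError as err:
            raise KeyError(f"exposure {name!r} not in model features") from err


class BetaBinomialRegression(_MapModel):
    """Weighted beta-binomial regression for bounded sum scores.

    ``y`` is an integer score in ``[0, n_trials]``; the mean is
    logit-linear in the features, the precision ``phi`` is a single
    scalar estimated on the log scale.  Fitted attributes:
    ``intercept_``, ``coef_``, ``dispersion_`` (phi), ``params_``,
    ``cov_params_``.
    """

    _n_extra = 1  # log phi

    def __init__(self, n_trials: int = N_TRIALS, prior_sd: float = 2.0,
                 max_iter: int = 500, tol: float = 1e-8):
        super().__init__(prior_sd=prior_sd, max_iter=max_iter, tol=tol)
        self.n_trials = n_trials

    def _unpack(self, params):
        return params[0], params[1:-1], params[-1]

    def _neg_logpost(self, params, X, y, w):
        b0, beta, logphi = self._unpack(params)
        phi = np.exp(logphi)
        mu = np.clip(_expit(b0 + X @ beta), 1e-10, 1 - 1e-10)
        ll = loglik_betabinomial(y, self.n_trials, mu, phi)
        return -(w @ ll) + self._penalty(beta)

    def _neg_grad(self, params, X, y, w):
        b0, beta, logphi = self._unpack(params)
        phi = np.exp(logphi)
        eta = b0 + X @ beta
        mu = np.clip(_expit(eta), 1e-10, 1 - 1e-10)
        n = self.n_trials
        a = mu * phi
        b = (1 - mu) * phi
        dll_da = special.digamma(y + a) - special.digamma(n + phi) - special.digamma(a) + special.digamma(phi)
        dll_db = special.digamma(n - y + b) - special.digamma(n + phi) - special.digamma(b) + special.digamma(phi)
        dmu = mu * (1 - mu)
        # d ll / d eta = phi * dmu * (dll_da - dll_db)
        g_eta = w * phi * dmu * (dll_da - dll_db)
        g0 = g_eta.sum()
        gbeta = X.T @ g_eta - beta / self.prior_sd**2
        g_logphi = phi * (w @ (mu * dll_da + (1 - mu) * dll_db))
        return -np.concatenate(([g0], gbeta, [g_logphi]))

    def fit(self, X, y, sample_weight=None):
        X, y, w = self._prepare(X, y, sample_weight)
        if np.any(y < 0) or np.any(y > self.n_trials):
            raise ValueError(f"scores must lie in [0, {self.n_trials}]")
        ybar = np.clip(y.mean() / self.n_trials, 1e-3, 1 - 1e-3)
        x0 = np.concatenate(([special.logit(ybar)], np.zeros(X.shape[1]), [np.log(10.0)]))
        self._fit_map(X, y, w, x0)
        self.intercept_ = float(self.params_[0])
        self.coef_ = self.params_[1:-1].copy()
        self.dispersion_ = float(np.exp(self.params_[-1]))
        return self

    def predict_mu(self, X, params=None) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        p = self.params_ if params is None else params
        return _expit(p[0] + X @ p[1:-1])

    def predict(self, X) -> np.ndarray:
        """Expected score (n_trials * mu)."""
        return self.n_trials * self.predict_mu(X)


class BayesLogisticRegression(_MapModel):
    """Weighted logistic regression with a normal(0, prior_sd) slope prior."""

    _n_extra = 0

    def _unpack(self, params):
        return params[0], params[1:]

    def _neg_logpost(self, params, X, y, w):
        b0, beta = self._unpack(params)
        eta = b0 + X @ beta
        # log-likelihood of Bernoulli in the numerically stable form
        ll = y * eta - np.logaddexp(0.0, eta)
        return -(w @ ll) + self._penalty(beta)

    def _neg_grad(self, params, X, y, w):
        b0, beta = self._unpack(params)
        p = _expit(b0 + X @ beta)
        g_eta = w * (y - p)
        return -np.concatenate(([g_eta.sum()], X.T @ g_eta - beta / self.prior_sd**2))

    def fit(self, X, y, sample_weight=None):
        X, y, w = self._prepare(X, y, sample_weight)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("diagnosis outcome must be 0/1")
        x0 = np.zeros(X.shape[1] + 1)
        x0[0] = special.logit(np.clip(y.mean(), 1e-4, 1 - 1e-4))
        self._fit_map(X, y, w, x0)
        self.intercept_ = float(self.params_[0])
        self.coef_ = self.params_[1:].copy()
        # flag (quasi-)separation: fitted probabilities piling on 0/1
        phat = self.predict_proba(X)
        self.separation_flag_ = bool(np.mean((phat < 1e-6) | (phat > 1 - 1e-6)) > 0.01)
        if self.separation_flag_:
            warnings.warn("possible separation: fitted probabilities at the boundary")
        return self

    def predict_proba(self, X, params=None) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        p = self.params_ if params is None else params
        return _expit(p[0] + X @ p[1:])

    predict_mu = predict_proba


def _shifted(X, idx, delta):
    Xs = np.array(X, dtype=float, copy=True)
    Xs[:, idx] += delta
    return Xs


def _interval(draws_values, point, scale):
    lo, hi = np.percentile(draws_values, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return EffectEstimate(float(point), float(lo), float(hi), scale)


def ame(
    model: BetaBinomialRegression,
    X,
    exposure: str | int,
    delta: float = 1.0,
    n_draws: int = 2000,
    rng=None,
) -> tuple[EffectEstimate, EffectEstimate]:
    """Absolute and relative average marginal effect of a ``delta`` shift.

    ``delta`` is expressed in the units of the model's exposure column
    (pass 1.0 when the model was fitted on a standardized exposure), so
    it represents a one-SD change of the raw score.
    """
    idx = model.get_feature_index(exposure) if isinstance(exposure, str) else exposure
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xs = _shifted(Xa, idx, delta)
    n = model.n_trials

    def _ame(params):
        mu0 = model.predict_mu(Xa, params)
        mu1 = model.predict_mu(Xs, params)
        absolute = n * float(np.mean(mu1 - mu0))
        relative = 100.0 * absolute / (n * float(np.mean(mu0)))
        return absolute, relative

    pt_abs, pt_rel = _ame(model.params_)
    draws = model.posterior_draws(n_draws, rng)
    vals = np.array([_ame(d) for d in draws])
    return (
        _interval(vals[:, 0], pt_abs, "absolute_ame"),
        _interval(vals[:, 1], pt_rel, "relative_ame_pct"),
    )


def marginal_rr(
    model: BayesLogisticRegression,
    X,
    exposure: str | int,
    delta: float = 1.0,
    n_draws: int = 2000,
    rng=None,
) -> EffectEstimate:
    """Marginal-standardization relative risk for a ``delta`` shift."""
    idx = model.get_feature_index(exposure) if isinstance(exposure, str) else exposure
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xs = _shifted(Xa, idx, delta)

    def _rr(params):
        p0 = float(np.mean(model.predict_proba(Xa, params)))
        if p0 <= 0:
            raise ValueError("mean baseline probability is zero")
        return float(np.mean(model.predict_proba(Xs, params))) / p0

    point = _rr(model.params_)
    draws = model.posterior_draws(n_draws, rng)
    vals = np.array([_rr(d) for d in draws])
    return _interval(vals, point, "rr")


def prevalence_curve(
    baseline_prevalence: float,
    rr_per_sd: float,
    shifts,
    model: BayesLogisticRegression | None = None,
    X=None,
    exposure: str | int | None = None,
) -> pd.DataFrame:
    """Prevalence under SD-shifts of the exposure.

    The closed-form column extrapolates log-linearly,
    ``prevalence(k) = baseline * rr^k``, clipped to (0, 1) with a
    warning.  When a fitted logistic model (plus its design matrix and
    exposure column) is supplied, a model-based column re-averages the
    predicted probabilities under each shift.
    """
    if not 0 < baseline_prevalence < 1:
        raise ValueError("baseline prevalence must be in (0, 1)")
    if rr_per_sd <= 0:
        raise ValueError("relative risk must be positive")
    shifts = np.asarray(list(shifts), dtype=float)
    prev = baseline_prevalence * rr_per_sd**shifts
    if np.any(prev >= 1) or np.any(prev <= 0):
        warnings.warn("extrapolated prevalence left (0,1); clipping")
        prev = np.clip(prev, 1e-12, 1 - 1e-12)
    out = pd.DataFrame({"shift_sd": shifts, "prevalence_pct": 100.0 * prev})
    if model is not None:
        if X is None or exposure is None:
            raise ValueError("model-based curve needs X and the exposure column")
        idx = model.get_feature_index(exposure) if isinstance(exposure, str) else exposure
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        out["prevalence_pct_model"] = [
            100.0 * float(np.mean(model.predict_proba(_shifted(Xa, idx, k)))) for k in shifts
        ]
    return out


def stratified_fit(
    model_factory,
    X: pd.DataFrame,
    y,
    strata,
    exposure: str,
    effect: str = "ame",
    sample_weight=None,
    delta: float = 1.0,
    min_stratum: int = 50,
    rng=None,
) -> dict:
    """Fit one model per stratum and summarise effect homogeneity.

    ``model_factory()`` must return an unfitted estimator.  Strata too
    small to fit are skipped (recorded under ``"skipped"``).  The
    homogeneity summary reports whether all pairwise 95% intervals
    overlap.
    """
    strata = pd.Series(np.asarray(strata), index=X.index)
    y = pd.Series(np.asarray(y), index=X.index)
    w = None if sample_weight is None else pd.Series(np.asarray(sample_weight), index=X.index)
    estimates: dict = {}
    skipped = []
    for level, idx in strata.groupby(strata).groups.items():
        if len(idx) < min_stratum:
            skipped.append(str(level))
            continue
        Xi, yi = X.loc[idx], y.loc[idx]
        wi = None if w is None else w.loc[idx].to_numpy()
        model = model_factory().fit(Xi, yi, sample_weight=wi)
        if effect == "ame":
            estimates[level] = ame(model, Xi, exposure, delta, rng=rng)[0]
        elif effect == "rr":
            estimates[level] = marginal_rr(model, Xi, exposure, delta, rng=rng)
        else:
            raise ValueError("effect must be 'ame' or 'rr'")
    keys = list(estimates)
    homogeneous = all(
        estimates[a].overlaps(estimates[b]) for i, a in enumerate(keys) for b in keys[i + 1:]
    )
    return {"estimates": estimates, "homogeneous": homogeneous, "skipped": skipped}
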