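"""End-to-end analysis pipeline.

Orchestrates simulate -> score -> weight -> fit -> validate -> report on
CSV tables, mirroring the analysis design of a diet-quality /
child-ADHD cohort study: for each exposure (PDQI, UPFI, CDQI) a crude
and an adjusted model are fitted for both outcomes (beta-binomial for
the symptom sum, logistic for the diagnosis), all inverse-probability
weighted, with effects summarised as absolute/relative AMEs and marginal
relative risks per 1 SD of exposure, plus a prevalence-extrapolation
curve and index validity metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .indices import standardize
from .ipw import InverseProbabilityWeighter
from .models import (
    BayesLogisticRegression,
    BetaBinomialRegression,
    ame,
    marginal_rr,
    prevalence_curve,
)
from .simulate import GeneratorConfig, generate_cohort
from .validity import hedges_g, index_correlations, omega_total

logger = logging.getLogger("dietcohort")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: covariate sets for the adjusted models; maternal exposures adjust for
#: child diet and vice versa, plus the shared confounder set
ADJUSTED_COVARIATES = {
    "pdqi": ["bmi", "education", "smoking", "alcohol", "depression_score",
             "maternal_adhd", "maternal_age", "parity", "child_sex", "cdqi",
             "birth_quarter"],
    "upfi": ["bmi", "education", "smoking", "alcohol", "depression_score",
             "maternal_adhd", "maternal_age", "parity", "child_sex", "cdqi",
             "birth_quarter"],
    "cdqi": ["bmi", "education", "maternal_adhd", "maternal_age", "pdqi",
             "child_sex", "parity", "sleep_problems", "birth_quarter"],
}

_CATEGORICAL = {"education", "birth_quarter", "child_sex"}


def build_design(
    df: pd.DataFrame, exposure: str, covariates: list[str]
) -> tuple[pd.DataFrame, float, pd.Index]:
    """Complete-case design matrix with a standardized exposure column.

    Returns ``(X, exposure_sd, kept_index)``; categorical covariates are
    dummy-coded (first level dropped), the exposure is standardized on
    the complete-case analysis sample so its coefficient is per 1 SD.
    """
    cols = [exposure] + [c for c in covariates if c != exposure]
    sub = df[cols].dropna()
    z, sd = standardize(sub[exposure].to_numpy())
    parts = [pd.Series(z, index=sub.index, name=f"{exposure}_z")]
    for c in cols[1:]:
        if c in _CATEGORICAL:
            d = pd.get_dummies(sub[c].astype("category"), prefix=c, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(sub[c].astype(float))
    return pd.concat(parts, axis=1), sd, sub.index


def fit_outcome_model(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    adjusted: bool = True,
    weight_col: str | None = "weight",
    n_draws: int = 2000,
    rng=None,
) -> dict:
    """Fit one exposure/outcome model and derive its effect estimates.

    ``outcome`` is ``"symptoms"`` (beta-binomial on the 0-54 sum) or
    ``"diagnosis"`` (logistic).  Complete cases on the model's variables
    only; the returned dict carries the fitted model, design matrix,
    exposure SD, bookkeeping and the 1-SD effect estimates.
    """
    ycol = {"symptoms": "adhd_symptoms", "diagnosis": "adhd_diagnosis"}[outcome]
    covars = ADJUSTED_COVARIATES[exposure] if adjusted else []
    needed = [ycol] + ([weight_col] if weight_col else [])
    frame = cohort.dropna(subset=[c for c in needed if c in cohort.columns])
    X, sd, idx = build_design(frame, exposure, covars)
    y = frame.loc[idx, ycol].to_numpy()
    w = frame.loc[idx, weight_col].to_numpy() if weight_col else None
    if outcome == "symptoms":
        model = BetaBinomialRegression().fit(X, y, sample_weight=w)
        absolute, relative = ame(model, X, f"{exposure}_z", 1.0, n_draws=n_draws, rng=rng)
        effects = {"absolute_ame": absolute, "relative_ame": relative}
    else:
        model = BayesLogisticRegression().fit(X, y, sample_weight=w)
        effects = {"rr": marginal_rr(model, X, f"{exposure}_z", 1.0, n_draws=n_draws, rng=rng)}
    return {
        "model": model,
        "X": X,
        "exposure_sd": sd,
        "n": len(idx),
        "n_input": len(cohort),
        "n_cases": int(y.sum()) if outcome == "diagnosis" else None,
        "effects": effects,
        "adjusted": adjusted,
        "exposure": exposure,
        "outcome": outcome,
    }


def _round(x, nd=2):
    return None if x is None else round(float(x), nd)


def _effects_json(effects, sd):
    out = {}
    for name, est in effects.items():
        nd = 1 if name == "relative_ame" else 2
        out[name] = {
            "estimate": _round(est.estimate, nd),
            "lower": _round(est.lower, nd),
            "upper": _round(est.upper, nd),
        }
    out["exposure_sd"] = _round(sd, 2)
    return out


def run_pipeline(
    config: GeneratorConfig | dict | None = None,
    outdir: str | Path = "pipeline_out",
    exposures: tuple = ("pdqi", "upfi", "cdqi"),
    make_figures: bool = True,
    n_draws: int = 1000,
) -> dict:
    """Run the full chain and write a deterministic JSON report bundle."""
    if config is None:
        config = GeneratorConfig()
    elif isinstance(config, dict):
        config = GeneratorConfig(**config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "version": __version__,
    }

    logger.info("simulate: population n=%d, seed=%d", config.n_population, config.seed)
    sim = generate_cohort(config)
    sim.write(outdir)

    sample = sim.cohort[sim.cohort["selected"] == 1].copy()
    logger.info("selection: %d of %d subjects participate", len(sample), len(sim.cohort))

    weighter = InverseProbabilityWeighter(sim.population_margins).fit(sample)
    sample = weighter.transform(sample)

    report: dict = {"manifest": manifest, "models": {}, "n": {"population": len(sim.cohort),
                                                              "sample": len(sample)}}
    rng = np.random.default_rng(config.seed + 1)
    for exposure in exposures:
        report["models"][exposure] = {}
        for outcome in ("symptoms", "diagnosis"):
            for adjusted in (False, True):
                tag = "adjusted" if adjusted else "crude"
                res = fit_outcome_model(
                    sample, exposure, outcome, adjusted=adjusted, n_draws=n_draws, rng=rng
                )
                logger.info(
                    "fit %s/%s/%s: complete cases n=%d%s", exposure, outcome, tag,
                    res["n"], f" (cases {res['n_cases']})" if res["n_cases"] else "",
                )
                report["models"][exposure].setdefault(outcome, {})[tag] = {
                    "n_complete": res["n"],
                    "n_cases": res["n_cases"],
                    **_effects_json(res["effects"], res["exposure_sd"]),
                }
                if exposure == "pdqi" and outcome == "diagnosis" and adjusted:
                    diag_res = res

    # prevalence extrapolation from the adjusted PDQI-diagnosis model
    baseline = sample["adhd_diagnosis"].mean()
    rr = diag_res["effects"]["rr"].estimate
    curve = prevalence_curve(baseline, rr, range(-5, 4),
                             model=diag_res["model"], X=diag_res["X"],
                             exposure="pdqi_z")
    curve.to_csv(outdir / "prevalence_curve.csv", index=False, float_format="%.6g")
    report["prevalence_curve"] = {
        str(int(k)): _round(v, 1)
        for k, v in zip(curve["shift_sd"], curve["prevalence_pct"])
    }

    # validity metrics on the analysis sample
    low, high = sample["education"] == 0, sample["education"] == 3
    g_upfi = hedges_g(sample.loc[low, "upfi"], sample.loc[high, "upfi"],
                      ("education<12y", "master"))
    # omega over the three CDQI components, recomputed from the child intakes
    from .indices import CDQIScorer
    comp = CDQIScorer(sim.metadata.child).fit(None).transform(
        sim.intake_child.set_index("subject_id").loc[sample["subject_id"]]
    )[["cdqi_diversity", "cdqi_quality", "cdqi_equilibrium"]]
    report["validity"] = {
        "hedges_g_upfi_low_vs_high_education": _round(g_upfi.g, 2),
        "omega_total_cdqi": _round(omega_total(comp.to_numpy()), 2),
        "r_pdqi_upfi": _round(index_correlations(sample[["pdqi", "upfi"]]).loc["pdqi", "upfi"], 2),
        "r_pdqi_cdqi": _round(index_correlations(sample[["pdqi", "cdqi"]]).loc["pdqi", "cdqi"], 2),
    }

    if make_figures:
        _figures(report, curve, outdir)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", outdir / "report.json")
    return report


def _forest(ax, rows, title, xlabel, ref):
    labels = [r[0] for r in rows]
    for i, (_, est) in enumerate(rows):
        ax.plot([est["lower"], est["upper"]], [i, i], "-", color="C0")
        ax.plot(est["estimate"], i, "s", color="C0")
    ax.axvline(ref, color="grey", lw=0.8, ls="--")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_title(title)
    ax.set_xlabel(xlabel)


def _figures(report, curve, outdir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ame_rows = [
        (f"{e} ({tag})", report["models"][e]["symptoms"][tag]["absolute_ame"])
        for e in report["models"] for tag in ("crude", "adjusted")
    ]
    rr_rows = [
        (f"{e} ({tag})", report["models"][e]["diagnosis"][tag]["rr"])
        for e in report["models"] for tag in ("crude", "adjusted")
    ]
    _forest(axes[0], ame_rows, "Symptom score AME per 1 SD", "score units", 0.0)
    _forest(axes[1], rr_rows, "Diagnosis RR per 1 SD", "relative risk", 1.0)
    fig.tight_layout()
    fig.savefig(outdir / "forest.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["shift_sd"], curve["prevalence_pct"], "o-", label="log-linear")
    if "prevalence_pct_model" in curve:
        ax.plot(curve["shift_sd"], curve["prevalence_pct_model"], "s--", label="model-based")
    ax.set_xlabel("exposure shift (SD)")
    ax.set_ylabel("diagnosis prevalence (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "prevalence_curve.png", dpi=120)
    plt.close(fig)
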