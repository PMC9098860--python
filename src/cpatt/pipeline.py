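"""End-to-end orchestration: preprocess -> propensity -> matching -> the
three estimators -> bootstrap -> effect-size categories -> summary.

For every treatment the pipeline produces five estimates per outcome level
(DM on the matched subset; VT and BCF each on the matched subset and on all
treated limbs), then pools Cohen's d across treatments and estimates per
level as median and interquartile range.  Comparing matched-subset with
all-treated estimates is the built-in check for bias from omitted
(unmatchable) treated limbs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .bart.model import BartParams, evaluate_propensity, fit_bart_probit
from .bcf import BcfParams, fit_bcf
from .estimators import (AttEstimate, bcf_att, dm_att, model_covariate_frame,
                         vt_att)
from .matching import MatchSpec, mahalanobis_rank_distance, solve_match
from .synthdata import LEVELS, SyntheticTruth, TREATMENTS

log = logging.getLogger(__name__)

EFFECT_THRESHOLDS = (("very large", 1.2), ("large", 0.8),
                     ("medium", 0.5), ("small", 0.2))

#: continuous exam/kinematic measures used in the distance by default
DEFAULT_DISTANCE_COVARIATES = [
    "age", "ank_dors_0", "pop_ang_uni", "anteversion", "bimal_angle",
    "speed_dimless", "body_structures_baseline", "specific_kinematic_baseline",
    "overall_kinematic_baseline", "functional_mobility_baseline",
]


def categorize_effect(d: float) -> str:
    """Conventional effect-size category by |d|: small >= 0.2,
    medium >= 0.5, large >= 0.8, very large >= 1.2 (half-open upward)."""
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    a = abs(d)
    for name, cut in EFFECT_THRESHOLDS:
        if a >= cut:
            return name
    return "none"


def aggregate_summary(estimates, pool: str = "all") -> pd.DataFrame:
    """Median and IQR of Cohen's d per outcome level.

    pool="all" pools every estimate (5 per treatment x level);
    pool="by-treatment" first averages the 5 estimates within a treatment.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    df = estimates_frame(estimates)
    if pool == "by-treatment":
        df = (df.groupby(["level", "treatment"], as_index=False)["d"].mean())
    rows = []
    for lv in LEVELS:
        sub = df.loc[df["level"] == lv, "d"]
        if sub.empty:
            raise ValueError(f"missing outcome level {lv!r}")
        rows.append({"level": lv,
                     "median_d": float(sub.median()),
                     "iqr_low": float(sub.quantile(0.25)),
                     "iqr_high": float(sub.quantile(0.75)),
                     "n_estimates": int(len(sub))})
    return pd.DataFrame(rows)


def estimates_frame(estimates) -> pd.DataFrame:
    """Tidy frame: one row per treatment x level x model x sample."""
    rows = []
    for e in estimates:
        rows.append({"treatment": e.treatment, "level": e.level,
                     "outcome": e.outcome, "model": e.model,
                     "sample": e.sample, "effect": e.effect, "d": e.d,
                     "ci_low": e.ci_low, "ci_high": e.ci_high,
                     "n_treated": e.n_treated,
                     "category": categorize_effect(e.d),
                     "borderline": e.borderline})
    return pd.DataFrame(rows)


@dataclass
class AnalysisConfig:
    treatments: tuple = TREATMENTS
    match_spec: MatchSpec | None = None
    bart_params: BartParams = field(default_factory=lambda: BartParams(
        n_burn=250, n_keep=500))
    bcf_params: BcfParams = field(default_factory=lambda: BcfParams(
        n_burn=250, n_keep=500))
    n_boot: int = 1000
    full_mcmc: bool = False   # restore the full 1000/1000 MCMC budget
    pool: str = "all"
    output_dir: str | None = None
    seed: int = 0

    def resolved_bart(self) -> BartParams:
        p = self.bart_params
        if self.full_mcmc:
            p = replace(p, n_burn=250, n_keep=1000)
        return p

    def resolved_bcf(self) -> BcfParams:
        p = self.bcf_params
        if self.full_mcmc:
            p = replace(p, n_burn=1000, n_keep=1000)
        return p


@dataclass
class AnalysisResult:
    estimates: list
    estimates_table: pd.DataFrame
    summary: pd.DataFrame
    balance: dict                # {treatment: BalanceReport}
    match_results: dict          # {treatment: MatchResult}
    propensity_metrics: dict     # {treatment: dict}
    recovery: pd.DataFrame | None = None


def prepare_cohort(cohort: pd.DataFrame,
                   rules: preprocess.EligibilityRules | None = None,
                   faq_weights=None) -> pd.DataFrame:
    """Standard preprocessing: eligibility filter, functional-mobility
    score with near-complete imputation, "Miss" encoding, and listwise
    deletion of rows with missing numeric covariates."""
    out = preprocess.filter_eligible(cohort, rules)
    if any(c.startswith("faq_item_") for c in out.columns):
        out = preprocess.impute_faqt(out, weights=faq_weights)
    out = preprocess.encode_missing_categorical(out)
    num_cols = [c for c in out.columns
                if pd.api.types.is_numeric_dtype(out[c])
                and not c.startswith("faq_item_")]
    before = len(out)
    out = out.dropna(subset=num_cols)
    log.info("complete-case filter removed %d rows", before - len(out))
    return out.reset_index(drop=True)


def propensity_holdout_metrics(X_prop: pd.DataFrame, z: np.ndarray,
                               params: BartParams, seed: int) -> dict:
    """Honest out-of-sample propensity metrics: refit on a random half,
    score the other half."""
    rng = np.random.RandomState(seed)
    perm = rng.permutation(len(z))
    tr, te = perm[: len(z) // 2], perm[len(z) // 2:]
    try:
        post = fit_bart_probit(X_prop.iloc[tr], z[tr],
                               replace(params, seed=seed + 7))
        scores = post.predict(X_prop.iloc[te])
        acc, sens, spec, auc = evaluate_propensity(scores, z[te])
    except ValueError:
        return {}
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "auc": auc}


def analyze_treatment(cohort: pd.DataFrame, treatment: str,
                      config: AnalysisConfig):
    """Propensity fit, matching, and the 20 estimates (4 levels x 5) for
    one treatment.  Returns (estimates, match_result, balance, prop_metrics).
    """
    z_col = f"interval_{treatment}"
    z = cohort[z_col].to_numpy()
    bart_p = config.resolved_bart()
    bcf_p = config.resolved_bcf()
    seed = config.seed

    # --- propensity (probit BART, uniform covariates minus the index flag)
    X_prop = model_covariate_frame(cohort, treatment, include_index_flag=False)
    # propensity fits keep the full 1000 retained draws (their default
    # budget); the reduced budget applies to the outcome models
    prop_post = fit_bart_probit(
        X_prop, z, replace(bart_p, seed=seed * 1000 + 1, n_keep=1000))
    pihat = np.clip(prop_post.predict(X_prop), 1e-4, 1 - 1e-4)
    prop_metrics = propensity_holdout_metrics(X_prop, z, bart_p,
                                              seed * 1000 + 2)

    # --- matching
    spec = config.match_spec
    if spec is None:
        dist_cov = [c for c in DEFAULT_DISTANCE_COVARIATES if c in cohort.columns]
        nf = [c for c in cohort.columns
              if (c.startswith("prior_") or c.startswith("interval_"))
              and c != z_col]
        spec = MatchSpec(distance_covariates=dist_cov, near_fine_vars=nf)
    tmask = z == 1
    D = mahalanobis_rank_distance(cohort.loc[tmask, spec.distance_covariates],
                                  cohort.loc[~tmask, spec.distance_covariates])
    mres = solve_match(
        D, spec,
        propensity_treated=pihat[tmask], propensity_control=pihat[~tmask],
        co_treatment_treated=cohort.loc[tmask, spec.near_fine_vars],
        co_treatment_control=cohort.loc[~tmask, spec.near_fine_vars],
        moment_treated=cohort.loc[tmask, spec.moment_vars] if spec.moment_vars else None,
        moment_control=cohort.loc[~tmask, spec.moment_vars] if spec.moment_vars else None,
        treated_ids=cohort.loc[tmask, "limb_id"].to_numpy(),
        control_ids=cohort.loc[~tmask, "limb_id"].to_numpy())
    covariate_sets = {
        "exam": [c for c in spec.distance_covariates if not c.endswith("_baseline")],
        "kinematic": [c for c in spec.distance_covariates if c.endswith("_baseline")],
    }
    bal_cohort = cohort.copy()
    bal_cohort["_propensity"] = pihat
    covariate_sets["propensity"] = ["_propensity"]
    balance = preprocess.balance_report(bal_cohort, mres.pairs,
                                        covariate_sets, treatment)
    mres.balance = balance
    matched_treated = [a for a, _ in mres.pairs]

    estimates = []
    X_vt = model_covariate_frame(cohort, treatment)
    for kk, lv in enumerate(LEVELS):
        try:
            y = cohort[f"{lv}_followup"].to_numpy()
            est_seed = seed * 1000 + kk
            estimates.append(dm_att(mres.pairs, cohort, lv,
                                    treatment=treatment,
                                    n_boot=config.n_boot, seed=est_seed))
            from .bart.model import fit_bart
            vt_post = fit_bart(X_vt, y, replace(bart_p, seed=est_seed + 10))
            for sample, mids in (("matched", matched_treated),
                                 ("all-treated", None)):
                estimates.append(vt_att(cohort, treatment, lv, sample=sample,
                                        matched_ids=mids, n_boot=config.n_boot,
                                        seed=est_seed, post=vt_post, X=X_vt))
            bcf_post = fit_bcf(
                model_covariate_frame(cohort, treatment, include_index_flag=False),
                z, pihat, y, replace(bcf_p, seed=est_seed + 20))
            for sample, mids in (("matched", matched_treated),
                                 ("all-treated", None)):
                estimates.append(bcf_att(cohort, treatment, lv, pihat,
                                         sample=sample, matched_ids=mids,
                                         n_boot=config.n_boot, seed=est_seed,
                                         post=bcf_post))
        except Exception:
            log.exception("estimation failed for %s / %s; continuing",
                          treatment, lv)
    return estimates, mres, balance, prop_metrics


def run_full_analysis(cohort: pd.DataFrame,
                      truth: SyntheticTruth | None = None,
                      config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the whole analysis over the configured treatments.

    A stage failure aborts that treatment (logged) and the others continue.
    When a ground truth is supplied, a per-estimate recovery report
    (estimated vs true d) is appended.
    """
    config = config or AnalysisConfig()
    all_est = []
    balance = {}
    match_results = {}
    prop_metrics = {}
    for treatment in config.treatments:
        if f"interval_{treatment}" not in cohort.columns:
            log.warning("treatment %s not in cohort; skipped", treatment)
            continue
        try:
            est, mres, bal, pm = analyze_treatment(cohort, treatment, config)
        except Exception:
            log.exception("treatment %s failed; continuing", treatment)
            continue
        all_est.extend(est)
        balance[treatment] = bal
        match_results[treatment] = mres
        prop_metrics[treatment] = pm

    table = estimates_frame(all_est)
    summary = aggregate_summary(all_est, pool=config.pool)

    recovery = None
    if truth is not None and not table.empty:
        rec = table.copy()
        rec["d_true"] = [truth.att_d(t, lv) for t, lv
                         in zip(rec["treatment"], rec["level"])]
        rec["d_err"] = rec["d"] - rec["d_true"]
        recovery = rec

    result = AnalysisResult(estimates=all_est, estimates_table=table,
                            summary=summary, balance=balance,
                            match_results=match_results,
                            propensity_metrics=prop_metrics,
                            recovery=recovery)
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


def write_outputs(result: AnalysisResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.estimates_table.to_csv(out / "estimates.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    for t, bal in result.balance.items():
        bal.smd.to_csv(out / f"balance_{t}.csv", index=False)
    if result.recovery is not None:
        result.recovery.to_csv(out / "recovery.csv", index=False)
    try:
        forest_plot(result.estimates_table, out / "forest.svg")
    except Exception:
        log.exception("figure generation failed")


def forest_plot(table: pd.DataFrame, path) -> None:
    """Forest-style plot: one panel per outcome level, effect sizes with
    95% CIs per treatment x model x sample."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = [lv for lv in LEVELS if lv in set(table["level"])]
    fig, axes = plt.subplots(1, len(levels), figsize=(4 * len(levels), 6),
                             sharey=True, squeeze=False)
    for ax, lv in zip(axes[0], levels):
        sub = table[table["level"] == lv].reset_index(drop=True)
        labels = sub["treatment"].str[:18] + " " + sub["model"] + "/" + sub["sample"].str[:3]
        ypos = np.arange(len(sub))
        ax.errorbar(sub["d"], ypos,
                    xerr=[sub["d"] - sub["ci_low"], sub["ci_high"] - sub["d"]],
                    fmt="o", ms=3, lw=1)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(lv.replace("_", " "))
        ax.set_xlabel("Cohen's d")
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels, fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
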