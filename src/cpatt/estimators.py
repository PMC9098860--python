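"""The three ATT estimators (direct matching, virtual twins, Bayesian
causal forest), Cohen's-d standardization, and limb-level bootstrap
confidence intervals.

Per-limb effect estimates are resampled (limbs are the bootstrap unit, so
no independence assumption is made about limbs of the same individual);
models are not refit inside the bootstrap.  For the posterior-based
estimators a replicate also draws a random posterior index, so the interval
reflects both sampling and model uncertainty.

Outcome convention: the virtual-twin and causal-forest models regress the
follow-up value on covariates including the baseline value; direct matching
differences pre/post changes between matched limbs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart.model import BartParams, BartPosterior, fit_bart
from .bcf import BcfParams, BcfPosterior, bcf_tau_draws, fit_bcf
from .synthdata import LEVELS

log = logging.getLogger(__name__)


@dataclass
class AttEstimate:
    treatment: str
    outcome: str
    level: str                  # one of LEVELS
    model: str                  # DM | VT | BCF
    sample: str                 # matched | all-treated
    effect: float               # raw ATT, outcome units
    d: float                    # Cohen's d
    ci_low: float               # 95% bootstrap CI, d units
    ci_high: float
    n_treated: int
    borderline: bool = False    # CI straddles 0

    def __post_init__(self):
        if self.model == "DM" and self.sample != "matched":
            raise ValueError("DM estimates are defined on the matched sample")


def change_sd(cohort: pd.DataFrame, level: str) -> float:
    """SD of the outcome change (follow-up minus baseline) over all
    analysis limbs; the default Cohen's-d standardizer."""
    ch = (cohort[f"{level}_followup"] - cohort[f"{level}_baseline"]).dropna()
    if len(ch) < 2:
        raise ValueError("need >= 2 analysis rows")
    sd = float(ch.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD of outcome change")
    return sd


def cohens_d(raw_effect: float, cohort: pd.DataFrame, level: str) -> float:
    """Standardize a raw ATT by the change SD of the analysis sample."""
    sd = change_sd(cohort, level)
    log.info("Cohen's d standardizer: change SD over all analysis limbs "
             "(%s: %.4f)", level, sd)
    return raw_effect / sd


def bootstrap_att(per_limb_effects, n_boot: int = 1000, seed: int = 0,
                  draws: np.ndarray | None = None):
    """Percentile bootstrap of the mean effect, resampling limbs.

    per_limb_effects : point effect per limb (posterior means for VT/BCF).
    draws : optional (n_draws, n_limbs) matrix of per-limb effect draws;
        when given, each replicate uses a random draw row (model
        uncertainty) on top of limb resampling.
    Returns (mean, ci_low, ci_high).
    """
    eff = np.asarray(per_limb_effects, dtype=float)
    if len(eff) < 2:
        raise ValueError("need >= 2 per-limb effects")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable interval endpoints")
    rng = np.random.RandomState(seed)
    n = len(eff)
    idx = rng.randint(0, n, size=(n_boot, n))
    if draws is not None:
        draws = np.asarray(draws, dtype=float)
        di = rng.randint(0, draws.shape[0], size=n_boot)
        reps = draws[di[:, None], idx].mean(axis=1)
    else:
        reps = eff[idx].mean(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(eff.mean()), float(lo), float(hi)


def _finish(treatment, outcome, level, model, sample, effect, effects,
            cohort, n_boot, seed, draws=None) -> AttEstimate:
    sd = change_sd(cohort, level)
    _, lo, hi = bootstrap_att(effects, n_boot=n_boot, seed=seed, draws=draws)
    d = effect / sd
    lo_d, hi_d = lo / sd, hi / sd
    return AttEstimate(treatment=treatment, outcome=outcome, level=level,
                       model=model, sample=sample, effect=float(effect),
                       d=float(d), ci_low=float(lo_d), ci_high=float(hi_d),
                       n_treated=len(effects),
                       borderline=bool(lo_d <= 0.0 <= hi_d))


# ---------------------------------------------------------------- DM ----

def dm_att(pairs, cohort: pd.DataFrame, level: str, treatment: str = "",
           outcome: str | None = None, n_boot: int = 1000,
           seed: int = 0) -> AttEstimate:
    """Direct-matching ATT: mean over pairs of
    (change of treated limb) - (change of matched control limb)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty match set")
    outcome = outcome or f"{level}_followup"
    idx = cohort.set_index("limb_id")
    ch = idx[f"{level}_followup"] - idx[f"{level}_baseline"]
    effects = []
    dropped = 0
    for t_id, c_id in pairs:
        e = ch.get(t_id, np.nan) - ch.get(c_id, np.nan)
        if np.isnan(e):
            dropped += 1
        else:
            effects.append(e)
    if dropped:
        log.info("dm_att: dropped %d pairs with missing outcomes", dropped)
    effects = np.asarray(effects)
    return _finish(treatment, outcome, level, "DM", "matched",
                   effects.mean(), effects, cohort, n_boot, seed)


# ---------------------------------------------------------------- VT ----

def model_covariate_frame(cohort: pd.DataFrame, treatment: str,
                          extra_numeric=(), include_index_flag: bool = True
                          ) -> pd.DataFrame:
    """Uniform covariate set for the outcome/propensity models: age, sex,
    follow-up interval, exam measures, clinical scores, classifications,
    all prior flags, all interval flags, and the four baseline outcomes."""
    cols = []
    for c in cohort.columns:
        if c in ("subject_id", "limb_id", "kvv_rom"):
            continue
        if c.endswith("_followup") or c.startswith("faq_item_"):
            continue
        if c == f"interval_{treatment}" and not include_index_flag:
            continue
        cols.append(c)
    out = cohort[cols].copy()
    for c in extra_numeric:
        out[c] = cohort[c]
    return out


def vt_effects(post: BartPosterior, X: pd.DataFrame, z_col: str,
               rows=None):
    """Per-limb virtual-twin effects for treated rows.

    For each row in ``rows`` (default: all with X[z_col] == 1), predict the
    observed configuration and its twin with the treatment flag flipped to
    0; the effect is the posterior-mean difference.  Returns (effects,
    effect_draws) with shapes (n,) and (n_keep, n).
    """
    if rows is None:
        rows = np.flatnonzero(X[z_col].to_numpy() == 1)
    rows = np.asarray(rows)
    Xs = X.iloc[rows]
    Xtwin = Xs.copy()
    Xtwin[z_col] = 0
    d_obs = post.predict_draws(Xs)
    d_twin = post.predict_draws(Xtwin)
    eff_draws = d_obs - d_twin
    return eff_draws.mean(axis=0), eff_draws


def vt_att(cohort: pd.DataFrame, treatment: str, level: str,
           sample: str = "all-treated", matched_ids=None,
           bart_params: BartParams | None = None, n_boot: int = 1000,
           seed: int = 0, post: BartPosterior | None = None,
           X: pd.DataFrame | None = None) -> AttEstimate:
    """Virtual-twins ATT at one outcome level.

    Fits BART of the follow-up outcome on the uniform covariate set
    (including the index-treatment flag and the baseline outcome), flips
    the flag for treated limbs, and averages the actual-minus-twin gap over
    the requested sample ("all-treated" or "matched", the latter requiring
    ``matched_ids`` = treated limb_ids of the matched subset).
    A prefit posterior (with its design frame X) may be passed to avoid
    refitting when several samples are evaluated.
    """
    z_col = f"interval_{treatment}"
    if X is None:
        X = model_covariate_frame(cohort, treatment)
    if post is None:
        post = fit_bart(X, cohort[f"{level}_followup"].to_numpy(),
                        bart_params or BartParams())
    z = X[z_col].to_numpy()
    if sample == "matched":
        if matched_ids is None:
            raise ValueError("matched sample requires matched_ids")
        limb = cohort["limb_id"].to_numpy()
        rows = np.flatnonzero(np.isin(limb, np.asarray(list(matched_ids))) & (z == 1))
    else:
        rows = np.flatnonzero(z == 1)
    if rows.size == 0:
        raise ValueError("empty sample")
    effects, eff_draws = vt_effects(post, X, z_col, rows)
    return _finish(treatment, f"{level}_followup", level, "VT", sample,
                   effects.mean(), effects, cohort, n_boot, seed,
                   draws=eff_draws)


# --------------------------------------------------------------- BCF ----

def bcf_att(cohort: pd.DataFrame, treatment: str, level: str,
            pihat, sample: str = "all-treated", matched_ids=None,
            bcf_params: BcfParams | None = None, n_boot: int = 1000,
            seed: int = 0, post: BcfPosterior | None = None) -> AttEstimate:
    """Causal-forest ATT: mean posterior individual effect over the
    treated limbs of the requested sample."""
    z_col = f"interval_{treatment}"
    z = cohort[z_col].to_numpy()
    if post is None:
        X = model_covariate_frame(cohort, treatment, include_index_flag=False)
        post = fit_bcf(X, z, np.asarray(pihat),
                       cohort[f"{level}_followup"].to_numpy(),
                       bcf_params or BcfParams())
    if sample == "matched":
        if matched_ids is None:
            raise ValueError("matched sample requires matched_ids")
        limb = cohort["limb_id"].to_numpy()
        rows = np.flatnonzero(np.isin(limb, np.asarray(list(matched_ids))) & (z == 1))
    else:
        rows = np.flatnonzero(z == 1)
    if rows.size == 0:
        raise ValueError("degenerate treated count")
    tau = bcf_tau_draws(post, rows)       # (n_keep, n_rows)
    effects = tau.mean(axis=0)
    return _finish(treatment, f"{level}_followup", level, "BCF", sample,
                   effects.mean(), effects, cohort, n_boot, seed, draws=tau)
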