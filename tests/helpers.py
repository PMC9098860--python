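"""Shared helpers for the statistical test harness."""

import itertools

import numpy as np

from dataclasses import replace

from cpatt import TREATMENTS
from cpatt.bart.model import BartParams, fit_bart_probit
from cpatt.bcf import BcfParams
from cpatt.estimators import (bcf_att, change_sd, dm_att, model_covariate_frame,
                              vt_att)
from cpatt.matching import MatchSpec, mahalanobis_rank_distance, solve_match
from cpatt.pipeline import DEFAULT_DISTANCE_COVARIATES

#: reduced desk-scale MCMC budget used across the statistical checks
BART_REDUCED = BartParams(n_burn=250, n_keep=500)
BCF_REDUCED = BcfParams(n_burn=250, n_keep=500)

T0 = TREATMENTS[0]
LEVEL1 = "body_structures"


def brute_force_optimum(cost, subset_w):
    """Exhaustive optimal-subset matching objective (oracle)."""
    nt, nc = cost.shape
    best = subset_w * nt
    for k in range(1, min(nt, nc) + 1):
        for tsub in itertools.combinations(range(nt), k):
            for csub in itertools.permutations(range(nc), k):
                obj = (sum(cost[t, c] for t, c in zip(tsub, csub))
                       + subset_w * (nt - k))
                best = min(best, obj)
    return best


def fit_propensity(prep, treatment=T0, seed=0):
    z = prep[f"interval_{treatment}"].to_numpy()
    Xp = model_covariate_frame(prep, treatment, include_index_flag=False)
    # propensity fits keep the full 1000 retained draws (default budget)
    post = fit_bart_probit(Xp, z, replace(BART_REDUCED, seed=seed,
                                          n_keep=1000))
    return np.clip(post.predict(Xp), 1e-4, 1 - 1e-4), z


def run_matching(prep, pihat, z, treatment=T0):
    dist_cov = [c for c in DEFAULT_DISTANCE_COVARIATES if c in prep.columns]
    nf = [c for c in prep.columns
          if (c.startswith("prior_") or c.startswith("interval_"))
          and c != f"interval_{treatment}"]
    tm = z == 1
    D = mahalanobis_rank_distance(prep.loc[tm, dist_cov],
                                  prep.loc[~tm, dist_cov])
    spec = MatchSpec(distance_covariates=dist_cov, near_fine_vars=nf)
    return solve_match(
        D, spec, pihat[tm], pihat[~tm], prep.loc[tm, nf], prep.loc[~tm, nf],
        treated_ids=prep.loc[tm, "limb_id"].to_numpy(),
        control_ids=prep.loc[~tm, "limb_id"].to_numpy()), spec


def estimate_all(prep, seed, with_dm=True, treatment=T0, level=LEVEL1):
    """The three ATT estimators (all-treated sample for VT/BCF; DM on its
    matched pairs) at one outcome level, reduced MCMC."""
    pihat, z = fit_propensity(prep, treatment, seed=seed * 10 + 1)
    out = {}
    out["VT"] = vt_att(prep, treatment, level, sample="all-treated",
                       bart_params=replace(BART_REDUCED, seed=seed * 10 + 2),
                       seed=seed)
    out["BCF"] = bcf_att(prep, treatment, level, pihat, sample="all-treated",
                         bcf_params=replace(BCF_REDUCED, seed=seed * 10 + 3),
                         seed=seed)
    if with_dm:
        mres, _ = run_matching(prep, pihat, z, treatment)
        out["DM"] = dm_att(mres.pairs, prep, level, treatment=treatment,
                           seed=seed)
    # naive unadjusted treated-minus-control difference in change, d units
    ch = prep[f"{level}_followup"] - prep[f"{level}_baseline"]
    out["naive_d"] = float((ch[z == 1].mean() - ch[z == 0].mean())
                           / change_sd(prep, level))
    return out


def true_d(prep, truth, treatment=T0, level=LEVEL1):
    """Realized true ATT (restricted to retained limbs) in d units."""
    limb = prep["limb_id"].to_numpy()
    mask = truth.treated[treatment].copy()
    keep = np.zeros_like(mask)
    keep[limb] = True
    mask = mask & keep
    att = truth.tau[treatment][level][mask].mean()
    return float(att / change_sd(prep, level))
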