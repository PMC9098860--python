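"""Propensity estimation and optimal-subset direct matching.

Fits the probit-BART propensity model, solves the one-to-one matching MIP
(rank-Mahalanobis distance, propensity caliper, near-fine balance on
co-treatment flags), and prints the balance improvement.
"""

import numpy as np

from cpatt import (MatchSpec, SyntheticConfig, balance_report, fit_bart_probit,
                   generate_cohort, inject_missingness,
                   mahalanobis_rank_distance, solve_match)
from cpatt.bart.model import BartParams
from cpatt.estimators import model_covariate_frame
from cpatt.pipeline import DEFAULT_DISTANCE_COVARIATES, prepare_cohort
from cpatt.synthdata import TREATMENTS

cfg = SyntheticConfig(seed=3)
cohort, _ = generate_cohort(cfg)
prep = prepare_cohort(inject_missingness(cohort, cfg))

t0 = TREATMENTS[0]
z = prep[f"interval_{t0}"].to_numpy()
X_prop = model_covariate_frame(prep, t0, include_index_flag=False)
prop = fit_bart_probit(X_prop, z, BartParams(n_burn=250, n_keep=500, seed=1))
pihat = np.clip(prop.predict(X_prop), 1e-4, 1 - 1e-4)

dist_cov = [c for c in DEFAULT_DISTANCE_COVARIATES if c in prep.columns]
co_flags = [c for c in prep.columns
            if (c.startswith("prior_") or c.startswith("interval_"))
            and c != f"interval_{t0}"]
spec = MatchSpec(distance_covariates=dist_cov, near_fine_vars=co_flags)
tm = z == 1
D = mahalanobis_rank_distance(prep.loc[tm, dist_cov], prep.loc[~tm, dist_cov])
mres = solve_match(D, spec, pihat[tm], pihat[~tm],
                   prep.loc[tm, co_flags], prep.loc[~tm, co_flags],
                   treated_ids=prep.loc[tm, "limb_id"].to_numpy(),
                   control_ids=prep.loc[~tm, "limb_id"].to_numpy())
print(f"matched {len(mres.pairs)} of {int(z.sum())} treated limbs "
      f"({100 * mres.matched_fraction:.0f}%), solver status: {mres.status}")

rep = balance_report(prep, mres.pairs, {"dist": dist_cov}, t0)
print(f"mean SMD raw -> matched: {rep.smd['raw'].mean():.3f} -> "
      f"{rep.smd['matched'].mean():.3f}")
print(f"mean |co-treatment rate difference| (matched): "
      f"prior {100 * rep.rate_diff['prior_diff'].abs().mean():.1f}%, "
      f"interval {100 * rep.rate_diff['interval_diff'].abs().mean():.1f}%")
# A several-fold SMD reduction with co-treatment rates matched within a few
# percent is what makes the matched pairwise outcome difference credible.
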