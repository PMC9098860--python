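"""Estimate one treatment's ATT with all three estimators.

Direct matching, virtual twins, and the Bayesian causal forest are run on
the same cohort at the body-structures outcome level; their Cohen's-d
estimates are printed next to the generator's ground truth.
"""

import numpy as np

from cpatt import (SyntheticConfig, generate_cohort, inject_missingness)
from cpatt.pipeline import AnalysisConfig, analyze_treatment, prepare_cohort
from cpatt.estimators import change_sd
from cpatt.synthdata import TREATMENTS

cfg = SyntheticConfig(seed=4)
cohort, truth = generate_cohort(cfg)
prep = prepare_cohort(inject_missingness(cohort, cfg))

t0 = TREATMENTS[0]
level = "body_structures"
ests, mres, bal, prop = analyze_treatment(prep, t0, AnalysisConfig(seed=1))

limb = prep["limb_id"].to_numpy()
mask = truth.treated[t0].copy()
keep = np.zeros_like(mask)
keep[limb] = True
dt = truth.tau[t0][level][mask & keep].mean() / change_sd(prep, level)
print(f"true ATT at {level} (d units): {dt:.3f}")

ch = prep[f"{level}_followup"] - prep[f"{level}_baseline"]
z = prep[f"interval_{t0}"] == 1
naive = (ch[z].mean() - ch[~z].mean()) / change_sd(prep, level)
print(f"naive difference-in-means: {naive:.3f}  <- confounded")

for e in ests:
    if e.level == level:
        print(f"{e.model:3s} ({e.sample:11s}): d = {e.d:6.3f}  "
              f"95% CI [{e.ci_low:.3f}, {e.ci_high:.3f}]  n={e.n_treated}")
# The unadjusted contrast is badly inflated by severity-driven selection
# into treatment; all three adjusted estimators remove most of that bias
# (regularized estimators retain some shrinkage toward zero).
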