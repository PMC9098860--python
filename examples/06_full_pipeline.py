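"""Run the full analysis over two treatments and aggregate.

Per treatment: propensity fit, matching, then 5 estimates per outcome
level (DM matched; VT and BCF each matched + all-treated).  The summary
pools Cohen's d across treatments and estimates: median and IQR per level,
which displays the attenuation along the causal chain.
"""

from cpatt import (AnalysisConfig, SyntheticConfig, generate_cohort,
                   inject_missingness, run_full_analysis)
from cpatt.pipeline import prepare_cohort
from cpatt.synthdata import TREATMENTS

cfg = SyntheticConfig(seed=5)
cohort, truth = generate_cohort(cfg)
prep = prepare_cohort(inject_missingness(cohort, cfg))

acfg = AnalysisConfig(treatments=TREATMENTS[:2], seed=1, n_boot=500)
res = run_full_analysis(prep, truth, acfg)

print(res.estimates_table[["treatment", "level", "model", "sample", "d",
                           "category"]].to_string(index=False))
print("\nmedian [IQR] of d per outcome level:")
for _, row in res.summary.iterrows():
    print(f"  {row['level']:22s} {row['median_d']:5.2f} "
          f"[{row['iqr_low']:5.2f}, {row['iqr_high']:5.2f}]")
print(f"\nrecovery MAE vs truth: {res.recovery['d_err'].abs().mean():.3f} d units")
# The level-wise medians decay toward zero along the chain: treatment
# effects are largest where the intervention acts (body structures) and
# wash out by the functional-mobility level.
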