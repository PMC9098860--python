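"""Eligibility filtering, questionnaire scoring, and balance metrics.

Shows the preprocessing chain (age/follow-up/varus-valgus filters, FAQt
imputation for near-complete questionnaires, "Miss" encoding) and the raw
treated-vs-control standardized mean differences that motivate matching.
"""

from cpatt import SyntheticConfig, compute_smd, generate_cohort, inject_missingness
from cpatt.pipeline import prepare_cohort

cfg = SyntheticConfig(seed=2)
cohort, _ = generate_cohort(cfg)
cohort = inject_missingness(cohort, cfg)
prep = prepare_cohort(cohort)

print(f"{len(cohort)} limbs generated, {len(prep)} eligible complete cases")
print(f"'Miss' GMFCS level count: {(prep['gmfcs'] == 'Miss').sum()}")

t0 = cfg.treatments[0]
z = prep[f"interval_{t0}"] == 1
print("\nraw covariate imbalance (SMD, treated vs control):")
for c in ("age", "pop_ang_uni", "body_structures_baseline"):
    print(f"  {c:28s} {compute_smd(prep.loc[z, c], prep.loc[~z, c]):.3f}")
print(f"  {'gmfcs (factor)':28s} "
      f"{compute_smd(prep.loc[z, 'gmfcs'], prep.loc[~z, 'gmfcs'], kind='factor'):.3f}")
# Values well above 0.1 show the selection into treatment that a causal
# analysis must remove before differencing outcomes.
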