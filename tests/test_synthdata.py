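"""Generator contracts: ground-truth bookkeeping, targeted selection,
missingness mechanics, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from cpatt import (EffectProfile, LEVELS, SyntheticConfig, TREATMENTS,
                   generate_cohort, inject_missingness)

T0 = TREATMENTS[0]


def test_null_effect_gives_zero_att_everywhere():
    cfg = SyntheticConfig(seed=1, effect_profile=EffectProfile(deltas=(0, 0, 0, 0)))
    _, truth = generate_cohort(cfg)
    for t in cfg.treatments:
        for lv in LEVELS:
            assert truth.att(t, lv) == 0.0


def test_homogeneous_effect_att_is_exact_constant():
    cfg = SyntheticConfig(
        seed=2, effect_profile=EffectProfile(deltas=(0.5, 0.5, 0.5, 0.5),
                                             het_gamma=0.0))
    _, truth = generate_cohort(cfg)
    assert truth.att(T0, "body_structures") == pytest.approx(0.5, abs=1e-12)


def test_att_is_mean_of_individual_effects_over_treated():
    cfg = SyntheticConfig(seed=3)
    cohort, truth = generate_cohort(cfg)
    for lv in LEVELS:
        mask = truth.treated[T0]
        assert truth.att(T0, lv) == pytest.approx(
            truth.tau[T0][lv][mask].mean())


def test_age_heterogeneity_att_matches_large_n_resimulation():
    """tau1(x) = centered age: the realized ATT is the mean centered age of
    treated limbs; a 10x-size re-simulation gives the same population value
    within Monte-Carlo error."""
    def het(df):
        return (df["age"] - df["age"].mean()).to_numpy()

    cfg = SyntheticConfig(seed=1, n_subjects=1000, targeted_selection_strength=2.0,
                          effect_profile=EffectProfile(deltas=(0, 0, 0, 0),
                                                       heterogeneity=het))
    cohort, truth = generate_cohort(cfg)
    # the oracle: direct averaging of tau over treated rows
    z = cohort[f"interval_{T0}"].to_numpy().astype(bool)
    oracle = het(cohort)[z].mean()
    assert truth.att(T0, "body_structures") == pytest.approx(oracle)
    big = SyntheticConfig(seed=99, n_subjects=10000, targeted_selection_strength=2.0,
                          effect_profile=EffectProfile(deltas=(0, 0, 0, 0),
                                                       heterogeneity=het))
    _, truth_big = generate_cohort(big)
    assert truth.att(T0, "body_structures") == pytest.approx(
        truth_big.att(T0, "body_structures"), abs=0.35)
    # targeted selection favors high-benefit (older) limbs
    assert truth_big.att(T0, "body_structures") > 0.5


def test_regeneration_same_seed_is_bit_identical():
    cfg = SyntheticConfig(seed=11)
    c1, t1 = generate_cohort(cfg)
    c2, t2 = generate_cohort(SyntheticConfig(seed=11))
    assert c1.equals(c2)
    for lv in LEVELS:
        assert np.array_equal(t1.tau[T0][lv], t2.tau[T0][lv])
    m1 = inject_missingness(c1, cfg)
    m2 = inject_missingness(c2, cfg)
    assert m1.equals(m2)


def test_targeted_selection_signature():
    """corr(pi, tau1) is ~0 at lambda=0 and clearly positive at lambda>0."""
    prof = EffectProfile(deltas=(0.5, 0.3, 0.2, 0.1), het_gamma=0.5)
    c0 = SyntheticConfig(seed=5, n_subjects=2000,
                         targeted_selection_strength=0.0, effect_profile=prof)
    c2 = SyntheticConfig(seed=5, n_subjects=2000,
                         targeted_selection_strength=2.0, effect_profile=prof)
    _, tr0 = generate_cohort(c0)
    _, tr2 = generate_cohort(c2)
    r0 = np.corrcoef(tr0.pi[T0], tr0.tau[T0]["body_structures"])[0, 1]
    r2 = np.corrcoef(tr2.pi[T0], tr2.tau[T0]["body_structures"])[0, 1]
    assert abs(r0) < 0.05
    assert r2 > 0.3


def test_attenuation_of_true_effects_along_the_chain():
    cfg = SyntheticConfig(seed=6)  # default monotone-decreasing deltas
    _, truth = generate_cohort(cfg)
    atts = [truth.att(T0, lv) for lv in LEVELS]
    assert atts[-1] <= atts[0]
    assert all(a >= b for a, b in zip(atts, atts[1:]))


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        SyntheticConfig(n_subjects=0)
    with pytest.raises(ValueError):
        EffectProfile(deltas=(0.5, 0.3))
    with pytest.raises(ValueError):
        SyntheticConfig(missingness_rates={"gmfcs": 1.5})


class TestInjectMissingness:
    def test_zero_rates_is_identity(self):
        cfg = SyntheticConfig(seed=8, missingness_rates={})
        cohort, _ = generate_cohort(cfg)
        assert inject_missingness(cohort, cfg).equals(cohort)

    def test_rate_one_blanks_whole_column_only(self):
        cfg = SyntheticConfig(seed=8, missingness_rates={"gmfcs": 1.0})
        cohort, _ = generate_cohort(cfg)
        out = inject_missingness(cohort, cfg)
        assert out["gmfcs"].isna().all()
        others = [c for c in cohort.columns if c != "gmfcs"]
        assert out[others].equals(cohort[others])

    def test_blanked_fraction_within_binomial_error(self):
        cfg = SyntheticConfig(seed=9, n_subjects=5000,
                              missingness_rates={"gmfcs": 0.20},
                              severity_dependent_missingness=False)
        cohort, _ = generate_cohort(cfg)
        out = inject_missingness(cohort, cfg)
        n = len(out)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(out["gmfcs"].isna().mean() - 0.20) < 3 * se

    def test_outcomes_never_blanked(self):
        cfg = SyntheticConfig(seed=10)
        cohort, _ = generate_cohort(cfg)
        out = inject_missingness(cohort, cfg)
        for lv in LEVELS:
            assert out[f"{lv}_followup"].notna().all()
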