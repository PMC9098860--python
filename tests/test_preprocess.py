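"""Eligibility filtering, Miss-encoding, FAQt scoring/imputation, and
standardized-mean-difference balance metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpatt import (EligibilityRules, SyntheticConfig, balance_report,
                   compute_faqt, compute_smd, encode_missing_categorical,
                   filter_eligible, generate_cohort, impute_faqt,
                   inject_missingness)
from cpatt.synthdata import DEFAULT_FAQ_WEIGHTS, N_FAQ_ITEMS


def _mini(**kw):
    base = {"age": [10.0], "follow_up_years": [1.5], "kvv_rom": [5.0]}
    base.update(kw)
    return pd.DataFrame(base)


class TestEligibility:
    def test_interior_point_retained(self):
        assert len(filter_eligible(_mini())) == 1

    @pytest.mark.parametrize("col,val", [
        ("follow_up_years", 0.5),    # under nine months
        ("follow_up_years", 2.5),    # thirty months, exclusive bound
        ("age", 25.0),               # must be under 25
        ("kvv_rom", 16.0),           # varus-valgus ROM > 15 degrees
    ])
    def test_violations_removed(self, col, val):
        assert len(filter_eligible(_mini(**{col: [val]}))) == 0

    def test_kvv_boundary_kept(self):
        assert len(filter_eligible(_mini(kvv_rom=[15.0]))) == 1

    def test_idempotent(self):
        df = pd.DataFrame({"age": [10, 30, 12], "follow_up_years": [1, 1, 3.0],
                           "kvv_rom": [5, 5, 5.0]})
        once = filter_eligible(df)
        twice = filter_eligible(once)
        assert once.equals(twice)
        assert once.attrs["removal_counts"]["age"] == 1

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            filter_eligible(pd.DataFrame({"age": [1.0]}))


class TestEncodeMissing:
    def test_blank_categorical_becomes_miss(self):
        df = pd.DataFrame({"gmfcs": ["I", np.nan], "x": [1.0, np.nan]})
        out = encode_missing_categorical(df)
        assert list(out["gmfcs"]) == ["I", "Miss"]
        assert np.isnan(out["x"][1])  # numeric untouched

    def test_no_blanks_is_identity(self):
        df = pd.DataFrame({"gmfcs": ["I", "II"], "x": [1.0, 2.0]})
        assert encode_missing_categorical(df).equals(df)


class TestComputeFaqt:
    def test_constant_items_give_the_constant(self):
        items = np.ones(N_FAQ_ITEMS)
        assert compute_faqt(items, DEFAULT_FAQ_WEIGHTS) == pytest.approx(1.0)

    def test_seventeen_items_is_undefined(self):
        items = np.ones(N_FAQ_ITEMS)
        items[:6] = np.nan  # 17 present < 18 threshold
        assert np.isnan(compute_faqt(items, DEFAULT_FAQ_WEIGHTS))
        items2 = np.ones(N_FAQ_ITEMS)
        items2[:5] = np.nan  # 18 present: defined
        assert not np.isnan(compute_faqt(items2, DEFAULT_FAQ_WEIGHTS))

    def test_two_item_toy_hand_arithmetic(self):
        assert compute_faqt([1.0, 0.0], [2.0, 1.0],
                            min_present=2) == pytest.approx(2.0 / 3.0)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            compute_faqt([1.0, 2.0], DEFAULT_FAQ_WEIGHTS)
        with pytest.raises(ValueError):
            compute_faqt([1.0, 2.0], [1.0, -1.0], min_present=0)


class TestImputeFaqt:
    def test_complete_rows_equal_direct_score_and_are_unaltered(self):
        cfg = SyntheticConfig(seed=21, n_subjects=100)
        cohort, _ = generate_cohort(cfg)
        out = impute_faqt(cohort)
        item_cols = [c for c in cohort.columns if c.startswith("faq_item_")]
        direct = cohort[item_cols].to_numpy() @ DEFAULT_FAQ_WEIGHTS \
            / DEFAULT_FAQ_WEIGHTS.sum()
        np.testing.assert_allclose(
            out["functional_mobility_baseline"].to_numpy(), direct)
        assert out[item_cols].equals(cohort[item_cols])

    def test_rows_below_threshold_stay_missing(self):
        cfg = SyntheticConfig(seed=22, n_subjects=50)
        cohort, _ = generate_cohort(cfg)
        item_cols = [c for c in cohort.columns if c.startswith("faq_item_")]
        cohort.loc[0, item_cols[:6]] = np.nan  # 17 present
        out = impute_faqt(cohort)
        assert np.isnan(out.loc[0, "functional_mobility_baseline"])
        assert out["functional_mobility_baseline"].notna()[1:].all()

    def test_imputation_close_to_restored_complete_data(self):
        """With 20/23 items present, the imputed score tracks the score
        computed after restoring the masked values (oracle), within
        0.1 SD on average."""
        cfg = SyntheticConfig(seed=23, n_subjects=400)
        cohort, _ = generate_cohort(cfg)
        item_cols = [c for c in cohort.columns if c.startswith("faq_item_")]
        complete = cohort[item_cols].to_numpy()
        oracle = complete @ DEFAULT_FAQ_WEIGHTS / DEFAULT_FAQ_WEIGHTS.sum()
        rng = np.random.RandomState(0)
        masked = cohort.copy()
        rows = rng.choice(len(cohort), 150, replace=False)
        for i in rows:
            drop = rng.choice(N_FAQ_ITEMS, 3, replace=False)
            masked.loc[i, [item_cols[j] for j in drop]] = np.nan
        out = impute_faqt(masked)
        err = np.abs(out.loc[rows, "functional_mobility_baseline"].to_numpy()
                     - oracle[rows])
        assert err.mean() <= 0.1 * oracle.std()


class TestComputeSmd:
    def test_identical_groups_zero(self):
        x = np.arange(10.0)
        assert compute_smd(x, x) == 0.0
        f = ["a"] * 5 + ["b"] * 5
        assert compute_smd(f, f, kind="factor") == pytest.approx(0.0)

    def test_unit_mean_gap_unit_sd(self):
        rng = np.random.RandomState(0)
        a = rng.randn(200000) + 1.0
        b = rng.randn(200000)
        assert compute_smd(a, b) == pytest.approx(1.0, abs=0.01)

    def test_factor_matches_hand_coded_matrix_arithmetic(self):
        """3-level factor, proportions T=(.5,.3,.2) vs C=(.4,.4,.2): the
        expected value is computed by explicit 2x2 inversion, independent
        of the implementation."""
        t = ["a"] * 50 + ["b"] * 30 + ["c"] * 20
        c = ["a"] * 40 + ["b"] * 40 + ["c"] * 20
        # hand computation over levels (b, c): d = (-0.1, 0.0)
        pt, pc = np.array([0.3, 0.2]), np.array([0.4, 0.2])
        d = pt - pc
        S = ((np.diag(pt) - np.outer(pt, pt))
             + (np.diag(pc) - np.outer(pc, pc))) / 2
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        expected = float(np.sqrt(d @ Sinv @ d))
        assert compute_smd(t, c, kind="factor") == pytest.approx(expected)

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert compute_smd([1.0, 1.0], [1.0, 1.0]) == 0.0

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=30),
           st.lists(st.floats(-10, 10), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_sign_invariance_continuous(self, a, b):
        got = compute_smd(a, b)
        assert got == pytest.approx(compute_smd(b, a))
        assert got >= 0

    @given(st.lists(st.sampled_from("abc"), min_size=2, max_size=40),
           st.lists(st.sampled_from("abc"), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_factor(self, a, b):
        assert compute_smd(a, b, kind="factor") == pytest.approx(
            compute_smd(b, a, kind="factor"), abs=1e-8)


class TestBalanceReport:
    def test_duplicated_controls_give_perfect_balance(self):
        cfg = SyntheticConfig(seed=24, n_subjects=60)
        cohort, _ = generate_cohort(cfg)
        t = cfg.treatments[0]
        treated = cohort[cohort[f"interval_{t}"] == 1].copy()
        clones = treated.copy()
        clones[f"interval_{t}"] = 0
        clones["limb_id"] = clones["limb_id"] + 100000
        combined = pd.concat([treated, clones], ignore_index=True)
        pairs = list(zip(treated["limb_id"], treated["limb_id"] + 100000))
        rep = balance_report(combined, pairs, {"exam": ["age", "pop_ang_uni"],
                                               "cat": ["gmfcs"]}, t)
        assert (rep.smd["matched"] == 0).all()
        assert (rep.rate_diff[["prior_diff", "interval_diff"]].abs()
                < 1e-12).all().all()

    def test_single_covariate_composition(self):
        cfg = SyntheticConfig(seed=25, n_subjects=80)
        cohort, _ = generate_cohort(cfg)
        t = cfg.treatments[0]
        z = cohort[f"interval_{t}"] == 1
        pairs = list(zip(cohort.loc[z, "limb_id"][:10],
                         cohort.loc[~z, "limb_id"][:10]))
        rep = balance_report(cohort, pairs, {"exam": ["age"]}, t)
        raw = compute_smd(cohort.loc[z, "age"], cohort.loc[~z, "age"])
        assert rep.smd.loc[0, "raw"] == pytest.approx(raw)

    def test_empty_match_set_raises(self):
        cfg = SyntheticConfig(seed=26, n_subjects=20)
        cohort, _ = generate_cohort(cfg)
        with pytest.raises(ValueError):
            balance_report(cohort, [], {"exam": ["age"]}, cfg.treatments[0])
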