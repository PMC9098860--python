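"""Rank-distance construction and the optimal-subset MIP, checked against
exhaustive enumeration on small instances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpatt import MatchSpec, mahalanobis_rank_distance, match_quality, solve_match

# small-instance suite for the exact-optimality check (<= 6 treated,
# <= 8 controls); seeds fixed so the suite is reproducible
SMALL_INSTANCE_SEEDS = list(range(12))


def brute_force_optimum(cost, subset_w):
    """Exhaustive search over all one-to-one assignments and subsets."""
    nt, nc = cost.shape
    best = subset_w * nt  # empty matching
    for k in range(1, min(nt, nc) + 1):
        for tsub in itertools.combinations(range(nt), k):
            for csub in itertools.permutations(range(nc), k):
                obj = (sum(cost[t, c] for t, c in zip(tsub, csub))
                       + subset_w * (nt - k))
                best = min(best, obj)
    return best


class TestRankDistance:
    def test_identical_rows_distance_zero(self):
        Xt = np.array([[1.0, 2.0]])
        Xc = np.array([[1.0, 2.0], [5.0, 7.0]])
        D = mahalanobis_rank_distance(Xt, Xc)
        assert D[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert D[0, 1] > 0

    def test_rank_gap_monotonicity(self):
        D = mahalanobis_rank_distance(np.array([[1.0]]),
                                      np.array([[2.0], [3.0]]))
        assert D[0, 0] < D[0, 1]

    def test_matches_hand_coded_rank_arithmetic(self):
        """2 covariates, 5 pooled rows: compare against an independent
        rank + covariance + quadratic-form computation."""
        Xt = np.array([[1.0, 10.0], [4.0, 40.0]])
        Xc = np.array([[2.0, 20.0], [3.0, 30.0], [5.0, 15.0]])
        pooled = np.vstack([Xt, Xc])
        ranks = np.column_stack([stats.rankdata(pooled[:, j]) for j in range(2)])
        V = np.cov(ranks, rowvar=False)
        Vi = np.linalg.pinv(V)
        expected = np.zeros((2, 3))
        for i in range(2):
            for j in range(3):
                dd = ranks[i] - ranks[2 + j]
                expected[i, j] = np.sqrt(dd @ Vi @ dd)
        got = mahalanobis_rank_distance(Xt, Xc)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_constant_covariate_dropped_with_warning(self):
        Xt = np.array([[1.0, 7.0]])
        Xc = np.array([[2.0, 7.0], [3.0, 7.0]])
        with pytest.warns(UserWarning):
            D = mahalanobis_rank_distance(Xt, Xc)
        assert np.isfinite(D).all()


class TestSolveMatch:
    def test_single_zero_distance_pair_matched(self):
        res = solve_match(np.array([[0.0]]),
                          MatchSpec(distance_covariates=[], subset_weight=1.0))
        assert len(res.pairs) == 1
        assert res.objective == pytest.approx(0.0)
        assert res.status == "optimal"

    def test_zero_subset_weight_empty_matching_is_optimal(self):
        D = np.random.RandomState(0).rand(3, 4) + 0.1
        res = solve_match(D, MatchSpec(distance_covariates=[], subset_weight=0.0))
        assert res.pairs == []

    @pytest.mark.parametrize("seed", SMALL_INSTANCE_SEEDS)
    def test_mip_equals_brute_force_on_small_instances(self, seed):
        rng = np.random.RandomState(seed)
        nt = rng.randint(2, 7)
        nc = rng.randint(3, 9)
        D = rng.rand(nt, nc) * 2
        w = float(np.median(D))
        res = solve_match(D, MatchSpec(distance_covariates=[], subset_weight=w))
        assert res.objective == pytest.approx(brute_force_optimum(D, w))

    def test_near_fine_balance_constraint_binds(self):
        """Two treated with co-flag 1 must pull in flag-1 controls even at
        larger distance."""
        D = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        co_t = pd.DataFrame({"v": [1, 1]})
        co_c = pd.DataFrame({"v": [0, 0, 1]})
        spec = MatchSpec(distance_covariates=[], subset_weight=10.0,
                         near_fine_vars=["v"], near_fine_slack_frac=0.0)
        res = solve_match(D, spec, co_treatment_treated=co_t,
                          co_treatment_control=co_c)
        matched_controls = [int(c) for _, c in res.pairs]
        assert 2 in matched_controls  # the only flag-1 control is used

    def test_duplicate_control_never_raises_objective(self):
        rng = np.random.RandomState(3)
        D = rng.rand(4, 5) + 0.5
        spec = MatchSpec(distance_covariates=[], subset_weight=0.3)
        base = solve_match(D, spec)
        # add a control at distance 0 to treated 0
        D2 = np.column_stack([D, np.array([0.0, 2.0, 2.0, 2.0])])
        better = solve_match(D2, spec)
        assert better.objective <= base.objective + 1e-9

    def test_caliper_penalty_diverts_match(self):
        D = np.zeros((1, 2))
        spec = MatchSpec(distance_covariates=[], subset_weight=5.0,
                         caliper_width=0.2, caliper_penalty=100.0)
        # control 0 violates the propensity caliper, control 1 does not
        res = solve_match(D, spec,
                          propensity_treated=np.array([0.9]),
                          propensity_control=np.array([0.1, 0.88]))
        assert res.pairs[0][1] == 1


class TestMatchQuality:
    def test_empty_matching_errors(self):
        from cpatt.matching import MatchResult
        with pytest.raises(ValueError):
            match_quality(MatchResult(pairs=[], matched_fraction=0,
                                      objective=0, status="optimal"))

    def test_reports_matched_percentage(self):
        res = solve_match(np.array([[0.0]]),
                          MatchSpec(distance_covariates=[], subset_weight=1.0))
        q = match_quality(res)
        assert q["matched_pct"] == 100.0
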