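import itertools
import math

import numpy as np
import pytest
from scipy import stats

from octvf import (
    EvalConfig,
    Pattern,
    bland_altman,
    build_grid,
    compare_groups,
    correlations,
    mae,
    mann_whitney_u,
    pairwise_rmse,
    pointwise_mae_map,
    severity_error_regression,
    severity_strata,
)
from octvf.evaluation import Severity, classify_severity, evaluate_block


def random_instance(seed, n_pairs=None, n_points=None, mask_frac=0.3):
    rng = np.random.default_rng(seed)
    n_pairs = n_pairs or int(rng.integers(1, 8))
    n_points = n_points or int(rng.integers(2, 20))
    p = rng.normal(20, 6, size=(n_pairs, n_points))
    l = rng.normal(20, 6, size=(n_pairs, n_points))
    m = (rng.random((n_pairs, n_points)) < mask_frac).astype(float)
    m[:, 0] = 0  # keep every pair usable
    return p, l, m


class TestPairwiseRMSEAndMAE:
    def test_perfect_prediction_zero(self):
        p = np.full((1, 5), 20.0)
        m = np.zeros_like(p)
        assert pairwise_rmse(p, p, m) == (0.0, 0.0)
        assert mae(p, p, m) == (0.0, 0.0)

    def test_average_of_per_pair_rmse_not_pooled(self):
        # pair RMSEs 3 and 5 -> mean 4 (pooled RMSE would be sqrt(17))
        p = np.array([[3.0, 3.0], [5.0, 5.0]])
        l = np.zeros((2, 2))
        m = np.zeros((2, 2))
        mean, sd = pairwise_rmse(p, l, m)
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(np.std([3.0, 5.0], ddof=1))

    def test_mae_averaging_order(self):
        p = np.array([[1.0, 1.0], [3.0, 3.0]])
        mean, _ = mae(p, np.zeros((2, 2)), np.zeros((2, 2)))
        assert mean == pytest.approx(2.0)

    def test_symmetric_residuals(self):
        p = np.array([[2.0, -2.0]])
        mean, _ = mae(p, np.zeros((1, 2)), np.zeros((1, 2)))
        assert mean == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce(self, seed):
        p, l, m = random_instance(seed)
        rm_vals, ma_vals = [], []
        for pi, li, mi in zip(p, l, m):
            keep = mi == 0
            rm_vals.append(math.sqrt(np.mean((pi[keep] - li[keep]) ** 2)))
            ma_vals.append(np.mean(np.abs(pi[keep] - li[keep])))
        assert pairwise_rmse(p, l, m)[0] == pytest.approx(np.mean(rm_vals), abs=1e-12)
        assert mae(p, l, m)[0] == pytest.approx(np.mean(ma_vals), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_rmse_at_least_mae_per_instance(self, seed):
        p, l, m = random_instance(seed + 100)
        assert pairwise_rmse(p, l, m)[0] >= mae(p, l, m)[0] - 1e-12

    def test_masked_garbage_ignored(self):
        p, l, m = random_instance(7)
        l2 = l.copy()
        l2[m == 1] = 9e9
        assert pairwise_rmse(p, l, m) == pairwise_rmse(p, l2, m)

    def test_all_masked_pair_excluded_with_warning(self):
        p = np.array([[1.0, 1.0], [5.0, 5.0]])
        l = np.zeros((2, 2))
        m = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            mean, _ = pairwise_rmse(p, l, m)
        assert mean == pytest.approx(1.0)


class TestCorrelations:
    def test_identity_perfect(self):
        l = np.arange(10, dtype=float)[None, :]
        r, rho = correlations(l, l, np.zeros_like(l))
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_negation_anti(self):
        l = np.arange(10, dtype=float)[None, :]
        r, rho = correlations(-l, l, np.zeros_like(l))
        assert r == pytest.approx(-1.0) and rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rank_oracle(self, seed):
        p, l, m = random_instance(seed, n_pairs=3, n_points=8)
        keep = m == 0
        r, rho = correlations(p, l, m)
        pk, lk = p[keep], l[keep]
        # Pearson by the closed-form moments
        r_direct = (np.mean(pk * lk) - pk.mean() * lk.mean()) / (pk.std() * lk.std())
        assert r == pytest.approx(r_direct, abs=1e-12)
        # Spearman = Pearson on average ranks
        rank_p = stats.rankdata(pk)
        rank_l = stats.rankdata(lk)
        rho_direct = stats.pearsonr(rank_p, rank_l).statistic
        assert rho == pytest.approx(rho_direct, abs=1e-12)

    def test_zero_variance_errors(self):
        p = np.full((1, 5), 3.0)
        with pytest.raises(ValueError):
            correlations(p, p + 1, np.zeros_like(p))


class TestBlandAltman:
    def test_perfect_agreement(self):
        md = np.array([-1.0, -5.0, -10.0])
        out = bland_altman(md, md)
        assert out == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0,
                       "proportional_r": 0.0}

    def test_closed_form_loa(self):
        est = np.array([1.0, -1.0, 0.0])
        act = np.zeros(3)
        out = bland_altman(est, act)
        sd = np.std(est, ddof=1)
        assert out["bias"] == pytest.approx(0.0)
        assert out["loa_high"] == pytest.approx(1.96 * sd)
        assert out["loa_low"] == pytest.approx(-1.96 * sd)
        assert out["loa_low"] <= out["bias"] <= out["loa_high"]

    def test_constructed_null_proportional_bias(self, rng):
        act = rng.normal(-8, 5, size=400)
        d = np.tile([0.5, -0.5], 200)  # differences independent of magnitude
        out = bland_altman(act + d, act)
        assert abs(out["proportional_r"]) < 0.15

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestSeverity:
    @pytest.mark.parametrize("md,expected", [
        (-5.99, Severity.MILD),
        (-6.0, Severity.MODERATE),   # boundary: MD <= -6 leaves mild
        (-11.99, Severity.MODERATE),
        (-12.0, Severity.SEVERE),
        (0.0, Severity.MILD),
        (-30.0, Severity.SEVERE),
    ])
    def test_boundaries(self, md, expected):
        assert classify_severity(md) is expected

    def test_strata_metrics_partition(self, rng):
        p, l, m = random_instance(3, n_pairs=12, n_points=10, mask_frac=0.0)
        md = rng.uniform(-20, 0, size=12)
        out = severity_strata(p, l, m, md)
        total = sum(v["n"] for v in out.values() if v)
        assert total == 12

    def test_empty_stratum_absent_not_error(self):
        p, l, m = random_instance(4, n_pairs=3, n_points=5, mask_frac=0.0)
        out = severity_strata(p, l, m, np.array([-1.0, -2.0, -3.0]))
        assert out[Severity.SEVERE] is None


class TestPointwiseMap:
    def test_identity_all_zero(self, grid24):
        p = np.full((3, 52), 25.0)
        out = pointwise_mae_map(p, p, np.zeros_like(p), grid24)
        assert len(out) == 52
        assert all(v == 0 for v in out.values())
        assert not set(out) & set(grid24.blind_spot_indices)

    def test_single_point_error_localized(self, grid24):
        p = np.full((2, 52), 25.0)
        l = p.copy()
        l[:, 10] = 22.0
        out = pointwise_mae_map(p, l, np.zeros_like(p), grid24)
        nonzero = [k for k, v in out.items() if v > 0]
        assert len(nonzero) == 1
        assert out[nonzero[0]] == pytest.approx(3.0)

    def test_mean_of_two_samples(self, grid24):
        p = np.full((2, 52), 25.0)
        l = p.copy()
        l[0, 0] = 23.0  # |e| = 2
        l[1, 0] = 21.0  # |e| = 4
        out = pointwise_mae_map(p, l, np.zeros_like(p), grid24)
        first_point = int(grid24.non_blind_indices[0])
        assert out[first_point] == pytest.approx(3.0)

    def test_fully_masked_point_absent(self, grid24):
        p = np.full((2, 52), 25.0)
        m = np.zeros_like(p)
        m[:, 5] = 1
        out = pointwise_mae_map(p, p, m, grid24)
        assert int(build_grid(Pattern.P24_2).non_blind_indices[5]) not in out


def exact_mw_p(a, b):
    """Independent enumeration oracle for the two-sided exact test."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        assert mann_whitney_u([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_capped_at_one(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p_corrected"] == 1.0

    def test_bonferroni_cap(self):
        out = compare_groups([1, 2, 3, 4], [2, 3, 4, 5], EvalConfig(bonferroni_m=6))
        assert out["p_corrected"] == min(1.0, out["p_raw"] * 6)
        assert out["p_corrected"] <= 1.0

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_path_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 7)))
        b = rng.normal(size=int(rng.integers(3, 9)))
        ours = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        assert mann_whitney_u(a, b) == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(1, 6, size=30).astype(float)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert mann_whitney_u(a, b) == pytest.approx(ref)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSeverityErrorRegression:
    def test_exact_parabola(self):
        x = np.array([-1.0, 0.0, 2.0])
        out = severity_error_regression(x, x ** 2)
        assert out["coefficients"] == pytest.approx((0.0, 0.0, 1.0), abs=1e-9)

    def test_constant_errors_error(self):
        with pytest.raises(ValueError):
            severity_error_regression([-1.0, 0.0, 1.0], [2.0, 2.0, 2.0])

    def test_too_few_distinct_x(self):
        with pytest.raises(ValueError):
            severity_error_regression([1.0, 1.0, 2.0], [0.0, 1.0, 2.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.uniform(0, 5, size=10)
        out = severity_error_regression(x, y)
        X = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert out["coefficients"] == pytest.approx(tuple(beta), abs=1e-8)
        assert out["spearman_rho"] == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12)


class TestEvaluateBlock:
    def test_identity_report(self, grid24, rng):
        labels = rng.uniform(5, 30, size=(6, 52))
        md = rng.uniform(-15, 0, size=6)
        rep = evaluate_block(labels, labels, np.zeros_like(labels),
                             md_preds=md, md_labels=md, grid=grid24)
        assert rep.rmse == (0.0, 0.0)
        assert rep.mae == (0.0, 0.0)
        assert rep.md_mae == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.bland_altman_md["bias"] == 0.0
        assert all(v == 0 for v in rep.pointwise_mae.values())
        d = rep.to_dict()
        assert d["n_pairs"] == 6
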