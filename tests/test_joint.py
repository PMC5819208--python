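"""Covariance estimation, the combined statistic, the declaration rule and
inflation diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan.errors import ConfigurationError, InputError
from pleioscan.joint import (
    GWS_PLEIOTROPIC,
    NOT_PLEIOTROPIC,
    PLEIOTROPIC,
    TestCovariance as StatCovariance,
    ZMatrix,
    classify_pleiotropy,
    estimate_covariance,
    genomic_lambda,
    joint_scan,
    obrien_statistic,
    qq_table,
)
from pleioscan.simulate import simulate_z_direct


def _zmatrix(values, traits=None):
    values = np.asarray(values, dtype=float)
    traits = traits or [f"T{k+1}" for k in range(values.shape[1])]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(values.shape[0])],
            "chrom": "1",
            "pos": np.arange(values.shape[0]) * 1000 + 1,
        }
    )
    return ZMatrix(values, snps, traits)


class TestEstimateCovariance:
    def test_identical_columns_give_correlation_one(self, rng):
        col = rng.standard_normal(500)
        cov = estimate_covariance(_zmatrix(np.column_stack([col, col])))
        # off-diagonal equals diagonal up to the tiny PD regularization
        assert cov.sigma[0, 1] == pytest.approx(cov.sigma[0, 0], rel=1e-6)

    def test_independent_pairs_near_zero(self, rng):
        M = 100_000
        cov = estimate_covariance(_zmatrix(rng.standard_normal((M, 2))))
        assert abs(cov.sigma[0, 1]) < 0.01  # ~3/sqrt(M)

    def test_recovers_known_correlation(self, rng):
        M, rho = 100_000, 0.6
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        cov = estimate_covariance(_zmatrix(rng.standard_normal((M, 2)) @ L.T))
        assert cov.sigma[0, 1] == pytest.approx(rho, abs=0.01)

    def test_truncated_mode_drops_extreme_rows(self, rng):
        Z = rng.standard_normal((5000, 2))
        Z[:100] += 8.0  # strong signal rows
        full = estimate_covariance(_zmatrix(Z), mode="all_snps")
        trunc = estimate_covariance(_zmatrix(Z), mode="truncated")
        assert trunc.m_used < full.m_used
        assert abs(trunc.sigma[0, 1]) < abs(full.sigma[0, 1])

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(InputError):
            estimate_covariance(_zmatrix(rng.standard_normal((20, 2))))


class TestObrienStatistic:
    def test_k1_reduces_to_univariate(self):
        assert obrien_statistic([2.0], np.eye(1)) == pytest.approx(2.0)

    def test_orthonormal_case(self):
        t = obrien_statistic([1.96, 1.96], np.eye(2))
        assert t == pytest.approx(3.92 / math.sqrt(2), rel=1e-12)

    def test_equicorrelated_published_style_example(self):
        # z back-transformed from univariate p's 2.3e-5 / 9.1e-6 is ~(4.24, 4.44);
        # with the rounder z = (4.95, 4.60) and rho = 0.68:
        sigma = np.array([[1.0, 0.68], [0.68, 1.0]])
        t_gls = obrien_statistic([4.95, 4.60], sigma, weights="gls")
        t_eq = obrien_statistic([4.95, 4.60], sigma, weights="equal")
        assert t_gls == pytest.approx(9.55 / math.sqrt(3.36), rel=1e-10)
        assert t_gls == pytest.approx(t_eq, abs=1e-10)  # weightings coincide

    def test_scale_equivariance_of_gls(self, rng):
        # T(c * Sigma) = T(Sigma) / sqrt(c): an overall covariance scale shifts
        # the statistic deterministically, and cancels entirely when Sigma is
        # estimated from the Z matrix itself (unit-variance diagonal)
        A = rng.standard_normal((3, 3))
        sigma = A @ A.T + 3 * np.eye(3)
        z = rng.standard_normal(3)
        t1 = obrien_statistic(z, sigma)
        t2 = obrien_statistic(z, 17.3 * sigma)
        assert t2 == pytest.approx(t1 / math.sqrt(17.3), rel=1e-12)

    def test_matches_dense_inverse_oracle(self, rng):
        for _ in range(100):
            K = int(rng.integers(1, 5))
            A = rng.standard_normal((K, K))
            sigma = A @ A.T + K * np.eye(K)
            z = rng.standard_normal(K)
            ones = np.ones(K)
            inv = np.linalg.inv(sigma)
            expected = (ones @ inv @ z) / math.sqrt(ones @ inv @ ones)
            assert obrien_statistic(z, sigma) == pytest.approx(expected, abs=1e-10)


class TestJointScan:
    def test_rowwise_consistency(self, rng):
        Z = _zmatrix(rng.standard_normal((50, 3)))
        sigma = StatCovariance(np.eye(3) + 0.3, Z.traits, "all_snps", 50)
        res = joint_scan(Z, sigma, ["T1", "T2"])
        sub = sigma.restrict(["T1", "T2"])
        for i in [0, 17, 49]:
            expect = obrien_statistic(Z.values[i, :2], sub)
            assert res["T_joint"].iloc[i] == pytest.approx(expect, rel=1e-12)

    def test_singleton_subset_reduces_to_univariate(self, rng):
        Z = _zmatrix(rng.standard_normal((40, 2)))
        sigma = StatCovariance(np.eye(2), Z.traits, "all_snps", 40)
        res = joint_scan(Z, sigma, ["T2"])
        np.testing.assert_allclose(res["p_joint"], res["p_T2"], rtol=1e-12)

    def test_null_calibration(self, rng):
        M = 20_000
        Z, _ = simulate_z_direct(M, np.eye(2), seed=rng)
        sigma = estimate_covariance(Z)
        res = joint_scan(Z, sigma)
        frac = (res["p_joint"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / M)

    def test_unknown_trait_is_config_error(self, rng):
        Z = _zmatrix(rng.standard_normal((40, 2)))
        sigma = StatCovariance(np.eye(2), Z.traits, "all_snps", 40)
        with pytest.raises(ConfigurationError):
            joint_scan(Z, sigma, ["T1", "XX"])
        with pytest.raises(ConfigurationError):
            joint_scan(Z, sigma, ["T1", "T1"])


class TestClassifyPleiotropy:
    @pytest.mark.parametrize(
        "p_joint,p_univ,expected",
        [
            (1.1e-8, [2.3e-5, 9.1e-6], GWS_PLEIOTROPIC),
            (2.5e-6, [7.7e-7, 0.06], NOT_PLEIOTROPIC),
            (1e-9, [0.5, 1e-10], NOT_PLEIOTROPIC),
            (1e-6, [1e-4, 1e-3], PLEIOTROPIC),  # order of magnitude but not GWS
            (4.9e-8, [4.9e-6, 4.9e-6], GWS_PLEIOTROPIC),
            (1e-3, [9.99e-3, 2e-2], NOT_PLEIOTROPIC),  # fails the factor-10 rule
        ],
    )
    def test_declaration_rule(self, p_joint, p_univ, expected):
        assert classify_pleiotropy(p_joint, p_univ) == expected

    def test_boundary_is_nonstrict(self):
        # exactly-representable p's so p_joint == p_univ/10 holds bit-for-bit
        assert classify_pleiotropy(0.003125, [0.03125, 0.03125]) == PLEIOTROPIC

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            classify_pleiotropy(0.0, [0.5])


class TestGenomicLambda:
    def test_null_median(self):
        assert genomic_lambda([0.5] * 101) == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_scaling(self):
        # p whose 1-df chi-square quantile is exactly twice the null median
        p = float(stats.chi2.sf(2 * stats.chi2.ppf(0.5, 1), df=1))
        assert genomic_lambda([p] * 11) == pytest.approx(2.0, rel=1e-10)

    def test_exclusion_region_noop_when_empty(self, rng):
        p = rng.uniform(0.01, 1, 500)
        chrom = np.repeat("1", 500)
        pos = np.arange(500) * 100
        lam0 = genomic_lambda(p)
        lam1 = genomic_lambda(p, chrom, pos, exclude_region=("19", 0, 10**9))
        assert lam0 == pytest.approx(lam1)

    def test_exclusion_region_removes_inflated_snps(self, rng):
        p = np.concatenate([rng.uniform(0.01, 1, 5000), np.full(500, 1e-8)])
        chrom = np.array(["1"] * 5000 + ["19"] * 500)
        pos = np.concatenate([np.arange(5000), 44_500_000 + np.arange(500)])
        lam_all = genomic_lambda(p)
        lam_ex = genomic_lambda(p, chrom, pos, exclude_region=("19", 44_400_000, 46_500_000))
        assert lam_ex < lam_all

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            genomic_lambda([])


class TestQQTable:
    def test_single_point(self):
        t = qq_table([0.5])
        assert t["expected_neglog10p"].iloc[0] == pytest.approx(0.3010, abs=1e-4)
        assert t["observed_neglog10p"].iloc[0] == pytest.approx(0.3010, abs=1e-4)

    def test_uniform_ps_stay_near_diagonal(self, rng):
        t = qq_table(rng.uniform(size=5000))
        gap = np.abs(
            10 ** -t["observed_neglog10p"] - 10 ** -t["expected_neglog10p"]
        ).max()
        assert gap < 1.95 / math.sqrt(5000)  # Kolmogorov 99.9% band

    def test_duplicates_kept(self):
        t = qq_table([0.5, 0.5, 0.1])
        assert len(t) == 3
        assert t["observed_neglog10p"].is_monotonic_decreasing
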