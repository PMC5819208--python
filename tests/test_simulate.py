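"""Generator properties: LD structure, trait correlations, ground truth,
determinism, and the direct-Z fast path."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan.errors import InputError
from pleioscan.joint import estimate_covariance, joint_scan
from pleioscan.simulate import (
    DEFAULT_TARGET_CORR,
    TRAIT_NAMES,
    fit_sumstats,
    latent_corr_for_target,
    simulate_expression,
    simulate_genotypes,
    simulate_study,
    simulate_traits,
    simulate_z_direct,
    write_vcf,
)


class TestSimulateGenotypes:
    def test_independent_blocks_uncorrelated(self):
        n = 5000
        X, _ = simulate_genotypes(n, 40, rho_within=0.0, seed=3)
        r = np.corrcoef(X, rowvar=False)
        adj = np.abs(np.diag(r, k=1))
        assert adj.max() < 3 / np.sqrt(n) + 0.02

    def test_strong_ld_within_blocks(self):
        # moderate common MAFs so thresholding attenuation is the only loss;
        # latent AR(1) at 0.9 then keeps adjacent dosage correlation above 0.6
        X, snp_map = simulate_genotypes(
            5000, 40, rho_within=0.9, block_size=20, maf_range=(0.2, 0.4), seed=4
        )
        r = np.corrcoef(X, rowvar=False)
        same_block = np.diff(snp_map["block"]) == 0
        adj = np.diag(r, k=1)[same_block]
        assert adj.min() > 0.6

    def test_sample_maf_matches_drawn_maf(self):
        X, snp_map = simulate_genotypes(5000, 60, seed=5)
        realized = X.mean(axis=0) / 2
        assert np.abs(realized - snp_map["maf"]).max() < 0.02 + 3 * np.sqrt(
            0.25 / (2 * 5000)
        )

    def test_deterministic_given_seed(self):
        X1, m1 = simulate_genotypes(100, 30, seed=7)
        X2, m2 = simulate_genotypes(100, 30, seed=7)
        assert np.array_equal(X1, X2)
        pd.testing.assert_frame_equal(m1, m2)


class TestLatentCalibration:
    @pytest.mark.parametrize("target", [0.68, 0.56, 0.40])
    def test_latent_exceeds_target(self, target):
        cuts = stats.norm.ppf([0.15, 0.35, 0.65])
        latent = latent_corr_for_target(target, cuts, stats.norm.ppf([0.5]))
        assert latent > target  # thresholding always attenuates

    def test_realized_score_correlations_hit_targets(self):
        X, _ = simulate_genotypes(4000, 20, seed=1)
        pheno, _ = simulate_traits(X, np.zeros((20, 3)), seed=2)
        got = np.corrcoef(pheno[list(TRAIT_NAMES)].T.astype(float))
        assert np.abs(got - DEFAULT_TARGET_CORR).max() < 0.05

    def test_case_enrichment(self):
        X, _ = simulate_genotypes(4000, 20, seed=1)
        pheno, _ = simulate_traits(X, np.zeros((20, 3)), seed=2)
        assert (pheno["status"] == "AD").mean() == pytest.approx(0.87, abs=0.02)


class TestSimulateTraits:
    def test_single_trait_effect_is_trait_specific(self):
        """A SNP affecting only NP shifts NP-stratified dosage means, not NFT's."""
        rng = np.random.default_rng(12)
        np_hits, nft_hits = 0, 0
        for rep in range(20):
            X, _ = simulate_genotypes(1500, 10, seed=100 + rep)
            eff = np.zeros((10, 3))
            eff[0, 0] = 0.35  # NP only
            pheno, _ = simulate_traits(X, eff, seed=200 + rep)
            for trait, bucket in (("NP", "np"), ("NFT", "nft")):
                lo = X[pheno[trait] <= 1, 0]
                hi = X[pheno[trait] >= 2, 0]
                p = stats.ttest_ind(lo, hi, equal_var=False).pvalue
                if p < 0.01:
                    if trait == "NP":
                        np_hits += 1
                    else:
                        nft_hits += 1
        assert np_hits >= 15
        # the SNP enters only the NP liability; NFT stratification should flag
        # at roughly the 1% false-positive rate
        assert nft_hits <= 4

    def test_degenerate_cutpoints_rejected_by_fitter(self):
        # infinite cutpoints give a single-level trait; the generator emits
        # it and the downstream fitter refuses to fit
        X, snp_map = simulate_genotypes(200, 5, seed=1)
        cuts = {"NP": np.array([np.inf] * 3), "NFT": stats.norm.ppf([0.1, 0.3, 0.65]),
                "CAA": stats.norm.ppf([0.5])}
        pheno, _ = simulate_traits(X, np.zeros((5, 3)), thresholds=cuts, seed=2)
        assert pheno["NP"].nunique() == 1
        with pytest.raises(InputError, match="single level"):
            fit_sumstats(X, pheno, snp_map)

    def test_non_pd_residual_corr_rejected(self):
        X, _ = simulate_genotypes(200, 5, seed=1)
        bad = np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1]])
        with pytest.raises(InputError):
            simulate_traits(X, np.zeros((5, 3)), residual_corr=bad, seed=2)


class TestFitSumstats:
    def test_tables_complete_and_monomorphic_dropped(self):
        study = simulate_study(n=400, M=60, seed=3, block_size=10)
        study.dosages[:, 5] = 0.0  # force monomorphic
        stats_by_trait, report = fit_sumstats(
            study.dosages, study.phenotypes, study.snp_map
        )
        assert set(stats_by_trait) == set(TRAIT_NAMES)
        assert report["n_monomorphic"] == 1
        for ss in stats_by_trait.values():
            assert "snp000005" not in set(ss.records["snp_id"])
            assert (ss.records["se"] > 0).all()

    def test_null_binary_betas_centered(self):
        study = simulate_study(n=1000, M=80, seed=4, block_size=10)
        stats_by_trait, _ = fit_sumstats(study.dosages, study.phenotypes, study.snp_map)
        caa = stats_by_trait["CAA"].records
        zbar = (caa["beta"] / caa["se"]).mean()
        assert abs(zbar) < 3 / np.sqrt(len(caa))


class TestSimulateZDirect:
    def test_covariance_recovered(self):
        sigma = np.array([[1.0, 0.4], [0.4, 1.0]])
        Z, _ = simulate_z_direct(100_000, sigma, seed=6)
        est = estimate_covariance(Z)
        assert np.abs(est.sigma - sigma).max() < 0.015

    def test_seed_reproducibility(self):
        sigma = np.eye(3)
        Z1, m1 = simulate_z_direct(500, sigma, signal_fraction=0.1, signal_size=3, seed=9)
        Z2, m2 = simulate_z_direct(500, sigma, signal_fraction=0.1, signal_size=3, seed=9)
        assert np.array_equal(Z1.values, Z2.values)
        assert np.array_equal(m1, m2)

    def test_joint_beats_univariate_on_shared_signal(self):
        """For SNPs affecting both traits, the joint p is stochastically
        smaller than either univariate p (median over 1000 signal SNPs)."""
        rho = 0.4
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        Z, mask = simulate_z_direct(
            50_000, sigma, signal_fraction=0.02, signal_size=4.0, seed=10
        )
        # covariance from a matched null draw, so the dense signal block of
        # this stress test does not inflate the between-trait estimate
        Z_null, _ = simulate_z_direct(50_000, sigma, seed=11)
        est = estimate_covariance(Z_null)
        res = joint_scan(Z, est)
        sig = res[mask]
        best_univ = np.minimum(sig["log10p_T1"], sig["log10p_T2"])
        assert (sig["log10p_joint"] < best_univ).mean() > 0.5
        # power at the genome-wide threshold
        pow_joint = (sig["p_joint"] < 5e-8).mean()
        pow_univ = (sig[["p_T1", "p_T2"]].min(axis=1) < 5e-8).mean()
        assert pow_joint > pow_univ

    def test_trivariate_attenuated_when_only_two_traits_carry_signal(self):
        """With signal on 2 of 3 traits, the trivariate joint p is typically
        larger (less significant) than the best bivariate p."""
        sigma = np.eye(3) * 0.6 + 0.4
        Z, mask = simulate_z_direct(
            30_000, sigma, signal_fraction=0.02, signal_size=4.0,
            signal_traits=[0, 1], seed=13,
        )
        est = estimate_covariance(Z)
        tri = joint_scan(Z, est)[np.asarray(mask)]
        bi = joint_scan(Z, est, ["T1", "T2"])[np.asarray(mask)]
        assert np.median(tri["log10p_joint"]) > np.median(bi["log10p_joint"])


class TestSimulateExpression:
    def test_truth_ledger_and_determinism(self):
        s1, t1 = simulate_expression(
            n_genes=20, n_samples=60, dge_effects={"gene0003": -0.3},
            eqtl_effects={"gene0005": (0.3, -0.25)}, seed=21,
        )
        s2, _ = simulate_expression(
            n_genes=20, n_samples=60, dge_effects={"gene0003": -0.3},
            eqtl_effects={"gene0005": (0.3, -0.25)}, seed=21,
        )
        pd.testing.assert_frame_equal(s1.expression, s2.expression)
        assert t1["dge"] == {"gene0003": -0.3}
        assert t1["eqtl"]["gene0005"]["snp_id"] in s1.dosages

    def test_study_roundtrip_through_files(self, tmp_path):
        study, _ = simulate_expression(n_genes=5, n_samples=30, seed=2)
        study.write(tmp_path / "e.tsv", tmp_path / "c.tsv")
        from pleioscan.expression import ExpressionStudy

        back = ExpressionStudy.read(tmp_path / "e.tsv", tmp_path / "c.tsv")
        assert back.markers is not None
        np.testing.assert_allclose(back.expression, study.expression, rtol=1e-9)


class TestStudySerialization:
    def test_save_writes_pipeline_inputs(self, tmp_path):
        study = simulate_study(n=50, M=20, seed=5, block_size=5)
        study.save(tmp_path)
        for name in ("dosages.tsv", "snp_map.tsv", "phenotypes.tsv",
                     "causal_effects.tsv", "truth.json"):
            assert (tmp_path / name).exists()

    def test_vcf_roundtrip(self, tmp_path):
        pytest.importorskip("cyvcf2")
        from pleioscan.genebased import dosages_from_vcf

        study = simulate_study(n=30, M=12, seed=6, block_size=4)
        path = tmp_path / "panel.vcf"
        write_vcf(path, study.dosages, study.snp_map)
        snps, X = dosages_from_vcf(path)
        order = {s: i for i, s in enumerate(snps["snp_id"])}
        cols = [order[s] for s in study.snp_map["snp_id"]]
        np.testing.assert_allclose(X[:, cols], study.dosages)
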