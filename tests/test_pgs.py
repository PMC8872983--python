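"""Genomics: GRM against a double-loop oracle, greedy pruning
post-conditions, REML against a brute-force restricted likelihood, the
infinitesimal shrinkage closed form, and incremental-R2 identities."""

import numpy as np
import pandas as pd
import pytest

from psychgen._types import GenotypeMatrix
from psychgen.pgs import (
    Grm,
    combine_scores,
    compute_grm,
    greml,
    ldpred_inf,
    polygenic_score,
    prune_related,
    score_and_r2,
)
from psychgen.simulate import GenoSimSpec, gen_genotypes_phenotype, gen_sumstats


def _geno(dosages, freq=None):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chrom": 1, "pos": np.arange(1, m + 1),
        "a1": "A", "a2": "G",
        "freq": freq if freq is not None else dosages.mean(axis=0) / 2,
    })
    return GenotypeMatrix(ids=[f"i{k}" for k in range(n)], snps=snps,
                          dosages=dosages)


class TestGrm:
    def test_single_snp_closed_form(self):
        # p = 0.5; x_j = 2, x_k = 0 -> A_jk = (2-1)(0-1)/0.5 = -2
        g = _geno([[2.0], [0.0], [1.0], [1.0]])
        grm = compute_grm(g, maf_min=0.0)
        assert grm.matrix[0, 1] == pytest.approx(-2.0)

    def test_matches_double_loop_oracle(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=8, m_snps=60,
                                                  h2_snp=0.3, seed=1))
        grm = compute_grm(sim.genotypes, maf_min=0.0)
        dose = sim.genotypes.dosages
        p = dose.mean(axis=0) / 2
        poly = [i for i in range(dose.shape[1]) if 0 < p[i] < 1]
        for j in range(8):
            for k in range(8):
                acc = 0.0
                for i in poly:
                    acc += ((dose[j, i] - 2 * p[i]) * (dose[k, i] - 2 * p[i])
                            / (2 * p[i] * (1 - p[i])))
                assert grm.matrix[j, k] == pytest.approx(acc / len(poly),
                                                         abs=1e-10)

    def test_duplicate_individual(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=6, m_snps=100,
                                                  h2_snp=0.0, seed=2))
        dose = sim.genotypes.dosages.copy()
        dose[1] = dose[0]
        grm = compute_grm(_geno(dose))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-10)

    def test_mean_diagonal_near_one(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=300,
                                                  m_snps=5000, h2_snp=0.0,
                                                  seed=3))
        grm = compute_grm(sim.genotypes)
        assert np.diag(grm.matrix).mean() == pytest.approx(1.0, abs=0.02)


class TestPruning:
    def test_identity_grm_all_retained(self):
        grm = Grm(ids=list("abcd"), matrix=np.eye(4),
                  n_snps=np.full((4, 4), 10))
        assert prune_related(grm) == list("abcd")

    def test_single_related_pair_drops_one(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.5
        grm = Grm(ids=list("abc"), matrix=m, n_snps=np.full((3, 3), 10))
        kept = prune_related(grm, 0.05)
        assert len(kept) == 2
        assert "c" in kept

    def test_family_blocks_postcondition(self):
        rng = np.random.default_rng(4)
        n = 60
        m = 0.01 * rng.standard_normal((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        # plant three family blocks of relatedness 0.25
        for start in (0, 10, 30):
            for j in range(start, start + 5):
                for k in range(start, j):
                    m[j, k] = m[k, j] = 0.25
        grm = Grm(ids=[f"i{k}" for k in range(n)], matrix=m,
                  n_snps=np.full((n, n), 10))
        kept = prune_related(grm, 0.05)
        idx = [grm.ids.index(i) for i in kept]
        sub = m[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.05


class TestGreml:
    def test_null_phenotype(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=500,
                                                  m_snps=2000, h2_snp=0.0,
                                                  seed=5))
        grm = compute_grm(sim.genotypes)
        res = greml(sim.phenotype, grm)
        assert res.h2 <= 2 * res.se_h2 + 0.02

    def test_matches_grid_search_oracle(self):
        """AI-REML solution maximizes the restricted likelihood computed by
        direct dense linear algebra on a 30-individual fixture."""
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=30,
                                                  m_snps=200, h2_snp=0.5,
                                                  seed=6))
        grm = compute_grm(sim.genotypes)
        res = greml(sim.phenotype, grm)

        y = sim.phenotype.to_numpy()
        y = (y - y.mean()) / y.std()
        x = np.ones((30, 1))
        a = grm.matrix

        def reml_ll(sg, se):
            v = sg * a + se * np.eye(30)
            vi = np.linalg.inv(v)
            xvx = x.T @ vi @ x
            beta = np.linalg.solve(xvx, x.T @ vi @ y)
            r = y - x @ beta
            return -0.5 * (np.linalg.slogdet(v)[1]
                           + np.linalg.slogdet(xvx)[1]
                           + r @ vi @ r)

        grid = np.linspace(0.01, 2.0, 120)
        lls = np.array([[reml_ll(sg, se) for se in grid] for sg in grid])
        j, k = np.unravel_index(lls.argmax(), lls.shape)
        # the fitted point must beat or match the best grid point
        assert reml_ll(res.sigma2_g, res.sigma2_e) >= lls.max() - 1e-6
        assert res.h2 == pytest.approx(grid[j] / (grid[j] + grid[k]),
                                       abs=0.05)

    def test_recovery_at_moderate_scale(self):
        h2s = []
        for seed in range(3):
            sim = gen_genotypes_phenotype(
                GenoSimSpec(n_individuals=800, m_snps=3000, h2_snp=0.4,
                            seed=100 + seed))
            grm = compute_grm(sim.genotypes)
            h2s.append(greml(sim.phenotype, grm).h2)
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.12)

    def test_covariates_absorbed(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=400,
                                                  m_snps=1500, h2_snp=0.4,
                                                  seed=7))
        rng = np.random.default_rng(8)
        cov = rng.standard_normal((400, 2))
        y = sim.phenotype + cov @ np.array([0.5, -0.3])
        grm = compute_grm(sim.genotypes)
        res = greml(y, grm, covariates=cov)
        assert 0.0 <= res.h2 <= 1.0


class TestLdpredInf:
    def test_no_ld_closed_form_shrinkage(self):
        """With D = I the posterior mean is uniform shrinkage
        beta / (1 + M/(N h2)); M = N = 1000, h2 = 0.5 gives factor 1/3."""
        m, n_ind = 1000, 8000
        rng = np.random.default_rng(9)
        # build genotypes with essentially independent SNPs
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=n_ind,
                                                  m_snps=m, h2_snp=0.5,
                                                  seed=9))
        ss = gen_sumstats(sim.effects, sim.genotypes.snps, n_gwas=1000, seed=9)
        w = ldpred_inf(ss, sim.genotypes, h2=0.5, n_gwas=1000, window=m)
        shrunk = ss["BETA"].to_numpy() / 3.0
        # empirical D deviates from I by sampling noise only
        np.testing.assert_allclose(w["beta_std"], shrunk, atol=0.012)

    def test_exact_identity_ld_solve(self):
        """A genotype panel with exactly orthogonal SNP columns (Hadamard
        design) yields the closed-form uniform shrinkage to machine
        precision."""
        from scipy.linalg import hadamard

        m = 50
        rng = np.random.default_rng(10)
        beta_hat = rng.standard_normal(m) * 0.05
        h = hadamard(64)
        dose = (h[:, 1:m + 1] + 1.0)  # {0, 2} dosages, exactly orthogonal
        geno = _geno(dose)
        ss = pd.DataFrame({"SNP": geno.snps["snp"], "A1": "A", "A2": "G",
                           "BETA": beta_hat, "SE": 0.01, "N": 500,
                           "FREQ": geno.snps["freq"]})
        w = ldpred_inf(ss, geno, h2=0.5, n_gwas=500, window=m)
        expected = beta_hat / (1.0 + m / (500 * 0.5))
        np.testing.assert_allclose(w["beta_std"], expected, atol=1e-10)

    def test_windowed_matches_full_solve_on_blocks(self):
        """With LD confined to blocks smaller than the window, the sliding
        solver agrees with the whole-matrix solve up to the sampling noise
        in cross-block correlations (which only the full solve sees)."""
        sim = gen_genotypes_phenotype(
            GenoSimSpec(n_individuals=12000, m_snps=120, h2_snp=0.5,
                        ld_block_size=20, ld_rho=0.7, seed=11))
        ss = gen_sumstats(sim.effects, sim.genotypes.snps, n_gwas=5000, seed=11)
        w_full = ldpred_inf(ss, sim.genotypes, h2=0.5, n_gwas=5000, window=120)
        w_win = ldpred_inf(ss, sim.genotypes, h2=0.5, n_gwas=5000,
                           window=40, overlap=20)
        np.testing.assert_allclose(w_win["beta_std"], w_full["beta_std"],
                                   atol=0.02)
        r = np.corrcoef(w_win["beta_std"], w_full["beta_std"])[0, 1]
        assert r > 0.99

    def test_infinite_h2_limit_no_shrinkage(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=4000,
                                                  m_snps=60, h2_snp=0.5,
                                                  seed=12))
        ss = gen_sumstats(sim.effects, sim.genotypes.snps, n_gwas=1000, seed=12)
        w = ldpred_inf(ss, sim.genotypes, h2=1e9, n_gwas=1000, window=60)
        dose = sim.genotypes.dosages
        d = (dose - dose.mean(axis=0)) / dose.std(axis=0)
        ld = d.T @ d / len(d)
        expected = np.linalg.solve(ld, ss["BETA"].to_numpy())
        np.testing.assert_allclose(w["beta_std"], expected, rtol=1e-4)

    def test_invalid_h2_rejected(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=10, m_snps=5,
                                                  seed=13))
        ss = gen_sumstats(sim.effects, sim.genotypes.snps, n_gwas=100, seed=13)
        with pytest.raises(ValueError, match="h2"):
            ldpred_inf(ss, sim.genotypes, h2=0.0, n_gwas=100)


class TestScoring:
    def test_zero_weights_zero_r2(self):
        sim = gen_genotypes_phenotype(GenoSimSpec(n_individuals=200,
                                                  m_snps=50, h2_snp=0.5,
                                                  seed=14))
        w = pd.DataFrame({"SNP": sim.genotypes.snps["snp"],
                          "beta_dose": 0.0})
        score = polygenic_score(sim.genotypes, w)
        res = score_and_r2(sim.phenotype, score)
        assert res["delta_r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_delta_r2_equals_squared_correlation_without_covariates(self):
        rng = np.random.default_rng(15)
        y = rng.standard_normal(500)
        gps = 0.3 * y + rng.standard_normal(500)
        res = score_and_r2(pd.Series(y), pd.Series(gps, name="gps"))
        assert res.loc["gps", "delta_r2"] == pytest.approx(
            np.corrcoef(y, gps)[0, 1] ** 2, abs=1e-10)

    def test_delta_r2_nonnegative_with_covariates(self):
        rng = np.random.default_rng(16)
        y = rng.standard_normal(400)
        cov = pd.DataFrame(rng.standard_normal((400, 3)))
        gps = rng.standard_normal(400)
        res = score_and_r2(pd.Series(y), pd.Series(gps, name="gps"), cov)
        assert res.loc["gps", "delta_r2"] >= 0.0

    def test_multi_score_combination_improves_or_matches(self):
        rng = np.random.default_rng(17)
        n = 3000
        g = rng.standard_normal(n)
        y = 0.5 * g + np.sqrt(0.75) * rng.standard_normal(n)
        scores = pd.DataFrame({
            "s1": 0.6 * g + 0.8 * rng.standard_normal(n),
            "s2": 0.5 * g + 0.9 * rng.standard_normal(n),
            "s3": 0.4 * g + 0.9 * rng.standard_normal(n),
        })
        out = combine_scores(pd.Series(y), scores, seed=17)
        single = score_and_r2(pd.Series(y), scores)["delta_r2"].max()
        assert out["holdout"]["delta_r2"] > 0.5 * single
        assert set(out["weights"]) == {"s1", "s2", "s3"}
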