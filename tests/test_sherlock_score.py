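import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triagene import (SherlockPriors, detect_esnps, score_gene,
                      sherlock_analysis, simulated_p, snp_log10_bf)


def esnp_frame(rows):
    return pd.DataFrame(rows, columns=["SNP", "GENE", "EQTL_P", "TYPE", "GWAS_P"])


class TestSnpLog10Bf:
    def test_zero_z_closed_form(self):
        # p = 1 gives z = 0: log10 BF = 0.5*log10(1/(1+W))
        assert snp_log10_bf(1.0, W=0.1) == pytest.approx(
            0.5 * np.log10(1 / 1.1), abs=1e-12)

    def test_z_five_closed_form(self):
        p = 2 * stats.norm.sf(5.0)
        expected = 0.5 * np.log10(1 / 1.1) + 12.5 * (0.1 / 1.1) * np.log10(np.e)
        assert snp_log10_bf(p, W=0.1) == pytest.approx(expected, rel=1e-10)
        assert snp_log10_bf(p, W=0.1) == pytest.approx(0.473, abs=5e-4)

    def test_w_to_zero_collapses_to_null(self):
        for p in (1e-8, 0.01, 0.5, 1.0):
            assert abs(snp_log10_bf(p, W=1e-12)) < 1e-9

    def test_strictly_decreasing_in_p(self):
        ps = np.logspace(-10, 0, 40)
        bf = snp_log10_bf(ps, W=0.1)
        assert np.all(np.diff(bf) < 0)

    def test_p_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            v = snp_log10_bf(0.0, W=0.1)
        assert np.isfinite(v) and v > 0

    def test_p_above_one_rejected(self):
        with pytest.raises(ValueError):
            snp_log10_bf(1.5)


class TestScoreGene:
    priors = SherlockPriors()

    def test_additivity(self):
        one = esnp_frame([("rs1", "G", 1e-8, "cis", 0.01)])
        two = esnp_frame([("rs2", "G", 1e-8, "trans", 0.3)])
        both = pd.concat([one, two], ignore_index=True)
        assert score_gene(both, self.priors) == pytest.approx(
            score_gene(one, self.priors) + score_gene(two, self.priors), abs=1e-12)

    def test_cis_exceeds_trans_by_prior_odds(self):
        cis = esnp_frame([("rs1", "G", 1e-8, "cis", 0.02)])
        trans = esnp_frame([("rs1", "G", 1e-8, "trans", 0.02)])
        a_c, a_t = self.priors.alpha_cis, self.priors.alpha_trans
        expected = np.log10(a_c * (1 - a_t) / (a_t * (1 - a_c)))
        diff = score_gene(cis, self.priors) - score_gene(trans, self.priors)
        assert diff == pytest.approx(expected, abs=1e-12)
        assert diff == pytest.approx(1.301, abs=2e-3)

    def test_empty_esnp_list_gives_no_score(self):
        with pytest.raises(ValueError):
            score_gene(esnp_frame([]), self.priors)

    def test_monotone_in_gwas_p(self):
        # decreasing any eSNP's GWAS p never decreases the gene score
        base = esnp_frame([("rs1", "G", 1e-8, "cis", 0.4),
                           ("rs2", "G", 1e-7, "trans", 0.2)])
        better = base.copy()
        better.loc[1, "GWAS_P"] = 0.001
        assert score_gene(better, self.priors) > score_gene(base, self.priors)


class TestDetectEsnps:
    priors = SherlockPriors(esnp_threshold=1e-5)
    gwas = pd.DataFrame({"SNP": ["rs1", "rs2"], "CHR": "1", "BP": [1, 2],
                         "P": [0.01, 0.5]})

    def test_single_passthrough(self):
        eqtl = pd.DataFrame({"SNP": ["rs1"], "GENE": ["geneA"], "P": [1e-8],
                             "TYPE": ["cis"]})
        out = detect_esnps(eqtl, self.gwas, self.priors)
        assert len(out) == 1
        assert out.loc[0, "GWAS_P"] == 0.01

    def test_threshold_boundary(self):
        eqtl = pd.DataFrame({"SNP": ["rs1", "rs2"], "GENE": ["a", "b"],
                             "P": [1e-4, 1e-5], "TYPE": ["cis", "cis"]})
        out = detect_esnps(eqtl, self.gwas, self.priors)
        assert out["GENE"].tolist() == ["b"]  # 1e-4 excluded, 1e-5 kept

    def test_unmatched_esnp_dropped_and_counted(self):
        eqtl = pd.DataFrame({"SNP": ["rs1", "rs_missing"], "GENE": ["a", "a"],
                             "P": [1e-8, 1e-8], "TYPE": ["cis", "cis"]})
        out = detect_esnps(eqtl, self.gwas, self.priors)
        assert len(out) == 1
        assert out.attrs["n_unmatched"] == 1

    def test_duplicate_rows_keep_smallest(self):
        eqtl = pd.DataFrame({"SNP": ["rs1", "rs1"], "GENE": ["a", "a"],
                             "P": [1e-6, 1e-9], "TYPE": ["cis", "cis"]})
        with pytest.warns(UserWarning):
            out = detect_esnps(eqtl, self.gwas, self.priors)
        assert len(out) == 1
        assert out.loc[0, "EQTL_P"] == 1e-9

    def test_missing_kind_label_rejected(self):
        eqtl = pd.DataFrame({"SNP": ["rs1"], "GENE": ["a"], "P": [1e-8],
                             "TYPE": [None]})
        with pytest.raises(ValueError):
            detect_esnps(eqtl, self.gwas, self.priors)


class TestSimulatedP:
    def test_floor_of_estimator(self, rng):
        priors = SherlockPriors(n_sim=999, seed=5)
        pool = rng.uniform(size=2000)
        p = simulated_p(1e9, n_cis=2, n_trans=0, gwas_p_pool=pool, priors=priors)
        assert p == pytest.approx(1 / 1000, abs=1e-15)

    def test_seed_determinism(self, rng):
        priors = SherlockPriors(n_sim=500, seed=42)
        pool = rng.uniform(size=1000)
        a = simulated_p(0.5, 1, 1, pool, priors)
        b = simulated_p(0.5, 1, 1, pool, priors)
        assert a == b

    def test_pool_smaller_than_esnp_count_rejected(self):
        priors = SherlockPriors(n_sim=100)
        with pytest.raises(ValueError):
            simulated_p(0.0, 2, 1, np.array([0.5, 0.5]), priors)

    def test_prior_constants_cancel_under_resampling(self, rng):
        # changing the alpha priors shifts every score by a constant and
        # leaves the simulated significance unchanged (fixed composition)
        pool = rng.uniform(size=1000)
        esnps = esnp_frame([("rs1", "G", 1e-8, "cis", 0.003),
                            ("rs2", "G", 1e-8, "trans", 0.02)])
        pa = SherlockPriors(n_sim=500, seed=9)
        pb = SherlockPriors(alpha_cis=0.3, alpha_trans=0.2, n_sim=500, seed=9)
        sp_a = simulated_p(score_gene(esnps, pa), 1, 1, pool, pa)
        sp_b = simulated_p(score_gene(esnps, pb), 1, 1, pool, pb)
        assert sp_a == sp_b

    def test_null_genes_uniform(self, rng):
        # eSNPs drawn from the pool itself give uniform simulated P
        pool = rng.uniform(size=2000)
        priors = SherlockPriors(n_sim=500, seed=0)
        shared = np.random.default_rng(7)
        sps = []
        for _ in range(250):
            obs = rng.choice(pool, size=3, replace=False)
            lbf = float(np.sum(snp_log10_bf(obs, priors.W)))  # constant prior omitted
            lbf += 3 * np.log10(priors.alpha_cis / (1 - priors.alpha_cis))
            sps.append(simulated_p(lbf, 3, 0, pool, priors, rng=shared))
        assert stats.kstest(sps, "uniform").pvalue > 0.01


class TestSherlockAnalysis:
    def test_gene_without_esnps_absent(self):
        # a genome-wide-significant SNP alone never creates a gene score
        gwas = pd.DataFrame({"SNP": ["rs1", "rs2"], "CHR": "1", "BP": [1, 2],
                             "P": [1e-12, 0.2]})
        eqtl = pd.DataFrame({"SNP": ["rs2"], "GENE": ["geneB"], "P": [1e-9],
                             "TYPE": ["cis"]})
        res, support = sherlock_analysis(eqtl, gwas, SherlockPriors(n_sim=100))
        assert res["GENE"].tolist() == ["geneB"]

    def test_results_sorted_by_simulated_p(self, small_study):
        priors = SherlockPriors(n_sim=200, seed=1)
        res, support = sherlock_analysis(small_study.eqtl_discovery,
                                         small_study.gwas, priors)
        assert (res["SIM_P"].diff().dropna() >= 0).all()
        assert set(support.columns) == {"GENE", "SNP", "KIND", "EQTL_P", "GWAS_P"}
        # true genes score at the top
        ranks = res.reset_index().set_index("GENE")["index"]
        for g in small_study.truth["genes"]:
            assert ranks[g] < len(res) / 10
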