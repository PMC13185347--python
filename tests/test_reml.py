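"""Variance-component REML: likelihood, optimizer, ratios, LRT and screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hologwas as hg
from hologwas.pipeline import analysis_covariates
from hologwas.reml import VarianceComponentModel, lrt_component, screen_heritable_taxa
from hologwas.simulate import SimulationConfig, simulate_all

from conftest import make_genotypes, make_table


def small_instance(n=60, p=120, h2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.5, size=p)
    g = make_genotypes(rng.binomial(2, freqs, size=(n, p)))
    grm = hg.build_grm(hg.filter_variants(g, hwe_alpha=0.0))
    L = np.linalg.cholesky(grm.values + 1e-8 * np.eye(n))
    y = (np.sqrt(h2) * L @ rng.normal(size=n)
         + np.sqrt(1 - h2) * rng.normal(size=n))
    return y, grm


class TestLikelihood:
    def test_restricted_loglik_matches_error_contrasts(self):
        """The reported REML criterion equals the exact MVN density of error
        contrasts A'y up to the constant 0.5 log|X'X|."""
        y, grm = small_instance(n=40)
        n = 40
        X = np.column_stack([np.ones(n), np.linspace(-1, 1, n)])
        model = VarianceComponentModel(y, [grm], exog=X)
        theta = np.array([0.3, 0.7])
        q, _ = np.linalg.qr(X, mode="complete")
        A = q[:, 2:]
        cov = A.T @ (theta[0] * grm.values + theta[1] * np.eye(n)) @ A
        contrast = stats.multivariate_normal(np.zeros(n - 2), cov).logpdf(A.T @ y)
        offset = 0.5 * np.linalg.slogdet(X.T @ X)[1]
        assert model.loglike_restricted(theta) == pytest.approx(
            contrast - offset, abs=1e-6)

    def test_spectral_and_ai_paths_agree(self):
        y, grm = small_instance(n=80, seed=3)
        m = VarianceComponentModel(y, [grm])
        a = m.fit(method="spectral")
        b = m.fit(method="ai")
        assert a.llf == pytest.approx(b.llf, abs=1e-5)
        assert a.ratios["genetic"] == pytest.approx(b.ratios["genetic"], abs=1e-3)

    def test_history_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(n_individuals=150, n_variants=400, n_lines=1, seed=9)
        geno, tables, pheno, _ = simulate_all(cfg)
        geno = hg.filter_variants(geno, hwe_alpha=0.0)
        grm = hg.build_grm(geno)
        mrm = hg.build_mrm(hg.clr_transform(tables["cecum"]))
        res = hg.reml_fit(pheno.fcr, [grm, mrm], method="ai")
        assert np.all(np.diff(res.history) >= -1e-10)

    def test_scale_invariance_of_ratios(self):
        y, grm = small_instance(n=70, seed=11)
        r1 = hg.reml_fit(y, [grm])
        r2 = hg.reml_fit(3.7 * y, [grm])
        assert r2.ratios["genetic"] == pytest.approx(r1.ratios["genetic"], abs=1e-5)
        assert r2.params["residual"] == pytest.approx(
            3.7**2 * r1.params["residual"], rel=1e-4)

    def test_rank_deficient_covariates_rejected(self):
        y, grm = small_instance(n=30)
        X = np.ones((30, 2))
        with pytest.raises(ValueError, match="rank"):
            VarianceComponentModel(y, [grm], exog=X)


class TestHeritability:
    def test_direct_ratio(self):
        y, grm = small_instance(n=50)
        res = hg.reml_fit(y, [grm])
        res.params[:] = [1.0, 3.0]
        assert res.heritability("genetic").h2 == pytest.approx(0.25)
        res.params[:] = [0.0, 3.0]
        assert res.heritability("genetic").h2 == 0.0

    def test_delta_se_matches_parametric_bootstrap(self):
        """Delta-method SE within a factor 1.5 of a 200-draw parametric
        bootstrap on a fixed n=200 instance."""
        rng = np.random.default_rng(21)
        n = 200
        y, grm = small_instance(n=n, p=300, h2=0.4, seed=21)
        fit = hg.reml_fit(y, [grm])
        se_delta = fit.heritability("genetic").se
        sg, se_ = fit.params["genetic"], fit.params["residual"]
        L = np.linalg.cholesky(sg * grm.values + se_ * np.eye(n) + 1e-10 * np.eye(n))
        boots = []
        for _ in range(200):
            yb = fit.model.exog @ np.array([y.mean()]) + L @ rng.normal(size=n)
            boots.append(hg.reml_fit(yb, [grm]).heritability("genetic").h2)
        se_boot = np.std(boots)
        assert se_boot / 1.5 <= se_delta <= se_boot * 1.5


class TestLRT:
    def test_boundary_mixture_values(self):
        y, grm = small_instance(n=50, seed=2)
        full = hg.reml_fit(y, [grm])
        reduced = VarianceComponentModel(y, []).fit()
        # identical log-likelihoods -> LRT 0, p 0.5 under the mixture
        full_clone = hg.reml_fit(y, [grm])
        full_clone.llf = reduced.llf
        lrt, p = lrt_component(full_clone, reduced)
        assert (lrt, p) == (0.0, 0.5)
        # chi2_1 upper quantile at 0.10, halved by the mixture
        full_clone.llf = reduced.llf + 2.706 / 2
        lrt, p = lrt_component(full_clone, reduced)
        assert lrt == pytest.approx(2.706)
        assert p == pytest.approx(0.05, abs=1.5e-4)
        # plain chi2 restores the unmixed reference
        _, p_plain = lrt_component(full_clone, reduced, boundary_mixture=False)
        assert p_plain == pytest.approx(2 * p, rel=1e-9)

    def test_mismatched_data_rejected(self):
        y, grm = small_instance(n=50, seed=2)
        full = hg.reml_fit(y, [grm])
        other = VarianceComponentModel(y + 1.0, []).fit()
        with pytest.raises(ValueError, match="same data"):
            lrt_component(full, other)

    def test_type_i_error_under_reduced_model(self):
        """Data simulated with no genetic component: rejection rate of the
        mixture LRT at nominal 0.05 stays within (0.02, 0.08)."""
        rng = np.random.default_rng(77)
        n = 300
        _, grm = small_instance(n=n, p=400, seed=7)
        X = np.ones((n, 1))
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            y = rng.normal(size=n)
            full = hg.reml_fit(y, [grm], X)
            reduced = VarianceComponentModel(y, [], exog=X).fit()
            _, p = lrt_component(full, reduced)
            rejections += p < 0.05
        assert 0.02 < rejections / n_reps < 0.08


class TestRecovery:
    def test_null_trait_h2_near_zero(self):
        """v_g = 0 (pure noise): mean REML heritability stays below 0.05."""
        ests = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_individuals=300, n_variants=600, n_lines=1, seed=seed,
                variance_fractions={"genetic": 0.0, "duodenum": 0.0,
                                    "jejunum": 0.0, "ileum": 0.0, "cecum": 0.0})
            geno, _, pheno, _ = simulate_all(cfg)
            grm = hg.build_grm(hg.filter_variants(geno, hwe_alpha=0.0))
            _, X = analysis_covariates(grm)
            ests.append(hg.reml_fit(pheno.fcr, [grm], X).ratios["genetic"])
        assert np.mean(ests) < 0.05

    def test_single_kernel_matches_five_kernel_when_microbes_null(self):
        """With all microbial fractions truly zero the genetic ratio agrees
        between the one- and five-kernel models."""
        diffs = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_individuals=300, n_variants=600, n_lines=1, seed=seed + 40,
                variance_fractions={"genetic": 0.3, "duodenum": 0.0,
                                    "jejunum": 0.0, "ileum": 0.0, "cecum": 0.0})
            geno, tables, pheno, _ = simulate_all(cfg)
            geno = hg.filter_variants(geno, hwe_alpha=0.0)
            grm = hg.build_grm(geno)
            _, X = analysis_covariates(grm)
            mrms = [hg.build_mrm(hg.clr_transform(hg.filter_core_taxa(tables[s])))
                    for s in hg.SEGMENTS]
            one = hg.reml_fit(pheno.fcr, [grm], X)
            five = hg.reml_fit(pheno.fcr, [grm] + mrms, X,
                               names=["genetic", *hg.SEGMENTS], method="ai")
            diffs.append(five.ratios["genetic"] - one.ratios["genetic"])
        assert abs(np.mean(diffs)) < 0.05


class TestScreen:
    def test_flag_rule_consistent_with_estimates(self):
        cfg = SimulationConfig(n_individuals=200, n_variants=400, n_lines=1, seed=4)
        geno, tables, _, _ = simulate_all(cfg)
        grm = hg.build_grm(hg.filter_variants(geno, hwe_alpha=0.0))
        out = screen_heritable_taxa(hg.clr_transform(tables["ileum"]), grm)
        ok = out.dropna(subset=["h2"])
        assert len(ok) == len(out)  # no silent failures on clean input
        expected = (ok["h2"] > 0.2) & (ok["p"] < 0.05)
        assert (ok["heritable"] == expected).all()
        assert ((ok["h2"] >= 0) & (ok["h2"] <= 1)).all()

    def test_joint_criterion_truth_table(self):
        """h2 and p must BOTH clear their cuts for the heritable flag."""
        frame = pd.DataFrame({"h2": [0.25, 0.25, 0.15], "p": [0.03, 0.06, 0.001]})
        flags = (frame["h2"] > 0.2) & (frame["p"] < 0.05)
        assert list(flags) == [True, False, False]

    def test_driven_taxa_recovered_and_nulls_calibrated(self):
        """Segments with 5/50 genetically driven taxa: the screen recovers a
        majority with few false positives; an all-noise segment yields few."""
        recovered, false_pos = [], []
        for seed in range(8):
            cfg = SimulationConfig(
                n_individuals=500, n_variants=1000, n_lines=1, seed=seed + 100,
                driven_zero_inflation_range=(0.0, 0.0),
                zero_inflation_range=(0.05, 0.3))
            geno, tables, _, truth = simulate_all(cfg)
            grm = hg.build_grm(hg.filter_variants(geno, hwe_alpha=0.0))
            _, X = analysis_covariates(grm)
            out = screen_heritable_taxa(hg.clr_transform(tables["cecum"]), grm, X)
            tt = truth.taxon_truth["cecum"]
            driven = {k for k, v in tt.items() if v["fraction"] > 0}
            hits = set(out[out["heritable"]]["feature"])
            recovered.append(len(hits & driven))
            false_pos.append(len(hits - driven))
        assert np.median(recovered) >= 3
        assert np.median(false_pos) <= 5
        assert np.mean(false_pos) < 3  # null taxa rarely flagged
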