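"""Filtering, compositional transforms and relationship kernels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import hologwas as hg
from hologwas.datatypes import MISSING

from conftest import make_genotypes, make_table


def brute_force_hwe(n_rr, n_het, n_aa):
    """Independent enumeration of the exact HWE test via the conditional
    distribution of heterozygote counts given allele counts."""
    from fractions import Fraction
    from math import factorial

    n = n_rr + n_het + n_aa
    n_ref = 2 * n_rr + n_het
    n_alt = 2 * n_aa + n_het
    probs = {}
    for het in range(min(n_ref, n_alt) + 1):
        if (n_ref - het) % 2 or (n_alt - het) % 2:
            continue
        hr, ha = (n_ref - het) // 2, (n_alt - het) // 2
        if hr < 0 or ha < 0 or hr + ha + het != n:
            continue
        probs[het] = Fraction(
            2**het * factorial(n) * factorial(n_ref) * factorial(n_alt),
            factorial(hr) * factorial(het) * factorial(ha) * factorial(2 * n))
    total = sum(probs.values())
    obs = probs[n_het] / total
    return float(sum(v / total for v in probs.values() if v / total <= obs))


class TestHWE:
    def test_two_individual_enumeration(self):
        """hom-ref + hom-alt and no hets: only two configurations exist and
        the observed one has probability 1/3."""
        assert hg.hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=80, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hg.hwe_exact_test(a, b, c) == pytest.approx(
            brute_force_hwe(a, b, c), rel=1e-9)


class TestFilterVariants:
    def test_monomorphic_removed_at_maf(self):
        dos = np.column_stack([np.zeros(20), np.random.default_rng(0).integers(0, 3, 20)])
        g = make_genotypes(dos)
        out = hg.filter_variants(g, min_maf=0.05, hwe_alpha=0.0)
        assert out.n_variants == 1
        assert out.variants[0].id == "v1"

    def test_missing_rate_threshold(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(20, 2)).astype(np.int8)
        dos[:3, 0] = MISSING  # rate 0.15 > 0.1
        g = make_genotypes(dos)
        out = hg.filter_variants(g, max_missing=0.1, min_maf=0.0, hwe_alpha=0.0)
        assert [v.id for v in out.variants] == ["v1"]

    def test_hwe_boundary_retained(self):
        # the 2-individual toy has exact p = 1/3 >> 1e-6
        g = make_genotypes([[0], [2]])
        out = hg.filter_variants(g, min_maf=0.0, hwe_alpha=1e-6)
        assert out.n_variants == 1

    def test_empty_result_raises(self):
        g = make_genotypes(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="review"):
            hg.filter_variants(g)


class TestFilterCoreTaxa:
    def test_both_thresholds_applied(self):
        """A kept; B fails mean abundance; C fails prevalence (0.25 < 0.30)."""
        a = np.full(4, 0.10)
        b = np.full(4, 0.0001)
        c = np.array([0.05, 0.0, 0.0, 0.0])
        rest = 1.0 - (a + b + c)
        t = make_table(np.column_stack([a, b, c, rest]), taxa=["A", "B", "C", "rest"])
        out = hg.filter_core_taxa(t)
        assert "A" in out.taxa and "B" not in out.taxa and "C" not in out.taxa
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0)

    def test_zero_thresholds_identity_on_taxa(self, rng):
        vals = rng.random((5, 6))
        vals /= vals.sum(axis=1, keepdims=True)
        t = make_table(vals)
        out = hg.filter_core_taxa(t, 0.0, 0.0)
        assert out.taxa == t.taxa

    def test_prevalence_boundary_inclusive(self):
        # present in exactly 30% of 10 samples -> retained
        x = np.zeros(10)
        x[:3] = 0.2
        t = make_table(np.column_stack([x, 1.0 - x]), taxa=["edge", "fill"])
        out = hg.filter_core_taxa(t, min_total_rel_abund=0.0, min_prevalence=0.30)
        assert "edge" in out.taxa


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        t = make_table([[0.25, 0.25, 0.25, 0.25]])
        np.testing.assert_allclose(hg.clr_transform(t).values, 0.0, atol=1e-12)

    def test_direct_evaluation(self):
        t = make_table([[1 / 6, 1 / 6, 4 / 6]])
        out = hg.clr_transform(t).values[0]
        expect = (2 / 3) * np.log(4)
        np.testing.assert_allclose(out, [-expect / 2, -expect / 2, expect], atol=1e-12)

    @given(arrays(float, (4, 6), elements=st.floats(1e-6, 1.0)))
    @settings(max_examples=60, deadline=None)
    def test_rows_sum_to_zero(self, vals):
        t = make_table(vals / vals.sum(axis=1, keepdims=True))
        assert np.abs(hg.clr_transform(t).values.sum(axis=1)).max() < 1e-9

    def test_zero_replacement_keeps_closure_and_signal(self, rng):
        vals = rng.random((6, 5))
        vals[0, 0] = 0.0
        t = make_table(vals / vals.sum(axis=1, keepdims=True))
        out = hg.clr_transform(t)
        assert np.abs(out.values.sum(axis=1)).max() < 1e-9

    def test_all_zero_row_rejected(self):
        t = make_table([[0.0, 0.0], [0.5, 0.5]], scale="counts")
        with pytest.raises(ValueError):
            hg.clr_transform(t)


class TestStandardize:
    def test_hand_zscore(self):
        t = make_table([[1.0], [3.0]], scale="clr")
        np.testing.assert_allclose(hg.standardize_taxa(t).values.ravel(),
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_idempotent(self, rng):
        t = make_table(rng.normal(size=(30, 4)), scale="clr")
        once = hg.standardize_taxa(t)
        twice = hg.standardize_taxa(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_column_rejected(self):
        t = make_table([[1.0, 2.0], [1.0, 3.0]], scale="clr", taxa=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hg.standardize_taxa(t)


class TestGRM:
    def test_single_variant_hand_example(self):
        g = make_genotypes([[0], [1], [2]])
        np.testing.assert_allclose(
            hg.build_grm(g).values,
            [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12)

    def test_symmetric_psd_on_random_fixtures(self, rng):
        for _ in range(40):
            freqs = rng.uniform(0.1, 0.5, size=15)
            g = make_genotypes(rng.binomial(2, freqs, size=(12, 15)))
            try:
                k = hg.build_grm(g)
            except ValueError:
                continue  # monomorphic draw
            np.testing.assert_allclose(k.values, k.values.T, atol=1e-10)
            assert np.linalg.eigvalsh(k.values)[0] > -1e-8

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        freqs = rng.uniform(0.1, 0.5, size=10_000)
        g = make_genotypes(rng.binomial(2, freqs, size=(200, 10_000)))
        k = hg.build_grm(g)
        assert 0.95 <= np.diag(k.values).mean() <= 1.05

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hg.build_grm(make_genotypes([[0], [0], [0]]))


class TestMRM:
    def test_two_duck_hand_example(self):
        t = make_table([[1.0], [3.0]], scale="clr")
        np.testing.assert_allclose(hg.build_mrm(t).values,
                                   [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_matches_direct_formula(self, rng):
        """Two-route check: kernel equals the elementwise cross-product sum
        with unbiased per-taxon variances computed independently."""
        vals = rng.normal(size=(9, 5))
        t = make_table(vals, scale="clr")
        mean = vals.mean(axis=0)
        var = vals.var(axis=0, ddof=1)
        direct = np.zeros((9, 9))
        for a in range(5):
            d = vals[:, a] - mean[a]
            direct += np.outer(d, d) / var[a]
        direct /= 5
        np.testing.assert_allclose(hg.build_mrm(t).values, direct, atol=1e-10)

    def test_mean_diagonal_is_unbiased_constant(self, rng):
        """With the (n-1) variance convention the mean diagonal is (n-1)/n."""
        n = 14
        t = make_table(rng.normal(size=(n, 7)), scale="clr")
        assert np.diag(hg.build_mrm(t).values).mean() == pytest.approx(
            (n - 1) / n, abs=1e-9)

    def test_sample_permutation_equivariance(self, rng):
        vals = rng.normal(size=(8, 4))
        t = make_table(vals, scale="clr")
        perm = rng.permutation(8)
        tp = make_table(vals[perm], scale="clr",
                        samples=[f"s{i}" for i in perm])
        np.testing.assert_allclose(hg.build_mrm(tp).values,
                                   hg.build_mrm(t).values[np.ix_(perm, perm)],
                                   atol=1e-10)


class TestKernelPCA:
    def test_rank_one_kernel(self, rng):
        v = rng.normal(size=6)
        v -= v.mean()  # centred so double-centring preserves rank-1 structure
        k = hg.KernelMatrix([f"s{i}" for i in range(6)], np.outer(v, v), "GRM")
        _, fracs = hg.kernel_pca(k, 3)
        assert fracs[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sorted_and_bounded(self, rng):
        a = rng.normal(size=(10, 6))
        k = hg.KernelMatrix([f"s{i}" for i in range(10)], a @ a.T, "GRM")
        _, fracs = hg.kernel_pca(k, 5)
        assert np.all(np.diff(fracs) <= 1e-12)
        assert fracs.sum() <= 1 + 1e-9

    def test_n_components_validated(self, rng):
        a = rng.normal(size=(4, 3))
        k = hg.KernelMatrix(list("abcd"), a @ a.T, "GRM")
        with pytest.raises(ValueError):
            hg.kernel_pca(k, 5)

    def test_two_line_cohort_separates_on_pc1(self):
        from hologwas.simulate import SimulationConfig, simulate_genotypes

        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(n_individuals=200, n_variants=800,
                                   line_divergence=0.05, seed=seed)
            g, lines = simulate_genotypes(cfg)
            scores, _ = hg.kernel_pca(hg.build_grm(hg.filter_variants(g, hwe_alpha=0.0)), 2)
            pc1 = scores["PC1"].to_numpy()
            a = pc1[np.array(lines) == "line1"]
            b = pc1[np.array(lines) == "line2"]
            hits += (a.max() < b.min()) or (b.max() < a.min())
        assert hits == 5


def test_clr_then_standardize_commutes_with_sample_order(rng):
    vals = rng.random((10, 6))
    vals /= vals.sum(axis=1, keepdims=True)
    t = make_table(vals)
    perm = rng.permutation(10)
    tp = make_table(vals[perm], samples=[f"s{i}" for i in perm])
    a = hg.standardize_taxa(hg.clr_transform(t)).values
    b = hg.standardize_taxa(hg.clr_transform(tp)).values
    np.testing.assert_allclose(b, a[perm], atol=1e-10)
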