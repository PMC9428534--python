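"""Genetics: Mendelian transmission, expression, and heritability recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batchspawn.genetics import (
    ExpressionParams,
    Genotype,
    express_linf,
    founder_genotype,
    founder_genotypes,
    inherit,
    k_from_linf,
    mendelian_offspring,
)


def _fixed(value, n_loci=10):
    return Genotype(np.full(2 * n_loci, value, dtype=np.uint8), n_loci)


class TestFounders:
    def test_degenerate_frequencies_fix_the_genotype(self, rng):
        assert founder_genotype(rng, allele_freq=1.0).value == 20
        assert founder_genotype(rng, allele_freq=0.0).value == 0

    @pytest.mark.parametrize("freq", [-0.1, 1.5])
    def test_invalid_frequency_rejected(self, rng, freq):
        with pytest.raises(ValueError):
            founder_genotypes(rng, 1, allele_freq=freq)

    def test_binomial_moments_at_half(self, rng):
        g = founder_genotypes(rng, 40000, allele_freq=0.5).sum(axis=1)
        # g ~ Binomial(20, 0.5): mean 10, variance 5
        assert g.mean() == pytest.approx(10.0, abs=0.05)
        assert g.var() == pytest.approx(5.0, rel=0.05)

    def test_genotype_invariants_enforced(self):
        with pytest.raises(ValueError):
            Genotype(np.array([0, 1, 2] * 7)[:20], 10)
        with pytest.raises(ValueError):
            Genotype(np.ones(19, dtype=np.uint8), 10)


class TestInheritance:
    def test_homozygous_crosses(self, rng):
        assert inherit(_fixed(1), _fixed(1), rng).value == 20
        # all-1 x all-0 forces heterozygosity at every locus
        assert inherit(_fixed(1), _fixed(0), rng).value == 10

    def test_mismatched_locus_count_rejected(self, rng):
        with pytest.raises(ValueError):
            inherit(_fixed(1, n_loci=10), _fixed(1, n_loci=5), rng)

    def test_offspring_mean_is_midparent(self, rng):
        dams = founder_genotypes(rng, 20000)
        sires = founder_genotypes(rng, 20000)
        kids = mendelian_offspring(dams, sires, rng)
        mid = (dams.sum(1) + sires.sum(1)) / 2.0
        resid = kids.sum(1) - mid
        assert abs(resid.mean()) < 0.05

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_alleles_conserved_no_mutation(self, seed):
        r = np.random.default_rng(seed)
        dams = founder_genotypes(r, 50)
        sires = founder_genotypes(r, 50)
        kids = mendelian_offspring(dams, sires, r)
        assert np.isin(kids, (0, 1)).all()
        # a locus fixed in both parents is fixed in the child
        both_one = (dams.reshape(50, 10, 2).min(2) == 1) & (
            sires.reshape(50, 10, 2).min(2) == 1
        )
        kid_pairs = kids.reshape(50, 10, 2)
        assert (kid_pairs.min(2)[both_one] == 1).all()

    def test_drift_only_frequency_change(self, rng):
        # allele frequency change over one generation of random mating is
        # within a few standard errors of binomial sampling noise
        n = 5000
        dams = founder_genotypes(rng, n, allele_freq=0.5)
        sires = founder_genotypes(rng, n, allele_freq=0.5)
        kids = mendelian_offspring(dams, sires, rng)
        p_parent = (dams.mean() + sires.mean()) / 2
        p_kid = kids.mean()
        se = np.sqrt(0.25 / (2 * 10 * n))
        assert abs(p_kid - p_parent) < 6 * se


class TestExpression:
    def test_noise_free_limit_of_default_calibration(self, rng):
        p = ExpressionParams(noise_sd=1e-12)
        assert express_linf(_fixed(1), rng, p) == pytest.approx(100.0)
        g10 = inherit(_fixed(1), _fixed(0), rng)  # g = 10
        assert express_linf(g10, rng, p) == pytest.approx(80.0, abs=1e-6)

    def test_floor_truncation(self, rng):
        p = ExpressionParams(intercept_cm=-500.0)
        assert express_linf(_fixed(0), rng, p) == pytest.approx(1.0)

    def test_phenotypic_variance_decomposition(self, rng):
        p = ExpressionParams()
        g = founder_genotypes(rng, 60000).sum(1).astype(float)
        linf = express_linf(g, rng, p)
        expected = p.slope_cm_per_score**2 * (5.0 + p.noise_sd**2)
        assert linf.var() == pytest.approx(expected, rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExpressionParams(noise_sd=0.0)
        with pytest.raises(ValueError):
            ExpressionParams(slope_cm_per_score=-1.0)
        with pytest.raises(ValueError):
            ExpressionParams(growth_beta=0.1)


def _h2_midparent_offspring(rng, p: ExpressionParams, n_trios=20000) -> float:
    """Independent heritability oracle: slope of offspring phenotype on
    midparent phenotype in a random-mating founder design."""
    dams = founder_genotypes(rng, n_trios)
    sires = founder_genotypes(rng, n_trios)
    kids = mendelian_offspring(dams, sires, rng)
    ph_d = express_linf(dams.sum(1).astype(float), rng, p)
    ph_s = express_linf(sires.sum(1).astype(float), rng, p)
    ph_k = express_linf(kids.sum(1).astype(float), rng, p)
    mid = (ph_d + ph_s) / 2.0
    return float(np.polyfit(mid, ph_k, 1)[0])


class TestHeritability:
    def test_founder_heritability_in_empirical_range(self, rng):
        h2 = _h2_midparent_offspring(rng, ExpressionParams())
        assert 0.2 - 0.03 <= h2 <= 0.3 + 0.03

    def test_affine_invariance_of_heritability(self):
        a = _h2_midparent_offspring(
            np.random.default_rng(5), ExpressionParams(intercept_cm=60, slope_cm_per_score=2)
        )
        b = _h2_midparent_offspring(
            np.random.default_rng(5), ExpressionParams(intercept_cm=120.0, slope_cm_per_score=5.0)
        )
        assert a == pytest.approx(b, abs=1e-9)


class TestGrowthCoupling:
    def test_published_style_calibration_identity(self):
        # log-log coefficients chosen to give k = exp(alpha)/L∞ reproduce
        # k(80) = 0.12 exactly when alpha = ln(0.12 * 80)
        p = ExpressionParams(growth_alpha=2.2618, growth_beta=-1.0)
        assert k_from_linf(80.0, p) == pytest.approx(0.12, rel=1e-3)

    def test_default_calibration_value(self):
        assert k_from_linf(80.0) == pytest.approx(0.0825, rel=1e-3)

    def test_strictly_decreasing_in_linf(self):
        linf = np.linspace(20, 140, 50)
        k = k_from_linf(linf)
        assert (np.diff(k) < 0).all()

    def test_non_positive_linf_rejected(self):
        with pytest.raises(ValueError):
            k_from_linf(0.0)
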