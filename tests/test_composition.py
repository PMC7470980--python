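"""Compositional statistics: binning, ilr, paired Hotelling T^2, Mardia."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ribopause.composition import (
    bin_composition, bin_edges, close, geometric_mean_profile, ilr_basis,
    ilr_transform, normality_check, paired_hotelling, replace_zeros,
)


class TestBinComposition:
    def test_uniform_density(self):
        parts = bin_composition(np.ones(200), (0, 200))
        assert np.allclose(parts, 10.0)

    def test_concentrated_density(self):
        v = np.zeros(30)
        v[:3] = 5.0
        parts = bin_composition(v, (0, 30))
        assert parts[0] == pytest.approx(100.0)
        assert np.allclose(parts[1:], 0.0)

    def test_matches_brute_force_segment_sums(self):
        rng = np.random.default_rng(8)
        v = rng.gamma(1.5, size=100)
        parts = bin_composition(v, (0, 100))
        oracle = 100 * np.array([v[10*j:10*(j+1)].sum() for j in range(10)]) / v.sum()
        assert np.allclose(parts, oracle)

    def test_remainder_goes_to_three_prime_bins(self):
        edges = bin_edges(103, 10)
        sizes = np.diff(edges)
        assert list(sizes) == [10] * 7 + [11] * 3

    def test_closure_to_100(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(1.0, size=137)
        assert bin_composition(v, (3, 130)).sum() == pytest.approx(100.0)

    def test_zero_window_raises(self):
        with pytest.raises(ValueError, match="zero density"):
            bin_composition(np.zeros(50), (0, 50))


class TestZeroReplacement:
    def test_replacement_rule(self):
        parts = np.array([50.0, 0.0, 30.0, 20.0, 0.0])
        out = replace_zeros(parts)
        delta = 0.65 * 20.0
        assert out.sum() == pytest.approx(100.0)
        # the two zero parts got delta before re-closure
        scale = 100.0 / (100.0 + 2 * delta)
        assert out[1] == pytest.approx(delta * scale)

    def test_strictly_positive_is_unchanged(self):
        parts = np.array([60.0, 30.0, 10.0])
        assert np.allclose(replace_zeros(parts), parts)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            replace_zeros(np.zeros(5))


class TestGeometricMean:
    def test_idempotent_on_identical_compositions(self):
        comp = np.array([40.0, 30.0, 20.0, 10.0])
        gm = geometric_mean_profile([comp, comp, comp])
        assert np.allclose(gm, comp)

    def test_two_part_symmetry(self):
        gm = geometric_mean_profile([[80.0, 20.0], [20.0, 80.0]])
        assert np.allclose(gm, [50.0, 50.0])

    def test_matches_log_mean_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(10) * 2, size=5) * 100
        gm = geometric_mean_profile(X)
        oracle = close(stats.gmean(X, axis=0), 100.0)
        assert np.allclose(gm, oracle)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            geometric_mean_profile([[50.0, 0.0, 50.0]])


class TestIlr:
    @pytest.mark.parametrize("kind", ["pivot-1", "helmert"])
    def test_basis_is_orthonormal_contrast(self, kind):
        V = ilr_basis(10, kind)
        assert V.shape == (9, 10)
        assert np.allclose(V @ V.T, np.eye(9), atol=1e-12)
        assert np.allclose(V.sum(axis=1), 0.0, atol=1e-12)

    def test_uniform_composition_maps_to_zero(self):
        V = ilr_basis(10)
        assert np.allclose(ilr_transform(np.full(10, 10.0), V), 0.0)

    def test_three_part_hand_oracle(self):
        """(1/2, 1/4, 1/4) against explicit V^T clr arithmetic."""
        V = ilr_basis(3)
        x = np.array([0.5, 0.25, 0.25])
        logx = np.log(x)
        clr = logx - logx.mean()
        oracle = V @ clr
        assert np.allclose(ilr_transform(x, V), oracle)
        # first pivot balance: sqrt(2/3) * ln(x1 / gmean(x2, x3))
        expected0 = np.sqrt(2.0 / 3.0) * np.log(0.5 / np.sqrt(0.25 * 0.25))
        assert oracle[0] == pytest.approx(expected0)

    def test_closure_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, size=10)
        V = ilr_basis(10)
        assert np.allclose(ilr_transform(x, V), ilr_transform(7.3 * x, V))

    def test_agrees_with_skbio_up_to_isometry(self):
        """Any orthonormal ilr preserves the Aitchison norm; compare with
        scikit-bio's implementation as an independent oracle."""
        from skbio.stats.composition import ilr as skbio_ilr

        rng = np.random.default_rng(3)
        X = rng.dirichlet(np.ones(10), size=20)
        ours = ilr_transform(X, ilr_basis(10))
        theirs = np.asarray(skbio_ilr(X))
        assert np.allclose(np.linalg.norm(ours, axis=1),
                           np.linalg.norm(theirs, axis=1))

    def test_nonpositive_part_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ilr_transform([1.0, 0.0, 2.0], ilr_basis(3))


class TestPairedHotelling:
    def test_identical_pairs(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(15, 9))
        res = paired_hotelling(a, a.copy())
        assert res.T2 == 0.0 and res.p_value == 1.0

    def test_matches_matrix_formula_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 2))
        b = rng.normal(loc=0.3, size=(12, 2))
        res = paired_hotelling(a, b)
        d = a - b
        dbar = d.mean(axis=0)
        S = np.cov(d, rowvar=False, ddof=1)
        T2 = 12 * dbar @ np.linalg.inv(S) @ dbar
        assert res.T2 == pytest.approx(T2)
        F = T2 * (12 - 2) / (2 * 11)
        assert res.F == pytest.approx(F)
        assert res.p_value == pytest.approx(float(stats.f.sf(F, 2, 10)))

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        a = rng.normal(size=(25, 4))
        b = rng.normal(loc=0.2, size=(25, 4))
        res = paired_hotelling(a, b)
        ref = pg.multivariate_ttest(a, b, paired=True)
        assert res.T2 == pytest.approx(float(ref["T2"].iloc[0]))
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]))

    def test_basis_invariance_of_t2(self):
        """T^2 is identical (1e-8) across orthonormal ilr bases."""
        rng = np.random.default_rng(8)
        X = rng.dirichlet(np.ones(10) * 3, size=30)
        Y = rng.dirichlet(np.ones(10) * 3, size=30)
        t2 = {}
        for kind in ("pivot-1", "helmert"):
            V = ilr_basis(10, kind)
            t2[kind] = paired_hotelling(ilr_transform(X, V), ilr_transform(Y, V)).T2
        assert t2["pivot-1"] == pytest.approx(t2["helmert"], abs=1e-8)

    def test_insufficient_pairs_rejected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(9, 9))
        with pytest.raises(ValueError, match="insufficient"):
            paired_hotelling(a, a + 1.0)

    def test_null_calibration_small(self):
        """Type-I error at alpha=0.05 over 200 null replicates (binomial
        4-sigma band); the full alpha=0.01 calibration runs in the
        acceptance suite."""
        rng = np.random.default_rng(10)
        rej = sum(
            paired_hotelling(rng.normal(size=(20, 3)), rng.normal(size=(20, 3))).p_value < 0.05
            for _ in range(200)
        )
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rej / 200 - 0.05) < 4 * se


class TestNormalityCheck:
    def test_null_p_values_roughly_uniform(self):
        """Mardia p-values under multivariate normality pass a KS
        uniformity check over 150 replicates."""
        rng = np.random.default_rng(11)
        pvals = [normality_check(rng.normal(size=(100, 3))).skew_p for _ in range(150)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(12)
        rejections = sum(
            normality_check(np.exp(rng.normal(size=(200, 3)))).p_value < 0.05
            for _ in range(20)
        )
        assert rejections >= 18  # power > 0.9 at n=200

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="n > p"):
            normality_check(rng.normal(size=(5, 9)))


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_composition_pipeline_closure_property(seed):
    """Random density -> binning -> zero replacement keeps closure and
    feeds ilr without error."""
    rng = np.random.default_rng(seed)
    v = rng.poisson(2.0, size=rng.integers(50, 300)).astype(float)
    if v.sum() == 0:
        v[0] = 1.0
    parts = replace_zeros(bin_composition(v, (0, len(v))))
    assert parts.sum() == pytest.approx(100.0)
    coords = ilr_transform(parts, ilr_basis(10))
    assert np.all(np.isfinite(coords))
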