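import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from icdep import midist


class TestRankTransform:
    def test_strictly_increasing_input(self):
        assert np.array_equal(midist.rank_transform(np.arange(10.0) * 3 + 1), np.arange(1, 11))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        x = np.random.default_rng(seed).normal(size=50)
        assert np.array_equal(midist.rank_transform(x), midist.rank_transform(np.exp(2 * x)))

    def test_constant_input_gets_midrank(self):
        r = midist.rank_transform(np.full(9, 3.3))
        assert np.all(r == 5.0)


class TestJointHistogram:
    def test_normalisation_and_bin_rule(self, rng):
        x, y = rng.normal(size=(2, 512))
        t = midist.joint_histogram(x, y)
        assert t.shape == (10, 10)  # M = 1 + log2(512)
        assert t.sum() == pytest.approx(1.0)

    def test_identical_inputs_concentrate_on_the_diagonal(self, rng):
        x = midist.rank_transform(rng.normal(size=1000))
        t = midist.joint_histogram(x, x, 8)
        assert np.trace(t) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            midist.joint_histogram(np.arange(5.0), np.arange(6.0))


class TestHistEntropyMI:
    def test_independent_uniform_product_table(self):
        m = 8
        t = np.full((m, m), 1.0 / m**2)
        h, i = midist.hist_entropy_mi(t)
        assert i == pytest.approx(0.0, abs=1e-12)
        assert h == pytest.approx(2 * np.log(m))

    def test_diagonal_table_has_zero_distance(self):
        m = 8
        t = np.diag(np.full(m, 1.0 / m))
        h, i = midist.hist_entropy_mi(t)
        assert h == pytest.approx(np.log(m))
        assert i == pytest.approx(np.log(m))

    def test_two_by_two_example(self):
        # direct summation: 0.8 ln 1.6 + 0.2 ln 0.4 = 0.19274 nats
        h, i = midist.hist_entropy_mi(np.array([[0.4, 0.1], [0.1, 0.4]]))
        assert i == pytest.approx(0.19274, abs=1e-4)


def _pairwise_vi_from_joint(p3):
    """Brute-force oracle: variation of information between each pair of three
    discrete variables, from their exact joint pmf."""

    def vi(p):
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        h = -(p[nz] * np.log(p[nz])).sum()
        i = (p[nz] * np.log(p[nz] / np.outer(px, py)[nz])).sum()
        return h - i

    d12 = vi(p3.sum(axis=2))
    d13 = vi(p3.sum(axis=1))
    d23 = vi(p3.sum(axis=0))
    return d12, d13, d23


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_vi_metric_axioms_on_discrete_triples(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    p3 = rng.uniform(size=(k, k, k))
    p3 /= p3.sum()
    d12, d13, d23 = _pairwise_vi_from_joint(p3)
    for d in (d12, d13, d23):
        assert d >= -1e-12
    assert d12 <= d13 + d23 + 1e-9
    assert d13 <= d12 + d23 + 1e-9
    assert d23 <= d12 + d13 + 1e-9


def test_histogram_self_distance_and_symmetry(rng):
    x, y = rng.normal(size=(2, 2000))
    assert midist.mi_distance(x, x) == pytest.approx(0.0, abs=1e-10)
    assert midist.mi_distance(x, y) == pytest.approx(midist.mi_distance(y, x))


class TestSilverman:
    def test_reference_value(self):
        assert midist.silverman_1d(1.0, 100) == pytest.approx(0.42200, abs=2e-4)

    def test_homogeneity_and_limit(self):
        assert midist.silverman_1d(3.0, 500) == pytest.approx(3 * midist.silverman_1d(1.0, 500))
        assert midist.silverman_1d(1.0, 10**7) < 0.05

    def test_2d_prefactor_is_unity(self):
        assert midist.silverman_2d(1.0, 4096) == pytest.approx(4096 ** (-1 / 6.0))

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            midist.silverman_1d(0.0, 100)


class TestKDEDensities:
    def test_single_kernel_is_the_normal_density(self):
        pdf = midist.kde_pdf_1d(np.array([0.0]), 1.0)
        x = np.linspace(-3, 3, 13)
        assert np.allclose(pdf(x), norm.pdf(x), atol=1e-12)

    def test_1d_density_integrates_to_one(self, rng):
        data = rng.normal(size=200)
        pdf = midist.kde_pdf_1d(data, 0.3)
        total = midist.adaptive_simpson(lambda x: pdf(x), data.min() - 3, data.max() + 3, tol=1e-8)
        assert total[0] == pytest.approx(1.0, abs=1e-6)

    def test_2d_density_integrates_to_one(self, rng):
        xd, yd = rng.normal(size=(2, 80))
        pdf = midist.kde_pdf_2d(xd, yd, 0.4)

        def outer(xq):
            res = midist.adaptive_simpson(
                lambda yq: np.stack([pdf(np.full_like(yq, xi), yq) for xi in xq], axis=1),
                yd.min() - 3,
                yd.max() + 3,
                tol=1e-7,
            )
            return res

        total = midist.adaptive_simpson(outer, xd.min() - 3, xd.max() + 3, tol=1e-6)
        assert total.sum() == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            midist.kde_pdf_1d(np.arange(3.0), 0.0)


class TestAdaptiveSimpson:
    def test_sine_integral(self):
        res = midist.adaptive_simpson(np.sin, 0.0, np.pi, tol=1e-9)
        assert res[0] == pytest.approx(2.0, abs=1e-8)

    @given(st.tuples(*[st.floats(-2, 2) for _ in range(4)]))
    @settings(max_examples=25, deadline=None)
    def test_cubics_are_exact(self, coeffs):
        a, b, c, d = coeffs
        res = midist.adaptive_simpson(
            lambda x: a + b * x + c * x**2 + d * x**3, -1.0, 2.0, tol=1e-10
        )
        exact = (
            a * 3 + b * (4 - 1) / 2 + c * (8 + 1) / 3 + d * (16 - 1) / 4
        )
        assert res[0] == pytest.approx(exact, abs=1e-7)

    def test_vector_valued_integrand(self):
        res = midist.adaptive_simpson(
            lambda x: np.stack([x**2, np.sin(x)], axis=1), 0.0, 1.0, tol=1e-9
        )
        assert res[0] == pytest.approx(1 / 3, abs=1e-8)
        assert res[1] == pytest.approx(1 - np.cos(1), abs=1e-8)

    def test_budget_exhaustion_raises(self):
        spiky = lambda x: 1.0 / np.sqrt(np.abs(x - np.sqrt(2) / 2) + 1e-14)
        with pytest.raises(midist.QuadratureError):
            midist.adaptive_simpson(spiky, 0.0, 1.0, tol=1e-12, max_depth=6)


def _gaussian_pair(rng, rho, n):
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return x, y


def _smoothed_gaussian_mi(rho, n):
    """MI of the Silverman-smoothed bivariate Gaussian: the population limit
    of the KDE plug-in estimate (joint smoothed with the 2D bandwidth, the
    marginals with the 1D one)."""
    h1sq = midist.silverman_1d(1.0, n) ** 2
    h2sq = midist.silverman_2d(1.0, n) ** 2
    det = (1 + h2sq) ** 2 - rho**2
    return -1.0 - 0.5 * np.log(det) + np.log(1 + h1sq) + (1 + h2sq) / (1 + h1sq)


class TestKDEEntropyMI:
    def test_independent_samples_have_near_zero_mi(self, rng):
        x, y = _gaussian_pair(rng, 0.0, 2000)
        _, i = midist.kde_entropy_mi(x, y)
        assert abs(i) < 0.05

    @pytest.mark.parametrize("rho", [0.5, 0.9])
    def test_matches_smoothed_gaussian_closed_form(self, rho, rng):
        # the correct oracle for the plug-in estimator: its population limit
        # is the MI of the kernel-smoothed Gaussian, not of the raw one
        x, y = _gaussian_pair(rng, rho, 2000)
        _, i = midist.kde_entropy_mi(x, y)
        assert i == pytest.approx(_smoothed_gaussian_mi(rho, 2000), abs=0.05)

    def test_moderate_dependence_recovered(self, rng):
        x, y = _gaussian_pair(rng, 0.5, 2000)
        _, i = midist.kde_entropy_mi(x, y)
        assert i == pytest.approx(-0.5 * np.log(1 - 0.25), abs=0.1)

    def test_self_distance_shrinks_with_sample_size(self, rng):
        x_small = rng.standard_normal(300)
        x_big = rng.standard_normal(3000)
        d_small = midist.mi_distance(x_small, x_small, "kde")
        d_big = midist.mi_distance(x_big, x_big, "kde")
        d_indep = midist.mi_distance(*_gaussian_pair(rng, 0.0, 3000), "kde")
        assert d_big < d_small  # bandwidth floor decreases with N
        assert d_big < 0.5 * d_indep

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            midist.kde_entropy_mi(np.ones(100), np.arange(100.0))


def test_histogram_recovers_gaussian_mi(rng):
    for rho in (0.0, 0.5, 0.9):
        x, y = _gaussian_pair(rng, rho, 2000)
        _, i = midist.entropy_mi(x, y, "histogram")
        assert i == pytest.approx(-0.5 * np.log(1 - rho**2) if rho else 0.0, abs=0.1)


def test_added_noise_cannot_increase_information(rng):
    x = rng.standard_normal(4000)
    base = rng.standard_normal(4000)
    mis = []
    for lam in (0.0, 0.5, 1.0, 2.0):
        _, i = midist.entropy_mi(x, x + lam * base, "histogram")
        mis.append(i)
    assert all(mis[k + 1] < mis[k] for k in range(3))


class TestPairwiseDistances:
    def test_matrix_invariants(self, decomp_delay5):
        dm = midist.pairwise_distances(decomp_delay5, "histogram")
        v = dm.values
        assert v.shape == (5, 5)
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0.0)
        assert np.all(v >= 0.0)
        assert len(np.unique(v[np.triu_indices(5, 1)])) == 10

    def test_sign_flip_invariance(self, decomp_delay5):
        maps = decomp_delay5.maps.copy()
        flipped = maps.copy()
        flipped[2] *= -1
        a = midist.pairwise_distances(maps, "histogram").values
        b = midist.pairwise_distances(flipped, "histogram").values
        assert np.allclose(a, b, atol=1e-12)

    def test_kde_sign_flip_invariance(self, rng):
        maps = rng.standard_normal((3, 400)) ** 3  # skewed, non-Gaussian
        flipped = maps.copy()
        flipped[1] *= -1
        a = midist.pairwise_distances(maps, "kde").values
        b = midist.pairwise_distances(flipped, "kde").values
        assert np.allclose(a, b, atol=1e-3)

    def test_single_component_rejected(self, rng):
        with pytest.raises(ValueError):
            midist.pairwise_distances(rng.normal(size=(1, 100)), "histogram")

    def test_failure_names_the_pair(self):
        maps = np.vstack([np.ones(100), np.arange(100.0)])
        with pytest.raises(RuntimeError, match=r"\(0, 1\)"):
            midist.pairwise_distances(maps, "kde")

    def test_csv_roundtrip(self, decomp_delay5, tmp_path):
        dm = midist.pairwise_distances(decomp_delay5, "histogram")
        out = tmp_path / "d.csv"
        dm.save(out)
        assert out.exists() and out.with_suffix(".json").exists()
        import pandas as pd

        back = pd.read_csv(out, index_col=0).to_numpy()
        assert np.allclose(back, dm.values)
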