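import itertools

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from betanest import (
    DistanceMatrix, ValidationError, attribute_distance, geo_distance,
    mantel, mrm, pairwise_matrices, partial_mantel,
)
from .conftest import random_community


def dm(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or tuple(str(i) for i in range(values.shape[0]))
    return DistanceMatrix(tuple(labels), values)


def random_dm(rng, n=6):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return dm(v)


class TestAttributeDistance:
    def test_equal_values_zero_matrix(self):
        assert np.all(attribute_distance([3, 3, 3]).values == 0)

    def test_log10_analytic(self):
        d = attribute_distance([10, 1000], transform="log10")
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_table1_extremes(self, table1):
        d = attribute_distance(table1.area_ha, transform="log10")
        expected = abs(np.log10(1289.23) - np.log10(0.57))
        assert d.to_frame().loc["1", "37"] == pytest.approx(expected)

    def test_nonpositive_under_log_rejected(self):
        with pytest.raises(ValidationError):
            attribute_distance([1, 0], transform="log10")


class TestGeoDistance:
    def test_one_degree_latitude(self):
        d = geo_distance([29.0, 30.0], [118.0, 118.0])
        assert d.values[0, 1] == pytest.approx(111.19, abs=0.1)

    def test_table1_matrix_contract(self, table1):
        d = geo_distance(table1.lat, table1.lon)
        assert d.n == 37
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert d.values.max() < 30  # the lake spans a few tens of km at most

    def test_invalid_coordinates(self):
        with pytest.raises(ValidationError):
            geo_distance([95.0, 0.0], [0.0, 0.0])


class TestMantel:
    def test_self_and_affine_correlation_is_one(self, rng):
        d = random_dm(rng)
        assert mantel(d, d, n_perm=99, seed=0).r == pytest.approx(1.0)
        d2 = dm(2.5 * d.values + (1 - np.eye(d.n)))
        assert mantel(d, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_constant_triangle_signalled(self):
        with pytest.raises(ValidationError):
            mantel(dm(1 - np.eye(4)), dm(np.abs(np.subtract.outer(
                range(4), range(4))).astype(float)), n_perm=9)

    def test_seed_determinism_and_label_invariance(self, rng):
        dx, dy = random_dm(rng), random_dm(rng)
        a = mantel(dx, dy, n_perm=199, seed=11)
        assert a == mantel(dx, dy, n_perm=199, seed=11)
        # common relabeling of both matrices leaves r unchanged
        perm = rng.permutation(dx.n)
        rx = dm(dx.permuted(perm))
        ry = dm(dy.permuted(perm))
        assert mantel(rx, ry, n_perm=9, seed=0).r == pytest.approx(a.r)

    def test_matches_exhaustive_relabeling_oracle_at_n4(self, rng):
        """The permutation p approximates the exact p over all 4! = 24
        simultaneous relabelings of one matrix."""
        dx, dy = random_dm(rng, 4), random_dm(rng, 4)
        y = dy.condensed()
        r_obs = pearsonr(dx.condensed(), y)[0]
        null = [pearsonr(squareform(dx.permuted(p), checks=False), y)[0]
                for p in itertools.permutations(range(4))]
        p_exact = np.mean(np.abs(null) >= abs(r_obs) - 1e-12)
        res = mantel(dx, dy, n_perm=4999, seed=2)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(p_exact, abs=0.03)

    def test_skbio_cross_check(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel
        dx, dy = random_dm(rng, 8), random_dm(rng, 8)
        r_ref, _, _ = sk_mantel(SkDM(np.array(dx.values)),
                                SkDM(np.array(dy.values)), permutations=1)
        assert mantel(dx, dy, n_perm=9, seed=0).r == pytest.approx(r_ref)


class TestPartialMantel:
    def test_uncorrelated_covariate_recovers_simple_r(self, rng):
        # build dz orthogonal to dx and dy triangles via regression residuals
        dx, dy = random_dm(rng, 7), random_dm(rng, 7)
        x, y = dx.condensed(), dy.condensed()
        z = rng.random(x.size)
        basis = np.column_stack([np.ones_like(x), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        dz = dm(squareform(z - z.min() + 0.1))
        res = partial_mantel(dx, dy, dz, n_perm=49, seed=0)
        simple = mantel(dx, dy, n_perm=9, seed=0)
        assert res.r == pytest.approx(simple.r, abs=1e-9)

    def test_closed_form_on_toy_triple(self, rng):
        dx, dy, dz = (random_dm(rng, 5) for _ in range(3))
        x, y, z = dx.condensed(), dy.condensed(), dz.condensed()
        r = lambda u, v: pearsonr(u, v)[0]
        expected = (r(x, y) - r(x, z) * r(y, z)) / np.sqrt(
            (1 - r(x, z) ** 2) * (1 - r(y, z) ** 2))
        res = partial_mantel(dx, dy, dz, n_perm=49, seed=0)
        assert res.r == pytest.approx(expected)
        assert res.partial and 0 < res.p <= 1

    def test_covariate_equal_to_input_signalled(self, rng):
        dx, dy = random_dm(rng, 5), random_dm(rng, 5)
        with pytest.raises(ValidationError):
            partial_mantel(dx, dy, dy, n_perm=9)


class TestMrm:
    def test_exact_linear_relation(self, rng):
        d = random_dm(rng, 6)
        resp = dm(2.0 * d.values + (1 - np.eye(6)))
        fit = mrm(resp, [d], n_perm=99, seed=0)
        assert fit.slopes[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_predictor_normal_equations(self, rng):
        d1, d2 = random_dm(rng, 4), random_dm(rng, 4)
        resp = random_dm(rng, 4)
        X = np.column_stack([np.ones(6), d1.condensed(), d2.condensed()])
        expected = np.linalg.solve(X.T @ X, X.T @ resp.condensed())
        fit = mrm(resp, [d1, d2], n_perm=9, seed=0)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        d = random_dm(rng, 5)
        d2 = dm(2 * d.values)
        with pytest.raises(ValidationError):
            mrm(random_dm(rng, 5), [d, d2], n_perm=9)

    def test_partition_coefficient_additivity(self, rng):
        """MRM coefficients for beta_sor equal the sums of those for
        beta_sim and beta_sne against any shared predictor set."""
        m = random_community(rng, 9, 20)
        bsor, bsim, bsne = pairwise_matrices(m)
        attr = rng.random(9)
        pred = dm(np.abs(np.subtract.outer(attr, attr)), bsor.labels)
        fits = [mrm(r, [pred], n_perm=9, seed=0) for r in (bsor, bsim, bsne)]
        np.testing.assert_allclose(
            fits[0].coefficients, fits[1].coefficients + fits[2].coefficients,
            atol=1e-10)

    def test_single_predictor_slope_sign_matches_mantel(self, rng):
        dx, dy = random_dm(rng, 8), random_dm(rng, 8)
        fit = mrm(dy, [dx], n_perm=9, seed=0)
        mt = mantel(dx, dy, n_perm=9, seed=0)
        assert np.sign(fit.slopes[0]) == np.sign(mt.r)
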