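import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betanest import (
    CommunityMatrix, PairCounts, ValidationError, alternative_partitions,
    beta_ratio, multisite_partition, pair_counts, pairwise_matrices,
    resampled_multisite, sorensen_nestedness_product, sorensen_partition,
)
from .conftest import random_community

counts = st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
                   ).filter(lambda t: sum(t) > 0).map(lambda t: PairCounts(*t))


def test_pair_counts_set_arithmetic():
    x = np.array([1, 1, 1, 0])  # {s1,s2,s3}
    y = np.array([0, 1, 1, 1])  # {s2,s3,s4}
    assert pair_counts(x, y) == (2, 1, 1)
    assert pair_counts(x, x) == (3, 0, 0)
    assert pair_counts(x, 1 - x) == (0, 3, 1)
    with pytest.raises(ValidationError):
        pair_counts(x, y[:3])


@pytest.mark.parametrize("pc, expected", [
    (PairCounts(3, 2, 0), (0.25, 0.0, 0.25)),   # nested pair: no turnover
    (PairCounts(2, 1, 1), (1 / 3, 1 / 3, 0.0)),  # balanced: no nestedness
    (PairCounts(1, 2, 1), (0.6, 0.5, 0.1)),
])
def test_sorensen_partition_hand_values(pc, expected):
    got = sorensen_partition(pc)
    assert got == pytest.approx(expected)
    assert sorensen_nestedness_product(pc) == pytest.approx(expected[2])


def test_both_sites_empty_is_signalled():
    with pytest.raises(ValidationError):
        sorensen_partition(PairCounts(0, 0, 0))


@settings(max_examples=300, deadline=None)
@given(counts)
def test_additivity_and_product_form(pc):
    """beta_sor = beta_sim + beta_sne exactly, and the closed-form product
    expression for beta_sne equals the subtraction."""
    b = sorensen_partition(pc)
    assert abs(b.beta_sor - (b.beta_sim + b.beta_sne)) <= 1e-12
    assert abs(sorensen_nestedness_product(pc) - b.beta_sne) <= 1e-12
    assert 0 <= b.beta_sim <= b.beta_sor <= 1


@settings(max_examples=200, deadline=None)
@given(counts, st.sampled_from(["jaccard", "carvalho"]))
def test_alternative_families_are_additive(pc, family):
    tot, comp1, comp2 = alternative_partitions(pc, family)
    assert abs(tot - (comp1 + comp2)) <= 1e-12


def test_alternative_family_hand_values():
    jac = alternative_partitions(PairCounts(2, 1, 1), "jaccard")
    assert jac == pytest.approx((0.5, 0.5, 0.0))
    assert alternative_partitions(PairCounts(3, 2, 0), "jaccard")[1] == 0.0
    carv = alternative_partitions(PairCounts(3, 2, 0), "carvalho")
    assert carv[1] == 0.0 and carv[2] == pytest.approx(0.4)


class TestPairwiseMatrices:
    def test_identical_sites_give_zero(self):
        inc = np.array([[1, 1, 0], [1, 1, 0]])
        m = CommunityMatrix(("a", "b"), ("x", "y", "z"), inc)
        for d in pairwise_matrices(m):
            assert np.all(d.values == 0)

    def test_three_site_toy(self):
        m = CommunityMatrix(("A", "B", "C"), ("1", "2", "3", "4"),
                            np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]]))
        bsor, bsim, bsne = pairwise_matrices(m)
        assert bsor.to_frame().loc["A", "C"] == 1.0
        assert bsim.to_frame().loc["A", "C"] == 1.0
        assert bsne.to_frame().loc["A", "C"] == 0.0

    def test_elementwise_additivity_and_bound(self, rng):
        m = random_community(rng, 10, 20)
        bsor, bsim, bsne = pairwise_matrices(m)
        np.testing.assert_allclose(bsor.values, bsim.values + bsne.values,
                                   atol=1e-12)
        assert (bsim.values <= bsor.values + 1e-12).all()

    def test_empty_site_instructs_dropping(self):
        m = CommunityMatrix(("a", "b"), ("x", "y"), np.array([[1, 0], [0, 0]]))
        with pytest.raises(ValidationError, match="drop_empty_sites"):
            pairwise_matrices(m)


class TestMultisite:
    def test_two_sites_reduces_to_pairwise(self, rng):
        for _ in range(25):
            m = random_community(rng, 2, rng.integers(3, 15))
            pc = pair_counts(m.incidence[0], m.incidence[1])
            pw = sorensen_partition(pc)
            ms = multisite_partition(m)
            assert ms.beta_SOR == pytest.approx(pw.beta_sor, abs=1e-12)
            assert ms.beta_SIM == pytest.approx(pw.beta_sim, abs=1e-12)

    def test_three_site_toy_counts(self):
        m = CommunityMatrix(("A", "B", "C"), ("1", "2", "3", "4"),
                            np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]]))
        ms = multisite_partition(m)
        assert ms.beta_SOR == pytest.approx(8 / 12)
        assert ms.beta_SIM == pytest.approx(8 / 12)
        assert ms.beta_SNE == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_nested_has_zero_turnover(self):
        inc = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0], [1, 0, 0, 0, 0]])
        ms = multisite_partition(CommunityMatrix(("a", "b", "c"),
                                                 tuple("vwxyz"), inc))
        assert ms.beta_SIM == 0.0
        assert beta_ratio(ms) == 1.0
        assert ms.dominance == "nestedness-dominated"

    def test_additivity_and_permutation_invariance(self, rng):
        m = random_community(rng, 9, 18)
        ms = multisite_partition(m)
        assert abs(ms.beta_SOR - (ms.beta_SIM + ms.beta_SNE)) <= 1e-12
        inc = np.asarray(m.incidence)
        perm = inc[rng.permutation(9)][:, rng.permutation(18)]
        ms2 = multisite_partition(perm)
        assert ms2.beta_SOR == pytest.approx(ms.beta_SOR, abs=1e-14)
        assert ms2.beta_SIM == pytest.approx(ms.beta_SIM, abs=1e-14)

    def test_beta_ratio_undefined_when_identical(self):
        inc = np.array([[1, 1], [1, 1]])
        ms = multisite_partition(inc)
        with pytest.raises(ValidationError):
            beta_ratio(ms)


class TestResampling:
    def test_full_subset_equals_full_matrix(self, rng):
        m = random_community(rng, 8, 16)
        full = multisite_partition(m)
        rs = resampled_multisite(m, subset_size=8, n_samples=10, seed=1)
        assert rs.mean.beta_SOR == pytest.approx(full.beta_SOR, abs=1e-12)
        assert rs.sd_SOR <= 1e-12

    def test_same_seed_identical_and_additive(self, rng):
        m = random_community(rng, 12, 25)
        a = resampled_multisite(m, 8, 30, seed=7)
        b = resampled_multisite(m, 8, 30, seed=7)
        assert a == b
        assert a.mean.beta_SOR == pytest.approx(
            a.mean.beta_SIM + a.mean.beta_SNE, abs=1e-12)

    def test_means_converge_toward_full_value(self, rng):
        m = random_community(rng, 14, 30)
        full = multisite_partition(m).beta_SOR
        err = [abs(resampled_multisite(m, k, 150, seed=3).mean.beta_SOR - full)
               for k in (4, 13)]
        assert err[1] < err[0]

    def test_invalid_sizes(self, rng):
        m = random_community(rng, 5, 10)
        with pytest.raises(ValidationError):
            resampled_multisite(m, 1, 10)
        with pytest.raises(ValidationError):
            resampled_multisite(m, 6, 10)
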