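import itertools

import numpy as np
import pandas as pd
import pytest

from galldiv import beta_sample, distribution_difference, multisite_beta
from galldiv.core_io import EmptySiteError, IncidenceMatrix

from conftest import brute_multisite, matrix_from_sets, random_incidence, site_sets


class TestMultisiteBeta:
    def test_pure_turnover_triplet(self):
        # {s1,s2},{s2,s3},{s3,s4}: Σmin = Σmax = 4, K = 2
        m = matrix_from_sets(
            {"A": {"s1", "s2"}, "B": {"s2", "s3"}, "C": {"s3", "s4"}}
        )
        beta = multisite_beta(m)
        assert beta.beta_sim == pytest.approx(4 / 6)
        assert beta.beta_sor == pytest.approx(8 / 12)
        assert beta.beta_sne == pytest.approx(0.0, abs=1e-12)

    def test_strict_nested_chain(self):
        # {1,2,3,4} ⊃ {1,2,3} ⊃ {1,2}: Σmin = 0, Σmax = 4, K = 5
        m = matrix_from_sets(
            {"A": {"1", "2", "3", "4"}, "B": {"1", "2", "3"}, "C": {"1", "2"}}
        )
        beta = multisite_beta(m)
        assert beta.beta_sim == 0.0
        assert beta.beta_sor == pytest.approx(4 / 14)
        assert beta.beta_sne == pytest.approx(4 / 14)

    def test_identical_sites_all_zero(self):
        m = matrix_from_sets({s: {"a", "b", "c"} for s in ("A", "B", "C", "D")})
        beta = multisite_beta(m)
        assert (beta.beta_sor, beta.beta_sim, beta.beta_sne) == (0.0, 0.0, 0.0)

    def test_requires_two_sites_and_no_empties(self):
        with pytest.raises(ValueError, match="at least 2"):
            multisite_beta(matrix_from_sets({"A": {"x"}}))
        m = IncidenceMatrix(pd.DataFrame({"sp": [1, 1, 0]}, index=["A", "B", "C"]))
        with pytest.raises(EmptySiteError):
            multisite_beta(m)
        assert multisite_beta(m, drop_empty=True).n_sites == 2

    def test_brute_force_oracle_500_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            m = random_incidence(rng, rng.integers(3, 8), rng.integers(4, 14))
            beta = multisite_beta(m)
            sor, sim, sne = brute_multisite(site_sets(m))
            assert beta.beta_sor == pytest.approx(sor, abs=1e-12)
            assert beta.beta_sim == pytest.approx(sim, abs=1e-12)
            assert beta.beta_sne == pytest.approx(sne, abs=1e-12)

    def test_identity_and_bounds_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            m = random_incidence(rng, 6, 10)
            beta = multisite_beta(m)
            assert 0.0 <= beta.beta_sim <= beta.beta_sor <= 1.0
            assert beta.beta_sne == pytest.approx(beta.beta_sor - beta.beta_sim, abs=1e-12)
            assert beta.beta_sne >= -1e-12

    def test_whole_set_beta_at_least_mean_of_subsets(self, study_sim):
        """Multi-site dissimilarity grows with the number of sites: the
        full-survey value is >= the mean over random smaller subsets."""
        plants, _, _, _ = study_sim
        full = multisite_beta(plants).beta_sor
        dist = beta_sample(plants, subset_size=10, n_reps=200, seed=3)
        assert full >= dist.summary.at["beta_sor", "mean"]


class TestBetaSample:
    def test_degenerate_subset_equals_full(self):
        rng = np.random.default_rng(1)
        m = random_incidence(rng, 5, 9)
        full = multisite_beta(m)
        dist = beta_sample(m, subset_size=5, n_reps=20, seed=0)
        assert np.allclose(dist.draws["beta_sor"], full.beta_sor)
        assert np.allclose(dist.draws["beta_sim"], full.beta_sim)
        assert int(dist.draws.nunique().max()) == 1  # zero-variance distribution

    def test_mean_matches_exhaustive_enumeration(self):
        """Monte-Carlo mean over C(4,3) = 4 possible subsets converges to the
        enumeration average (within 3 standard errors at 1000 reps)."""
        rng = np.random.default_rng(3)
        m = random_incidence(rng, 4, 10)
        sets = site_sets(m)
        expected = np.mean(
            [brute_multisite([sets[i] for i in combo]) for combo in itertools.combinations(range(4), 3)],
            axis=0,
        )  # (sor, sim, sne)
        dist = beta_sample(m, subset_size=3, n_reps=1000, seed=9)
        for col, exp in zip(("beta_sor", "beta_sim", "beta_sne"), expected):
            draws = dist.draws[col]
            se = draws.std(ddof=1) / np.sqrt(len(draws))
            assert abs(draws.mean() - exp) <= max(3 * se, 1e-12)

    def test_same_seed_bitwise_identical(self):
        m = random_incidence(np.random.default_rng(5), 8, 12)
        d1 = beta_sample(m, subset_size=4, n_reps=50, seed=123)
        d2 = beta_sample(m, subset_size=4, n_reps=50, seed=123)
        assert (d1.draws.to_numpy() == d2.draws.to_numpy()).all()

    def test_every_draw_satisfies_identity(self):
        m = random_incidence(np.random.default_rng(8), 9, 15)
        dist = beta_sample(m, subset_size=4, n_reps=100, seed=1)
        d = dist.draws
        assert np.allclose(d["beta_sor"], d["beta_sim"] + d["beta_sne"], atol=1e-12)

    def test_subset_size_bounds(self):
        m = random_incidence(np.random.default_rng(2), 4, 6)
        with pytest.raises(ValueError, match="exceeds"):
            beta_sample(m, subset_size=5, n_reps=5, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            beta_sample(m, subset_size=1, n_reps=5, seed=0)


class TestDistributionDifference:
    @staticmethod
    def _dist(values):
        draws = pd.DataFrame(
            {"beta_sor": values, "beta_sim": values, "beta_sne": np.zeros(len(values))}
        )
        from galldiv.beta_multisite import BetaSampleDistribution

        return BetaSampleDistribution(
            subset_size=2, n_reps=len(values), seed=0, draws=draws,
            summary=pd.DataFrame({"mean": draws.mean(), "sd": draws.std(ddof=1)}),
        )

    def test_identical_distributions_give_half(self):
        d = self._dist([0.1, 0.2, 0.3])
        cmp = distribution_difference(d, d, "beta_sim")
        assert cmp.prob_greater == pytest.approx(0.5)
        assert cmp.intervals_overlap

    def test_fully_separated_distributions(self):
        hi = self._dist([0.8, 0.9])
        lo = self._dist([0.1, 0.2])
        cmp = distribution_difference(hi, lo, "beta_sor")
        assert cmp.prob_greater == 1.0
        assert not cmp.intervals_overlap

    def test_interleaved_brute_force(self):
        d1 = self._dist([0.1, 0.3])
        d2 = self._dist([0.2, 0.4])
        cmp = distribution_difference(d1, d2, "beta_sim")
        assert cmp.prob_greater == pytest.approx(0.25)

    def test_unknown_component_rejected(self):
        d = self._dist([0.1])
        with pytest.raises(KeyError, match="unknown component"):
            distribution_difference(d, d, "beta_jac")
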