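"""Likelihood core: elementary pieces, oracle equivalence, MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from opennmix.count_data import CountDataset, PeriodScheme, SiteSeries
from opennmix.nmixture_core import (
    ModelParams,
    TruncationConfig,
    TruncationError,
    brute_force_site_loglik,
    dataset_loglik,
    emission_weights,
    fit_mle,
    site_loglik,
    transition_matrix,
)
from opennmix.synthetic_data import recovery_scenario, simulate_dataset


def single_params(lam=1.0, p=0.5, init=5.0):
    return ModelParams(lam={"all": lam}, p={"all": p}, init_mean=init)


@pytest.fixture
def scheme():
    return PeriodScheme(((2000, 2009),), ("all",))


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


class TestTransitionMatrix:
    def test_row_zero_is_point_mass_at_zero(self):
        T = transition_matrix(1.7, 6)
        assert T[0, 0] == 1.0
        assert not T[0, 1:].any()

    def test_unit_growth_row_one_is_poisson_one(self):
        T = transition_matrix(1.0, 30)
        expected = np.exp(-1.0) / np.array([math.factorial(n) for n in range(5)])
        np.testing.assert_allclose(T[1, :5], expected, rtol=1e-12)

    @pytest.mark.parametrize("lam,K", [(0.3, 4), (1.0, 7), (2.6, 3)])
    def test_folded_rows_sum_to_one(self, lam, K):
        T = transition_matrix(lam, K, fold=True)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_unfolded_rows_drop_tail(self):
        T = transition_matrix(2.0, 3)
        sums = T.sum(axis=1)
        assert sums[0] == 1.0
        assert np.all(sums[1:] < 1.0)

    def test_rejects_bad_growth(self):
        for lam in (0.0, -1.0, float("nan"), float("inf")):
            with pytest.raises(ValueError):
                transition_matrix(lam, 5)


class TestEmissionWeights:
    def test_perfect_detection_is_indicator(self):
        w = emission_weights(3, 1.0, 8)
        assert w[3] == 1.0
        assert w.sum() == 1.0

    def test_binomial_value(self):
        # P(y=1 | n=2, p=0.5) = 2 * 0.5^2
        assert emission_weights(1, 0.5, 5)[2] == pytest.approx(0.5)

    def test_zero_count_geometric_in_n(self):
        w = emission_weights(0, 0.5, 10)
        np.testing.assert_allclose(w, 0.5 ** np.arange(11), rtol=1e-12)

    def test_zero_below_count(self):
        assert not emission_weights(4, 0.3, 9)[:4].any()

    def test_count_above_bound_raises(self):
        with pytest.raises(TruncationError):
            emission_weights(7, 0.5, 6)


# ---------------------------------------------------------------------------
# forward pass against closed forms and the enumeration oracle
# ---------------------------------------------------------------------------


class TestSiteLoglik:
    def test_degenerate_empty_population(self, scheme):
        s = SiteSeries("z", (2003,), (0,))
        ll = site_loglik(s, single_params(init=0.0), scheme, TruncationConfig(K=5))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_perfect_detection_reduces_to_poisson_products(self, scheme):
        s = SiteSeries("x", (2000, 2001, 2002, 2003), (4, 5, 3, 6))
        params = single_params(lam=1.1, p=1.0, init=5.0)
        ll = site_loglik(s, params, scheme, TruncationConfig(K=300))
        closed = (stats.poisson.logpmf(4, 5.0) + stats.poisson.logpmf(5, 1.1 * 4)
                  + stats.poisson.logpmf(3, 1.1 * 5) + stats.poisson.logpmf(6, 1.1 * 3))
        assert ll == pytest.approx(closed, abs=1e-10)

    def test_year_outside_scheme_raises(self, scheme):
        s = SiteSeries("x", (1999, 2000), (1, 1))
        with pytest.raises(KeyError):
            site_loglik(s, single_params(), scheme, TruncationConfig(K=50))

    def test_count_above_K_raises(self, scheme):
        s = SiteSeries("x", (2000,), (80,))
        with pytest.raises(TruncationError):
            site_loglik(s, single_params(), scheme, TruncationConfig(K=50))

    def test_large_count_stability(self, scheme):
        # counts up to 12000 with modest detection stay finite and fast
        s = SiteSeries("big", (2000, 2001, 2002), (12000, 11800, 12100))
        params = single_params(lam=1.0, p=0.5, init=24000.0)
        ll = site_loglik(s, params, scheme, TruncationConfig(p_floor=0.1))
        assert np.isfinite(ll)


@settings(max_examples=120, deadline=None)
@given(data=st.data())
@pytest.mark.parametrize("fold", [False, True])
def test_forward_matches_enumeration(fold, data):
    """Forward pass equals explicit path enumeration on tiny instances."""
    scheme = PeriodScheme(((2000, 2001), (2002, 2003)), ("a", "b"))
    K = data.draw(st.integers(1, 6), label="K")
    span = data.draw(st.integers(1, 3), label="span")
    first = data.draw(st.integers(2000, 2004 - span), label="first")
    years = list(range(first, first + span))
    keep = [data.draw(st.booleans(), label=f"keep{j}") or j in (0, span - 1)
            for j in range(span)]
    obs_years = tuple(y for y, k in zip(years, keep) if k)
    counts = tuple(data.draw(st.integers(0, K), label=f"y{j}")
                   for j in range(len(obs_years)))
    s = SiteSeries("x", obs_years, counts)
    params = ModelParams(
        lam={"a": data.draw(st.floats(0.1, 2.5), label="lam_a"),
             "b": data.draw(st.floats(0.1, 2.5), label="lam_b")},
        p={"a": data.draw(st.floats(0.05, 1.0), label="p_a"),
           "b": data.draw(st.floats(0.05, 1.0), label="p_b")},
        # Lambda = 0 is an exact degenerate case; sub-normal means would
        # push the likelihood below the forward pass's pruning floor
        init_mean=data.draw(st.one_of(st.just(0.0), st.floats(0.05, 8.0)),
                            label="Lam"))
    trunc = TruncationConfig(K=K, fold_tail=fold)
    a = site_loglik(s, params, scheme, trunc)
    b = brute_force_site_loglik(s, params, scheme, trunc)
    assert a == pytest.approx(b, abs=1e-10)


class TestBruteForce:
    def test_budget_guard(self, scheme):
        s = SiteSeries("x", tuple(range(2000, 2008)), (2,) * 8)
        with pytest.raises(ValueError, match="budget"):
            brute_force_site_loglik(s, single_params(), scheme, TruncationConfig(K=30))

    def test_K_zero_only_zero_path(self, scheme):
        s = SiteSeries("x", (2000, 2001), (0, 0))
        params = single_params(lam=1.0, p=0.5, init=2.0)
        ll = brute_force_site_loglik(s, params, scheme, TruncationConfig(K=0))
        # only the all-zero trajectory contributes: Pois(0; 2) * 1 * 1
        assert ll == pytest.approx(stats.poisson.logpmf(0, 2.0), abs=1e-10)

    def test_probability_monotone_in_K(self, scheme):
        s = SiteSeries("x", (2000, 2001), (2, 3))
        params = single_params(lam=1.2, p=0.4, init=6.0)
        lls = [brute_force_site_loglik(s, params, scheme, TruncationConfig(K=K))
               for K in (3, 5, 8, 12)]
        assert all(b >= a for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# dataset-level likelihood
# ---------------------------------------------------------------------------


class TestDatasetLoglik:
    def make(self, scheme):
        s1 = SiteSeries("a", (2000, 2001, 2002), (4, 6, 5))
        s2 = SiteSeries("b", (2001, 2003), (2, 3))
        return CountDataset((s1, s2)), ModelParams(
            lam={"all": 1.05}, p={"all": 0.5}, init_mean={"a": 10.0, "b": 5.0})

    def test_additive_and_permutation_invariant(self, scheme):
        ds, params = self.make(scheme)
        trunc = TruncationConfig(K=80)
        total, parts = dataset_loglik(ds, params, scheme, trunc, per_site=True)
        assert total == pytest.approx(sum(parts.values()), abs=1e-12)
        flipped = CountDataset(ds.series[::-1])
        assert dataset_loglik(flipped, params, scheme, trunc) == pytest.approx(total)

    def test_two_identical_sites_double_the_value(self, scheme):
        s = SiteSeries("a", (2000, 2001), (3, 4))
        t = SiteSeries("b", (2000, 2001), (3, 4))
        params = ModelParams(lam={"all": 1.0}, p={"all": 0.5}, init_mean=8.0)
        trunc = TruncationConfig(K=60)
        one = dataset_loglik(CountDataset((s,)), params, scheme, trunc)
        two = dataset_loglik(CountDataset((s, t)), params, scheme, trunc)
        assert two == pytest.approx(2 * one, abs=1e-10)

    def test_error_names_offending_site(self, scheme):
        ds, params = self.make(scheme)
        with pytest.raises(TruncationError, match="'a'"):
            dataset_loglik(ds, params, scheme, TruncationConfig(K=3))

    def test_splitting_periods_with_equal_params_is_invariant(self):
        s = SiteSeries("a", tuple(range(2000, 2008)), (5, 7, 6, 4, 8, 5, 6, 7))
        ds = CountDataset((s,))
        whole = PeriodScheme(((2000, 2009),), ("w",))
        split = PeriodScheme(((2000, 2003), (2004, 2009)), ("u", "v"))
        trunc = TruncationConfig(K=120)
        ll1 = dataset_loglik(ds, ModelParams(lam={"w": 0.97}, p={"w": 0.4},
                                             init_mean=15.0), whole, trunc)
        ll2 = dataset_loglik(ds, ModelParams(lam={"u": 0.97, "v": 0.97},
                                             p={"u": 0.4, "v": 0.4},
                                             init_mean=15.0), split, trunc)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_doubling_K_leaves_loglik_unchanged(self, scheme):
        ds, params = self.make(scheme)
        trunc = TruncationConfig(p_floor=0.25)
        base = dataset_loglik(ds, params, scheme, trunc)
        doubled = dataset_loglik(ds, params, scheme, trunc.scaled(2.0))
        assert abs(doubled - base) < 1e-6
        assert doubled >= base - 1e-12  # dropped tail mass only grows with K


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


class TestFitMle:
    def test_perfect_detection_two_year_ratio_statistic(self):
        scheme = PeriodScheme(((2000, 2001),), ("s",))
        pairs = [(10, 12), (20, 18), (5, 6), (40, 44)]
        ds = CountDataset(tuple(SiteSeries(f"s{i}", (2000, 2001), yc)
                                for i, yc in enumerate(pairs)))
        params, ll, rep = fit_mle(ds, scheme, TruncationConfig(K=200),
                                  fix_p=1.0, n_starts=1)
        ratio = sum(b for _, b in pairs) / sum(a for a, _ in pairs)
        assert params.lam["s"] == pytest.approx(ratio, abs=1e-3)
        assert np.isfinite(ll)

    def test_recovers_growth_under_perfect_detection(self):
        sc = recovery_scenario(n_sites=100, seed=3, true_p=(1.0, 1.0, 1.0),
                               missing_prob=0.0)
        ds, truth = simulate_dataset(sc)
        from opennmix.count_data import UK_SCHEME
        params, _, _ = fit_mle(ds, UK_SCHEME, TruncationConfig(p_floor=1.0),
                               fix_p=1.0, n_starts=1)
        for key, true_lam in truth.lambda_table.items():
            assert params.lam[key] == pytest.approx(true_lam, abs=0.02)

    def test_empty_dataset_raises(self, scheme):
        with pytest.raises(ValueError):
            fit_mle(CountDataset(()), scheme, TruncationConfig(K=10))
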