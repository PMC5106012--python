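import numpy as np
import pytest

from helpers import random_dataset
from upmclock import (
    MethylationDataset,
    SimulationParams,
    UPMSearchOptions,
    ValidationError,
    average_rates,
    conditional_site_fit,
    conditional_times_fit,
    fit_mc,
    fit_upm,
    normalize_scale,
    rss_of,
    simulate_dataset,
)
from upmclock.upm import upm_rss_check


class TestConditionalSiteFit:
    def test_equals_clock_fit_at_chronological_ages(self, toy_dataset):
        rates, starts, rss = conditional_site_fit(toy_dataset, toy_dataset.ages)
        fit = fit_mc(toy_dataset)
        np.testing.assert_allclose(rates, fit.rates, rtol=1e-12)
        np.testing.assert_allclose(starts, fit.starts, rtol=1e-12)
        assert rss == pytest.approx(fit.rss, abs=1e-15)

    def test_time_rescaling_gauge(self):
        """Scaling candidate times by c scales rates by 1/c; starts, rss fixed."""
        ds = random_dataset(4, 4, seed=8)
        r1, s1, rss1 = conditional_site_fit(ds, ds.ages)
        c = 3.7
        r2, s2, rss2 = conditional_site_fit(ds, ds.ages * c)
        np.testing.assert_allclose(r2, r1 / c, rtol=1e-10)
        np.testing.assert_allclose(s2, s1, rtol=1e-8, atol=1e-12)
        assert rss2 == pytest.approx(rss1, rel=1e-10)

    def test_single_site_line(self):
        ds = MethylationDataset(["s"], ["a", "b"], np.array([[3.0, 5.0]]),
                                ages=np.array([1.0, 2.0]))
        rates, starts, _ = conditional_site_fit(ds, np.array([1.0, 2.0]))
        assert rates[0] == pytest.approx(2.0)
        assert starts[0] == pytest.approx(1.0)


class TestConditionalTimesFit:
    def test_single_site_closed_form_and_clipping(self):
        ds = MethylationDataset(["s"], ["a", "b", "c"],
                                np.array([[5.0, 9.0, -100.0]]),
                                ages=np.array([1.0, 2.0, 3.0]))
        t = conditional_times_fit(ds, np.array([2.0]), np.array([1.0]),
                                  lower_bound=1e-3)
        # t_j = (s_1j - s0) / r, clipped below
        np.testing.assert_allclose(t[:2], [2.0, 4.0], rtol=1e-12)
        assert t[2] == pytest.approx(1e-3)

    def test_rate_rescaling_gauge(self):
        ds = random_dataset(5, 4, seed=9)
        fit = fit_mc(ds)
        t1 = conditional_times_fit(ds, fit.rates, fit.starts, lower_bound=1e-9)
        t2 = conditional_times_fit(ds, fit.rates * 2.0, fit.starts, lower_bound=1e-9)
        np.testing.assert_allclose(t2, t1 / 2.0, rtol=1e-10)

    def test_matches_scalar_minimization(self):
        """Each t_j agrees with a 1-D numeric minimizer of its column RSS."""
        from scipy.optimize import minimize_scalar

        ds = random_dataset(5, 3, seed=10)
        fit = fit_mc(ds)
        t = conditional_times_fit(ds, fit.rates, fit.starts, lower_bound=1e-3)
        for j in range(ds.m):
            col = ds.values[:, j]

            def col_rss(x):
                return float(((col - fit.rates * x - fit.starts) ** 2).sum())

            res = minimize_scalar(col_rss, bounds=(1e-3, 1e4), method="bounded",
                                  options={"xatol": 1e-12})
            assert t[j] == pytest.approx(res.x, abs=1e-6)
            assert col_rss(t[j]) <= res.fun + 1e-8

    def test_all_zero_rates_rejected(self, toy_dataset):
        with pytest.raises(ValidationError):
            conditional_times_fit(toy_dataset, np.zeros(3), np.zeros(3))


class TestFitUPM:
    def test_recovers_chronological_ages_from_clock_data(self):
        """With t' = t and no noise the pacemaker collapses onto the clock."""
        sim = simulate_dataset(
            SimulationParams(n_sites=10, n_individuals=8, sigma_t2=0.0,
                             sigma_s2=0.0, seed=21)
        )
        fit = fit_upm(sim.dataset, UPMSearchOptions(seed=1))
        scale = float((sim.dataset.values**2).sum())
        assert fit.rss <= 1e-12 * scale
        np.testing.assert_allclose(fit.epigenetic_times, sim.dataset.ages,
                                   rtol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_fits_worse_than_clock(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 12)), int(rng.integers(3, 12))
        ds = random_dataset(n, m, seed=seed + 100, sigma_s2=float(rng.uniform(0.5, 5)))
        upm = fit_upm(ds, UPMSearchOptions(seed=seed))
        mc = fit_mc(ds)
        assert upm.rss <= mc.rss + 1e-8

    def test_rss_is_minimum_over_starts_and_recomputable(self):
        ds = random_dataset(6, 6, seed=30)
        fit = fit_upm(ds, UPMSearchOptions(n_starts=5, seed=2))
        assert len(fit.converged_rss_per_start) == 5
        assert fit.rss == pytest.approx(np.nanmin(fit.converged_rss_per_start))
        # parameters stored in the fit reproduce its reported rss
        assert upm_rss_check(ds, fit) == pytest.approx(fit.rss, rel=1e-9)

    def test_strategies_agree(self):
        """Alternating updates and SLSQP time search find the same optimum."""
        for seed in (1, 2):
            ds = random_dataset(10, 10, seed=seed, sigma_t2=0.15, sigma_s2=1.0)
            a = fit_upm(ds, UPMSearchOptions(strategy="alternating", seed=5))
            d = fit_upm(ds, UPMSearchOptions(strategy="direct-search", seed=5))
            assert abs(a.rss - d.rss) <= 1e-4 * a.rss

    def test_degenerate_identical_columns_rejected(self):
        values = np.tile(np.array([[1.0], [2.0]]), (1, 4))
        ds = MethylationDataset(["s0", "s1"], list("abcd"), values,
                                ages=np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValidationError, match="degenerate"):
            fit_upm(ds)

    def test_deterministic_under_seed(self):
        ds = random_dataset(8, 8, seed=42)
        f1 = fit_upm(ds, UPMSearchOptions(seed=3))
        f2 = fit_upm(ds, UPMSearchOptions(seed=3))
        np.testing.assert_array_equal(f1.epigenetic_times, f2.epigenetic_times)
        assert f1.rss == f2.rss


class TestGaugeAndNormalization:
    def test_rss_invariant_under_time_rate_rescaling(self):
        ds = random_dataset(5, 5, seed=13)
        fit = fit_upm(ds, UPMSearchOptions(seed=0))
        for c in (0.5, 2.0, 17.3):
            rss_scaled = rss_of(ds, fit.epigenetic_times * c, fit.rates / c,
                                fit.starts)
            assert rss_scaled == pytest.approx(fit.rss, rel=1e-12)

    def test_normalize_is_idempotent_and_collapses_gauge_orbit(self):
        ds = random_dataset(5, 5, seed=14)
        fit = fit_upm(ds, UPMSearchOptions(seed=0))  # already anchored
        again = normalize_scale(fit, ds.ages)
        np.testing.assert_allclose(again.epigenetic_times, fit.epigenetic_times,
                                   rtol=1e-12)
        np.testing.assert_allclose(again.rates, fit.rates, rtol=1e-12)
        # a point elsewhere on the gauge orbit maps back to the anchor
        from dataclasses import replace

        shifted = replace(fit, epigenetic_times=fit.epigenetic_times * 2.0,
                          rates=fit.rates / 2.0)
        back = normalize_scale(shifted, ds.ages)
        np.testing.assert_allclose(back.epigenetic_times, fit.epigenetic_times,
                                   rtol=1e-12)
        np.testing.assert_allclose(back.rates, fit.rates, rtol=1e-12)

    def test_rss_invariant_under_affine_gauge(self):
        """t -> a*t + b with compensating rates/starts never changes the RSS."""
        ds = random_dataset(5, 5, seed=13)
        fit = fit_upm(ds, UPMSearchOptions(seed=0))
        for a, b in ((2.0, 5.0), (0.5, -0.3), (1.0, 40.0)):
            new_rates = fit.rates / a
            rss = rss_of(ds, a * fit.epigenetic_times + b, new_rates,
                         fit.starts - new_rates * b)
            assert rss == pytest.approx(fit.rss, rel=1e-11)

    def test_normalization_preserves_rss(self):
        ds = random_dataset(4, 6, seed=15)
        fit = fit_upm(ds, UPMSearchOptions(seed=0))
        assert upm_rss_check(ds, fit) == pytest.approx(fit.rss, rel=1e-12)


class TestAverageRates:
    def test_hand_value(self):
        ds = MethylationDataset(["s"], ["a"], np.array([[5.0]]),
                                ages=np.array([2.0]))
        r = average_rates(ds, np.array([1.0]), np.array([2.0]))
        assert r[0, 0] == pytest.approx(2.0)

    def test_pairwise_ratios_constant_on_noiseless_pacemaker_data(self):
        """Defining pacemaker property: site-rate ratios are individual-free."""
        sim = simulate_dataset(
            SimulationParams(n_sites=6, n_individuals=7, sigma_t2=0.15,
                             sigma_s2=0.0, seed=31)
        )
        ds = sim.dataset
        r = average_rates(ds, sim.true_starts, ds.ages)
        for i in range(1, 6):
            ratios = r[i, :] / r[0, :]
            expected = sim.true_rates[i] / sim.true_rates[0]
            np.testing.assert_allclose(ratios, expected, rtol=1e-10)

    def test_clock_limit_recovers_site_rates(self):
        sim = simulate_dataset(
            SimulationParams(n_sites=4, n_individuals=5, sigma_t2=0.0,
                             sigma_s2=0.0, seed=32)
        )
        r = average_rates(sim.dataset, sim.true_starts, sim.dataset.ages)
        np.testing.assert_allclose(r, np.tile(sim.true_rates[:, None], (1, 5)),
                                   rtol=1e-10)

    def test_zero_time_rejected(self, toy_dataset):
        with pytest.raises(ValidationError):
            average_rates(toy_dataset, np.zeros(3),
                          np.array([0.0, 1.0, 2.0, 3.0]))


def test_fitted_average_rates_factor_into_site_times_individual_terms():
    """At the noiseless optimum, r_ij = r_i * (t'_j / t_j): a per-individual
    stretch applied uniformly across sites."""
    sim = simulate_dataset(
        SimulationParams(n_sites=5, n_individuals=6, sigma_t2=0.15,
                         sigma_s2=0.0, seed=33)
    )
    ds = sim.dataset
    fit = fit_upm(ds, UPMSearchOptions(seed=4))
    r_ij = average_rates(ds, fit.starts, ds.ages)
    delta = fit.epigenetic_times / ds.ages
    np.testing.assert_allclose(r_ij, np.outer(fit.rates, delta), rtol=1e-6,
                               atol=1e-10)
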