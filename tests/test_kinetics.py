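"""Kinetic estimators: arrival-rate fits, dwell-time mixture fits, and the
population-percentage and average-dwell formulas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fretbind import (
    ArrivalCurve,
    DwellHistogram,
    TraceSimConfig,
    accumulate_first_bindings,
    average_dwell_time,
    build_dwell_histogram,
    fit_arrival_curve,
    fit_dwell_distribution,
    population_fractions,
    select_model,
)
from fretbind.simulate import true_dwells

positive = st.floats(min_value=1e-3, max_value=1e3)


# ---------------------------------------------------------------------------
# accumulated first bindings


class TestAccumulate:
    def test_step_curve_normalized_by_targets(self):
        c = accumulate_first_bindings([1.0, 2.0, 3.0], n_targets=4,
                                      frame_interval=0.5)
        assert c.cumulative_fraction[-1] == pytest.approx(0.75)
        assert c.cumulative_fraction[0] == 0.0
        assert np.all(np.diff(c.cumulative_fraction) >= 0)

    def test_no_arrivals_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            c = accumulate_first_bindings([], n_targets=10)
        assert not c.cumulative_fraction.any()

    def test_more_arrivals_than_targets_rejected(self):
        with pytest.raises(ValueError):
            accumulate_first_bindings([1.0, 2.0], n_targets=1)

    def test_curve_within_binomial_envelope_of_growth_law(self):
        rate, n = 0.033, 2000
        rng = np.random.default_rng(37)
        arrivals = rng.exponential(1.0 / rate, n)
        c = accumulate_first_bindings(arrivals, n, duration=120.0)
        expected = 1.0 - np.exp(-rate * c.time)
        sd = np.sqrt(np.clip(expected * (1 - expected), 1e-12, None) / n)
        assert np.all(np.abs(c.cumulative_fraction - expected) < 4 * sd + 1.0 / n)


class TestArrivalFit:
    def test_noiseless_recovery_is_exact(self):
        """A=1, k=0.02/s at 0.5 nM -> kon_obs = 0.040 /s/nM."""
        t = np.arange(0, 300, 0.1)
        y = 1.0 * (1 - np.exp(-0.02 * t))
        fit = fit_arrival_curve(
            ArrivalCurve(t, y, n_targets=100, n_arrivals=100), concentration=0.5
        )
        assert fit.kon_obs == pytest.approx(0.040, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    @given(a=st.floats(0.2, 1.0), k=st.floats(0.005, 0.5))
    def test_noiseless_recovery_any_parameters(self, a, k):
        t = np.arange(0.0, 200.0, 0.5)
        y = a * (1 - np.exp(-k * t))
        fit = fit_arrival_curve(
            ArrivalCurve(t, y, n_targets=10, n_arrivals=10), concentration=1.0
        )
        assert fit.k == pytest.approx(k, rel=1e-4)
        assert fit.amplitude == pytest.approx(a, rel=1e-4)

    def test_all_zero_curve_fails_without_fabricated_rate(self):
        t = np.arange(0, 10, 0.1)
        fit = fit_arrival_curve(
            ArrivalCurve(t, np.zeros_like(t), n_targets=5, n_arrivals=0),
            concentration=1.0,
        )
        assert not fit.success and fit.k == 0.0 and np.isnan(fit.amplitude)

    def test_decreasing_curve_rejected(self):
        t = np.arange(5) * 1.0
        with pytest.raises(ValueError):
            fit_arrival_curve(
                ArrivalCurve(t, np.array([0, 0.5, 0.4, 0.6, 0.7]), 5, 4), 1.0
            )

    def test_stochastic_recovery_within_ten_percent(self):
        """500 molecules at kon_obs = 0.033 /s/nM, 1 nM."""
        rng = np.random.default_rng(41)
        arrivals = rng.exponential(1 / 0.033, 500)
        arrivals = arrivals[arrivals < 295.0]
        c = accumulate_first_bindings(arrivals, 500, duration=295.0)
        fit = fit_arrival_curve(c, concentration=1.0)
        assert abs(fit.kon_obs - 0.033) / 0.033 < 0.10


# ---------------------------------------------------------------------------
# dwell histogram


class TestDwellHistogram:
    def test_normalized_counts(self):
        h = build_dwell_histogram([0.15, 0.25, 0.25], bin_width=0.1,
                                  exclude_first_bin=False)
        np.testing.assert_allclose(h.normalized_counts[1], 1 / 3)
        np.testing.assert_allclose(h.normalized_counts[2], 2 / 3)
        assert h.normalized_counts.sum() == pytest.approx(1.0)

    def test_first_bin_excluded_from_fit_mask(self):
        h = build_dwell_histogram([0.2, 0.7, 1.2], bin_width=0.5,
                                  exclude_first_bin=True)
        assert not h.fit_mask[0] and h.fit_mask[1:].all()
        # normalization still counts the excluded bin's events
        assert h.normalized_counts.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_dwell_histogram([])

    def test_histogram_within_multinomial_envelope(self):
        p, ts, tl = 0.5, 1.6, 8.7
        cfg = TraceSimConfig(p_long=p, tau_short=ts, tau_long=tl, seed=43)
        d = true_dwells(cfg, n_events=20000)
        h = build_dwell_histogram(d, bin_width=0.5)
        lo, hi = h.bin_edges[:-1], h.bin_edges[1:]
        expect = p * (np.exp(-lo / tl) - np.exp(-hi / tl)) + (1 - p) * (
            np.exp(-lo / ts) - np.exp(-hi / ts)
        )
        sd = np.sqrt(expect * (1 - expect) / d.size)
        assert np.all(np.abs(h.normalized_counts - expect) < 4 * sd + 2 / d.size)


# ---------------------------------------------------------------------------
# population formulas


class TestPopulationFormulas:
    @pytest.mark.parametrize(
        "a1,t1,a2,t2,p1",
        [
            (1.0, 2.0, 1.0, 8.0, 0.2),
            (1.0, 1.0, 0.0, 5.0, 1.0),
            (5.355, 1.61, 1.0, 8.69, 0.498),  # ~equal event split
        ],
    )
    def test_event_fraction_formula(self, a1, t1, a2, t2, p1):
        f1, f2 = population_fractions(a1, t1, a2, t2)
        assert f1 == pytest.approx(p1, abs=5e-4)
        assert f1 + f2 == pytest.approx(1.0, abs=1e-15)

    def test_average_dwell_values(self):
        # single population reduces to tau
        assert average_dwell_time(1.0, 1.64, 0.0, 5.0) == pytest.approx(1.64)
        # two populations at ~50/50 with tau 1.61/8.69 -> ~5.16 s
        assert average_dwell_time(5.355, 1.61, 1.0, 8.69) == pytest.approx(
            5.16, abs=0.01
        )
        # degenerate mixture: equal taus give tau for any amplitudes
        assert average_dwell_time(3.0, 2.5, 7.0, 2.5) == pytest.approx(2.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_fractions(0.0, 1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            population_fractions(1.0, -1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            population_fractions(-1.0, 1.0, 1.0, 2.0)

    @given(a1=positive, t1=positive, a2=positive, t2=positive)
    def test_fractions_sum_to_one_and_average_is_bounded(self, a1, t1, a2, t2):
        f1, f2 = population_fractions(a1, t1, a2, t2)
        assert f1 + f2 == pytest.approx(1.0, abs=1e-12)
        avg = average_dwell_time(a1, t1, a2, t2)
        assert min(t1, t2) - 1e-9 <= avg <= max(t1, t2) + 1e-9

    @given(a1=positive, t1=st.floats(0.5, 2.0), a2=positive,
           t2=st.floats(2.5, 50.0), dt=st.floats(0.1, 10.0))
    def test_average_dwell_monotone_in_long_tau(self, a1, t1, a2, t2, dt):
        assert average_dwell_time(a1, t1, a2, t2 + dt) >= average_dwell_time(
            a1, t1, a2, t2
        )


# ---------------------------------------------------------------------------
# dwell distribution fitting


class TestDwellFit:
    def test_untruncated_exponential_mle_is_sample_mean(self):
        fit = fit_dwell_distribution([2.0, 2.0, 2.0], order=1, method="mle",
                                     truncation=0.0)
        assert fit.taus[0] == pytest.approx(2.0)
        assert fit.average_dwell == pytest.approx(2.0)

    def test_noiseless_single_exponential_ls(self):
        edges = np.arange(0.0, 20.5, 0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        h = DwellHistogram(
            bin_edges=edges,
            normalized_counts=0.26 * np.exp(-centers / 1.64),
            excluded_first_bin=True,
            n_events=1000,
        )
        fit = fit_dwell_distribution(h, order=1, method="ls")
        assert fit.taus[0] == pytest.approx(1.64, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["ls", "mle"])
    def test_two_population_recovery(self, method):
        """3000 dwells at p_long=0.5, tau 1.61/8.69 s, 0.1 s frames: a
        single replicate lands within the estimators' sampling spread."""
        cfg = TraceSimConfig(p_long=0.5, tau_short=1.61, tau_long=8.69,
                             frame_interval=0.1, seed=47)
        d = true_dwells(cfg, n_events=3000, quantize=True)
        fit = fit_dwell_distribution(d, order=2, method=method,
                                     resolution=0.1 if method == "mle" else 0.0)
        assert fit.success and fit.order == 2
        # ~3 sigma of the per-replicate spread at this n
        assert abs(fit.taus[0] - 1.61) / 1.61 < 0.25
        assert abs(fit.taus[1] - 8.69) / 8.69 < 0.25
        assert abs(fit.fractions[0] - 0.5) < 0.12
        assert fit.taus[0] < fit.taus[1]
        assert sum(fit.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_ls_and_mle_agree_on_large_sample(self):
        cfg = TraceSimConfig(p_long=0.5, tau_short=1.6, tau_long=8.7, seed=53)
        d = true_dwells(cfg, n_events=100_000)
        f_ls = fit_dwell_distribution(d, order=2, method="ls")
        f_mle = fit_dwell_distribution(d, order=2, method="mle")
        for a, b in zip(f_ls.taus, f_mle.taus):
            assert abs(a - b) / b < 0.05
        assert abs(f_ls.fractions[0] - f_mle.fractions[0]) < 0.05

    def test_too_few_events_for_two_components(self):
        fit = fit_dwell_distribution([1.0] * 10, order=2, method="mle")
        assert not fit.success and "20" in fit.message

    def test_parameter_recovery_median_bias(self):
        """Median bias of each tau < 5% over 20 seeded replicates."""
        taus1, taus2 = [], []
        for seed in range(20):
            cfg = TraceSimConfig(p_long=0.5, tau_short=1.61, tau_long=8.69,
                                 seed=1000 + seed)
            d = true_dwells(cfg, n_events=3000, quantize=True)
            fit = fit_dwell_distribution(d, order=2, method="mle",
                                         resolution=0.1)
            taus1.append(fit.taus[0])
            taus2.append(fit.taus[1])
        assert abs(np.median(taus1) - 1.61) / 1.61 < 0.05
        assert abs(np.median(taus2) - 8.69) / 8.69 < 0.05


class TestModelSelection:
    @staticmethod
    def _fits(dwells, method, resolution=0.0):
        kw = dict(method=method)
        if method == "mle":
            kw["resolution"] = resolution
        f1 = fit_dwell_distribution(dwells, order=1, **kw)
        f2 = fit_dwell_distribution(dwells, order=2, **kw)
        return f1, f2

    @pytest.mark.parametrize("method", ["ls", "mle"])
    def test_single_population_selects_order_one(self, method):
        cfg = TraceSimConfig(p_long=0.0, tau_short=1.64, tau_long=1.64,
                             seed=59)
        d = true_dwells(cfg, n_events=3000, quantize=True)
        f1, f2 = self._fits(d, method, resolution=0.1)
        sel = select_model(f1, f2)
        assert sel.chosen_order == 1
        assert abs(f1.taus[0] - 1.64) / 1.64 < 0.05

    @pytest.mark.parametrize("method", ["ls", "mle"])
    def test_two_populations_select_order_two(self, method):
        cfg = TraceSimConfig(p_long=0.5, tau_short=1.6, tau_long=8.7, seed=61)
        d = true_dwells(cfg, n_events=1000, quantize=True)
        f1, f2 = self._fits(d, method, resolution=0.1)
        sel = select_model(f1, f2)
        assert sel.chosen_order == 2

    def test_collapsed_fit_selects_order_one_by_parsimony(self):
        rng = np.random.default_rng(67)
        d = rng.exponential(2.0, 5000)
        f1 = fit_dwell_distribution(d, order=1, method="mle")
        f2 = fit_dwell_distribution(d, order=2, method="mle")
        sel = select_model(f1, f2)
        assert sel.chosen_order == 1
        if f2.order == 1:  # collapsed tau1 ~ tau2
            assert sel.rule == "collapse"

    def test_mismatched_fits_rejected(self):
        f1 = fit_dwell_distribution([1.0, 2.0, 3.0] * 10, order=1, method="mle")
        f2 = fit_dwell_distribution([1.0, 2.0] * 20, order=2, method="mle")
        with pytest.raises(ValueError):
            select_model(f1, f2)
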