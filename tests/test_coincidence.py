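"""Coincidence matching, Stokes-Einstein sizing, cargo counts, gamma fits."""

import numpy as np
import pytest

from evfccs import (
    BurstSearchParams,
    SizeEstimationConfig,
    cargo_count,
    chance_coincidence_rate,
    coincidence_metrics,
    compute_tolerance_window,
    ev_size_from_burst,
    fit_gamma_size_distribution,
    match_coincident_bursts,
    size_cargo_histogram2d,
)
from evfccs.bursts import Burst, BurstSet, InsufficientDataError
from evfccs.coincidence import CoincidentEvent
from evfccs.photon_data import ConfigurationError


def burst_at(center, duration=2e-3, channel="g", n_photons=25):
    return Burst(channel=channel, start_time=center - duration / 2,
                 stop_time=center + duration / 2, n_photons=n_photons,
                 first_photon=0, last_photon=n_photons - 1)


def burst_set(centers, durations=None, channel="g"):
    durations = durations if durations is not None else [2e-3] * len(centers)
    bursts = [burst_at(c, d, channel) for c, d in zip(centers, durations)]
    params = BurstSearchParams(background_rate=200.0)
    stop = max((b.stop_time for b in bursts), default=1.0) + 1.0
    return BurstSet(channel=channel, params=params, bursts=bursts, duration=stop)


def optimal_match_count(cg, cr, window):
    """Oracle: maximum-cardinality one-to-one matching by exhaustion."""
    from itertools import permutations

    best = 0
    idx_r = list(range(len(cr))) + [None] * len(cg)
    for perm in permutations(idx_r, len(cg)):
        used = [j for j in perm if j is not None]
        if len(set(used)) != len(used):
            continue
        n = sum(
            1 for i, j in enumerate(perm)
            if j is not None and abs(cg[i] - cr[j]) <= window
        )
        best = max(best, n)
    return best


class TestToleranceWindow:
    def test_identical_distributions_give_zero(self):
        g = burst_set(np.arange(10) * 1.0, [3e-3] * 10, "green")
        r = burst_set(np.arange(10) * 1.0 + 0.5, [3e-3] * 10, "red")
        w = compute_tolerance_window(g, r)
        assert w.value == pytest.approx(0.0, abs=1e-12)

    def test_q10_difference_arithmetic(self):
        dg = np.full(10, 1e-3)
        dr = np.full(10, 3e-3)
        g = burst_set(np.arange(10) * 1.0, dg, "green")
        r = burst_set(np.arange(10) * 1.0 + 0.5, dr, "red")
        w = compute_tolerance_window(g, r)
        assert w.value == pytest.approx(1e-3)
        assert (w.q10_green, w.q10_red) == (pytest.approx(1e-3), pytest.approx(3e-3))

    def test_symmetric_under_channel_exchange(self):
        dg = np.linspace(1e-3, 5e-3, 12)
        dr = np.linspace(2e-3, 9e-3, 15)
        g = burst_set(np.arange(12) * 1.0, dg, "green")
        r = burst_set(np.arange(15) * 1.0 + 0.4, dr, "red")
        assert compute_tolerance_window(g, r).value == pytest.approx(
            compute_tolerance_window(r, g).value
        )

    def test_alternative_rules(self):
        dg = np.full(10, 1e-3)
        dr = np.full(10, 3e-3)
        g = burst_set(np.arange(10) * 1.0, dg, "green")
        r = burst_set(np.arange(10) * 1.0 + 0.2, dr, "red")
        assert compute_tolerance_window(g, r, "q10_min_half").value == pytest.approx(0.5e-3)
        with pytest.raises(ConfigurationError):
            compute_tolerance_window(g, r, "bogus")

    def test_too_few_bursts_rejected(self):
        g = burst_set([1.0], channel="green")
        r = burst_set([1.5], channel="red")
        with pytest.raises(InsufficientDataError):
            compute_tolerance_window(g, r)


class TestMatching:
    def test_identical_lists_fully_matched(self):
        centers = np.arange(8) * 1.0
        g = burst_set(centers, channel="green")
        r = burst_set(centers, channel="red")
        events, unmatched = match_coincident_bursts(g, r, 1e-3)
        assert len(events) == 8
        assert unmatched == {"n_green_unmatched": 0, "n_red_unmatched": 0}

    def test_disjoint_lists_no_matches(self):
        g = burst_set(np.arange(5) * 1.0, channel="green")
        r = burst_set(np.arange(5) * 1.0 + 0.5, channel="red")
        events, _ = match_coincident_bursts(g, r, 1e-3)
        assert events == []

    def test_constructed_overlap_pattern(self):
        """5 green, 4 red, 3 centers within the window: exactly those 3
        matched, agreeing with the exhaustive optimal assignment."""
        cg = [1.0, 2.0, 3.0, 4.0, 10.0]
        cr = [1.0005, 2.0008, 3.0002, 7.0]
        w = 1e-3
        g = burst_set(cg, channel="green")
        r = burst_set(cr, channel="red")
        events, _ = match_coincident_bursts(g, r, w)
        assert len(events) == 3 == optimal_match_count(cg, cr, w)
        matched_pairs = {
            (e.green_burst.center_time, e.red_burst.center_time) for e in events
        }
        assert matched_pairs == {(1.0, 1.0005), (2.0, 2.0008), (3.0, 3.0002)}

    def test_greedy_matches_optimal_cardinality_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cg = np.sort(rng.uniform(0, 10, rng.integers(2, 5)))
            cr = np.sort(rng.uniform(0, 10, rng.integers(2, 5)))
            w = rng.uniform(0.05, 1.0)
            g = burst_set(cg, [1e-3] * len(cg), "green")
            r = burst_set(cr, [1e-3] * len(cr), "red")
            events, _ = match_coincident_bursts(g, r, w)
            assert len(events) == optimal_match_count(list(cg), list(cr), w)

    def test_symmetric_in_channel_roles(self):
        rng = np.random.default_rng(23)
        cg = np.sort(rng.uniform(0, 10, 6))
        cr = np.sort(rng.uniform(0, 10, 5))
        g = burst_set(cg, [1e-3] * 6, "green")
        r = burst_set(cr, [1e-3] * 5, "red")
        ev_a, _ = match_coincident_bursts(g, r, 0.5)
        ev_b, _ = match_coincident_bursts(r, g, 0.5)
        pairs_a = {(e.green_burst.center_time, e.red_burst.center_time) for e in ev_a}
        pairs_b = {(e.red_burst.center_time, e.green_burst.center_time) for e in ev_b}
        assert pairs_a == pairs_b

    def test_events_bounded_by_channel_counts(self):
        rng = np.random.default_rng(29)
        cg = np.sort(rng.uniform(0, 100, 40))
        cr = np.sort(rng.uniform(0, 100, 25))
        g = burst_set(cg, [1e-3] * 40, "green")
        r = burst_set(cr, [1e-3] * 25, "red")
        events, _ = match_coincident_bursts(g, r, 5.0)
        assert len(events) <= min(len(g), len(r))


class TestSizing:
    def test_transit_time_maps_to_90nm(self):
        b = burst_at(1.0, duration=3.776e-3, channel="green")
        size = ev_size_from_burst(b, SizeEstimationConfig())
        assert size == pytest.approx(90.0, rel=5e-3)

    def test_size_linear_in_duration(self):
        cfg = SizeEstimationConfig()
        s1 = ev_size_from_burst(burst_at(1.0, 2e-3, "green"), cfg)
        s2 = ev_size_from_burst(burst_at(1.0, 4e-3, "green"), cfg)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_channel_selects_waist(self):
        cfg = SizeEstimationConfig()
        sg = ev_size_from_burst(burst_at(1.0, 3e-3, "green"), cfg)
        sr = ev_size_from_burst(burst_at(1.0, 3e-3, "red"), cfg)
        assert sg / sr == pytest.approx((372 / 287) ** 2, rel=1e-9)

    def test_zero_duration_rejected(self):
        b = Burst(channel="green", start_time=1.0, stop_time=1.0, n_photons=25,
                  first_photon=0, last_photon=24)
        with pytest.raises(ValueError):
            ev_size_from_burst(b, SizeEstimationConfig())


class TestCargo:
    def _event(self, rate, n_photons=24):
        # duration chosen so the burst mean rate is exactly `rate`
        duration = n_photons / rate
        g = Burst(channel="green", start_time=0.0, stop_time=duration,
                  n_photons=n_photons, first_photon=0, last_photon=n_photons - 1)
        return CoincidentEvent(green_burst=g, red_burst=burst_at(0.001, channel="red"),
                               center_offset=0.0)

    def test_single_molecule(self):
        ev = self._event(rate=1200.0)  # eps + B with eps 1000, B 200
        raw, count = cargo_count(ev, brightness=1000.0, background_green=200.0)
        assert raw == pytest.approx(1.0, rel=1e-9)
        assert count == 1

    def test_background_only_burst_counts_zero(self):
        ev = self._event(rate=200.0)
        raw, count = cargo_count(ev, brightness=1000.0, background_green=200.0)
        assert (raw, count) == (0.0, 0)

    def test_rounding_half_away_from_zero(self):
        ev = self._event(rate=2500.0 + 200.0)
        raw, count = cargo_count(ev, brightness=1000.0, background_green=200.0)
        assert raw == pytest.approx(2.5, rel=1e-9)
        assert count == 3

    def test_invalid_brightness_rejected(self):
        with pytest.raises(ConfigurationError):
            cargo_count(self._event(1000.0), brightness=0.0, background_green=0.0)


class TestGammaFit:
    def test_recovers_known_gamma_parameters(self):
        rng = np.random.default_rng(41)
        sizes = rng.gamma(shape=4.0, scale=25.0, size=500)  # mean 100 nm
        fit = fit_gamma_size_distribution(sizes)
        assert fit.mean == pytest.approx(100.0, rel=0.10)

    def test_exponential_special_case(self):
        rng = np.random.default_rng(43)
        sizes = rng.gamma(shape=1.0, scale=100.0, size=1000)
        fit = fit_gamma_size_distribution(sizes)
        assert 0.8 <= fit.alpha <= 1.2

    def test_mle_mean_equals_sample_mean(self):
        rng = np.random.default_rng(47)
        sizes = rng.gamma(shape=3.0, scale=30.0, size=400)
        fit = fit_gamma_size_distribution(sizes, method="mle")
        assert fit.mean == pytest.approx(float(sizes.mean()), rel=1e-3)

    def test_degenerate_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_size_distribution(np.full(100, 90.0))

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_size_distribution(np.concatenate([[0.0], np.ones(99)]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gamma_size_distribution(np.ones(10) + np.arange(10))


class TestMetrics:
    def _events(self, n):
        return [
            CoincidentEvent(
                green_burst=burst_at(i * 1.0, channel="green"),
                red_burst=burst_at(i * 1.0, channel="red"),
                center_offset=0.0,
            )
            for i in range(n)
        ]

    def test_rate_unit_is_events_per_minute(self):
        red = burst_set(np.arange(100) * 6.0, channel="red")
        rate, y = coincidence_metrics(self._events(27), red, duration=600.0)
        assert rate == pytest.approx(2.7)
        assert y == pytest.approx(27 / 100)

    def test_no_events_zero_metrics(self):
        red = burst_set(np.arange(10) * 1.0, channel="red")
        rate, y = coincidence_metrics([], red, duration=60.0)
        assert (rate, y) == (0.0, 0.0)

    def test_chance_rate_formula(self):
        assert chance_coincidence_rate(2.0, 3.0, 1e-3) == pytest.approx(0.012)


class TestHistogram2D:
    def _annotated_events(self):
        events = []
        for size, cargo in [(85.0, 2), (95.0, 2), (150.0, 1)]:
            ev = CoincidentEvent(
                green_burst=burst_at(1.0, channel="green"),
                red_burst=burst_at(1.0, channel="red"), center_offset=0.0,
                size_green_nm=size, size_red_nm=size, cargo_count_raw=float(cargo),
                cargo_count=cargo,
            )
            events.append(ev)
        return events

    def test_single_event_single_cell(self):
        events = self._annotated_events()[:1]
        h = size_cargo_histogram2d(events, [0, 100, 200], [0, 1, 2, 3])
        assert h.sum() == 1
        assert h[0, 2] == 1

    def test_marginal_matches_1d_histogram(self):
        events = self._annotated_events()
        size_bins = [0, 100, 200]
        h = size_cargo_histogram2d(events, size_bins, [0, 1, 2, 3])
        sizes = [e.size_green_nm for e in events]
        marg, _ = np.histogram(sizes, bins=size_bins)
        np.testing.assert_array_equal(h.sum(axis=1), marg)
        assert h.sum() == len(events)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            size_cargo_histogram2d(self._annotated_events(), [100], [0, 1])
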