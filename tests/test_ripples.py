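"""Ripple detection, chance control, channel QC, rates, coincidence, states."""

import numpy as np
import pytest

from ripplemem.ripples import (ChannelQC, RippleEvent, chance_count,
                               coincidence, detect_ripples,
                               dual_state_proportion, select_channels,
                               time_resolved_rate)

RATE = 1000.0


def _trace_with_burst(rng, dur_s=30.0, burst_t=12.0, burst_dur=0.060,
                      carrier=100.0, amp=8.0):
    n = int(dur_s * RATE)
    x = rng.standard_normal(n)
    m = int(burst_dur * RATE)
    t = np.arange(m) / RATE
    burst = np.hanning(m) * np.sin(2 * np.pi * carrier * t)
    burst *= amp / np.abs(burst).max()
    i0 = int((burst_t - burst_dur / 2) * RATE)
    x[i0 : i0 + m] += burst
    return x


class TestDetect:
    def test_zero_trace_no_events(self):
        with pytest.warns(UserWarning, match="envelope"):
            ev = detect_ripples(np.zeros(20000), RATE, [(2.0, 18.0)])
        assert ev == []

    def test_single_burst_found_at_center(self, rng):
        x = _trace_with_burst(rng)
        ev = detect_ripples(x, RATE, [(1.0, 29.0)], channel="H")
        assert len(ev) == 1
        assert abs(ev[0].peak - 12.0) < 0.010
        assert ev[0].peak_z >= 5.0
        assert 0.020 <= ev[0].duration <= 0.100

    def test_overlong_burst_rejected(self, rng):
        x = rng.standard_normal(int(30 * RATE))
        m = int(0.150 * RATE)
        t = np.arange(m) / RATE
        x[int(12 * RATE) : int(12 * RATE) + m] += 8.0 * np.sin(2 * np.pi * 100 * t)
        ev = detect_ripples(x, RATE, [(1.0, 29.0)])
        assert ev == []

    def test_edge_blanking_suppresses_boundary_events(self, rng):
        # burst right at an epoch edge is inside the +/-75 ms blanked zone
        x = _trace_with_burst(rng, burst_t=10.03)
        ev = detect_ripples(x, RATE, [(10.0, 29.0)])
        assert ev == []

    def test_events_satisfy_invariants(self, rng):
        x = rng.standard_normal(int(60 * RATE))
        for bt in (5.0, 15.0, 25.0, 35.0, 45.0):
            m = int(0.06 * RATE)
            t = np.arange(m) / RATE
            x[int(bt * RATE) : int(bt * RATE) + m] += \
                8.0 * np.hanning(m) * np.sin(2 * np.pi * 120 * t)
        ev = detect_ripples(x, RATE, [(1.0, 59.0)])
        assert len(ev) >= 3
        for e in ev:
            assert e.onset <= e.peak <= e.offset
            assert 0.020 <= e.duration <= 0.100
            assert e.peak_z >= 5.0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            detect_ripples(np.zeros(1000), 250.0, [(0.0, 1.0)])


class TestChance:
    def test_planted_events_exceed_chance(self, rng):
        x = rng.standard_normal(int(120 * RATE))
        for k in range(50):
            bt = 2.0 + k * 2.3
            m = int(0.05 * RATE)
            t = np.arange(m) / RATE
            x[int(bt * RATE) : int(bt * RATE) + m] += \
                8.0 * np.hanning(m) * np.sin(2 * np.pi * 110 * t)
        epochs = [(0.5, 119.5)]
        real = len(detect_ripples(x, RATE, epochs))
        surr = chance_count(x, RATE, epochs, seed=0)
        assert real > surr

    def test_noise_counts_near_chance(self, rng):
        x = rng.standard_normal(int(120 * RATE))
        epochs = [(0.5, 119.5)]
        real = len(detect_ripples(x, RATE, epochs))
        surr = chance_count(x, RATE, epochs, seed=1)
        # both are rare-event counts on noise: Poisson-compatible difference
        assert abs(real - surr) <= 3 * np.sqrt(max(real + surr, 1.0))

    def test_reproducible(self, rng):
        x = rng.standard_normal(int(30 * RATE))
        a = chance_count(x, RATE, [(0.5, 29.5)], seed=7)
        b = chance_count(x, RATE, [(0.5, 29.5)], seed=7)
        assert a == b


class TestSelect:
    def test_single_qualifying_channel(self):
        qcs = select_channels([ChannelQC("c1", 100, 40.0)])
        assert qcs[0].selected

    def test_all_below_chance_excluded(self):
        qcs = select_channels([ChannelQC("c1", 10, 40.0),
                               ChannelQC("c2", 20, 40.0)])
        assert not any(q.selected for q in qcs)

    def test_argmax_count_selected(self):
        qcs = select_channels([ChannelQC("c1", 80, 40.0),
                               ChannelQC("c2", 120, 40.0)])
        sel = [q.channel for q in qcs if q.selected]
        assert sel == ["c2"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_channels([])


class TestRates:
    def test_no_events_zero_rate(self):
        t, r = time_resolved_rate([np.array([])] * 3, (-1.0, 0.0))
        assert np.all(r == 0)

    def test_single_event_rate_arithmetic(self):
        t, r = time_resolved_rate([np.array([0.0])], (-0.5, 0.5),
                                  bin_width=0.1, step=0.1, smooth_sigma=0)
        k = np.argmin(np.abs(t))
        assert r[k] == pytest.approx(10.0)

    def test_poisson_rate_recovered(self, rng):
        lam = 4.0
        trials = [np.sort(rng.uniform(0, 10, rng.poisson(lam * 10)))
                  for _ in range(200)]
        t, r = time_resolved_rate(trials, (0.0, 10.0), smooth_sigma=0)
        inner = r[(t > 0.5) & (t < 9.5)]
        assert abs(inner.mean() - lam) / lam < 0.1

    def test_rate_integral_conserves_count(self, rng):
        # with step == bin width (tiling bins) the integral equals the count
        ev = [np.sort(rng.uniform(0, 2, 7)) for _ in range(20)]
        t, r = time_resolved_rate(ev, (0.0, 2.0), bin_width=0.1, step=0.1,
                                  smooth_sigma=0)
        counts = r * 0.1
        assert counts.sum() == pytest.approx(np.mean([len(e) for e in ev]))


class TestCoincidence:
    def _ev(self, times):
        return [RippleEvent("c", t - 0.01, t, t + 0.01, 6.0) for t in times]

    def test_identical_trains_full(self):
        ev = self._ev([1.0, 2.0, 3.0])
        assert coincidence(ev, ev) == 100.0

    def test_disjoint_trains_zero(self):
        assert coincidence(self._ev([1.0]), self._ev([2.0])) == 0.0

    def test_partial_match_percentage(self):
        hpc = self._ev([1.0, 2.0, 3.0])
        amy = self._ev([1.02])
        assert coincidence(hpc, amy) == pytest.approx(100 / 3)

    def test_empty_hpc_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            coincidence([], self._ev([1.0]))


class TestDualState:
    def test_events_in_low_state_only(self):
        power = np.concatenate([np.zeros(500), np.ones(500)])
        lo, hi = dual_state_proportion(power, 1000.0, np.array([0.1, 0.2]))
        assert (lo, hi) == (1.0, 0.0)

    def test_uniform_events_split_evenly(self, rng):
        power = rng.standard_normal(100_000)
        events = rng.uniform(0, 100, 5000)
        lo, hi = dual_state_proportion(power, 1000.0, events)
        assert lo + hi == pytest.approx(1.0)
        assert abs(lo - 0.5) < 0.03

    def test_single_event_is_all_or_nothing(self):
        power = np.arange(1000.0)
        lo, hi = dual_state_proportion(power, 1000.0, np.array([0.9]))
        assert sorted((lo, hi)) == [0.0, 1.0]

    def test_median_ties_go_low(self):
        power = np.ones(1000)
        lo, hi = dual_state_proportion(power, 1000.0, np.array([0.5]))
        assert (lo, hi) == (1.0, 0.0)
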