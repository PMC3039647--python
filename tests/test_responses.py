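import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from careact import (
    EventSchedule,
    SpikeTrainSet,
    bin_event_responses,
    build_response_table,
    characterize,
    classify_selectivity,
    classify_unit_type,
    compute_baseline,
    normalize_response,
    smooth_rate,
    taxonomy_report,
)
from careact.containers import Event
from careact.responses import classify_intensity_dependence, ResponseTable


def simple_schedule(onsets, span, types=None, levels=None):
    types = types or ["drop"] * len(onsets)
    levels = levels if levels is not None else [0] * len(onsets)
    events = [Event(t, l, o, 0) for t, l, o in zip(types, levels, onsets)]
    return EventSchedule(events, baseline_span_s=onsets[0], span_s=span)


class TestBinning:
    def test_rate_arithmetic(self):
        spikes = SpikeTrainSet([np.array([100.1, 100.2, 100.3, 100.7])], span_s=200)
        sched = simple_schedule([100.0], 200)
        rates = bin_event_responses(spikes, sched)
        assert rates[0, 0, 0] == pytest.approx(6.0)  # 3 spikes / 0.5 s
        assert rates[0, 0, 1] == pytest.approx(2.0)

    def test_empty_train_zero_rates(self):
        spikes = SpikeTrainSet([np.array([])], span_s=200)
        rates = bin_event_responses(spikes, simple_schedule([100.0], 200))
        assert np.all(rates == 0)

    def test_windows_half_open(self):
        # spike exactly at the bin boundary belongs to the second bin
        spikes = SpikeTrainSet([np.array([100.5])], span_s=200)
        rates = bin_event_responses(spikes, simple_schedule([100.0], 200))
        assert rates[0, 0, 0] == 0 and rates[0, 0, 1] == pytest.approx(2.0)

    def test_mean_rate_matches_poisson_oracle(self, rng):
        # 10 Hz homogeneous unit over many events
        span = 5000.0
        train = np.sort(rng.uniform(0, span, rng.poisson(10 * span)))
        onsets = np.arange(50.0, span - 10, 5.0)
        sched = simple_schedule(list(onsets), span)
        spikes = SpikeTrainSet([train], span_s=span)
        rates = bin_event_responses(spikes, sched)
        mean = rates.mean()
        se = np.sqrt(10.0 / (len(onsets) * 1.0))
        assert abs(mean - 10.0) < 3 * se


class TestBaseline:
    def test_constant_rate_unit(self, rng):
        span = 2000.0
        train = np.sort(rng.uniform(0, span, rng.poisson(2 * span)))
        sched = simple_schedule([500.0, 700.0, 900.0], span)
        f0, g0 = compute_baseline(SpikeTrainSet([train], span_s=span), sched)
        assert abs(f0[0] - 2.0) < 3 * np.sqrt(2.0 / span)
        assert g0 == pytest.approx(f0[0])

    def test_spikes_only_in_event_windows(self):
        sched = simple_schedule([100.0], 300)
        spikes = SpikeTrainSet([np.array([100.5, 101.0, 102.9])], span_s=300)
        f0, _ = compute_baseline(spikes, sched)
        assert f0[0] == 0.0

    def test_no_eligible_time_errors(self):
        sched = simple_schedule([0.0], 3.0)
        with pytest.raises(ValueError):
            compute_baseline(SpikeTrainSet([np.array([1.0])], span_s=3.0), sched)


class TestNormalization:
    def test_identity_at_baseline(self):
        R, T = normalize_response(2.0, 2.0, 2.7)
        assert R == 0.0 and T == 0.0

    def test_worked_example(self):
        R, T = normalize_response(5.0, 1.0, 2.7)
        assert R == pytest.approx(4.0 / 3.7, abs=1e-4)
        assert T == pytest.approx(np.log(1 + 4.0 / 3.7), abs=1e-4)
        assert T == pytest.approx(0.7330, abs=1e-3)

    def test_low_rate_limit_absolute_change(self):
        R, _ = normalize_response(5.0, 0.0, 2.7)
        assert R == pytest.approx(5.0 / 2.7)

    def test_undefined_when_denominator_zero(self):
        with pytest.raises(ValueError):
            normalize_response(1.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f1=st.floats(0, 50),
        f2=st.floats(0, 50),
        f0=st.floats(0, 20),
        g0=st.floats(0.1, 20),
    )
    def test_T_monotone_in_event_rate(self, f1, f2, f0, g0):
        _, t1 = normalize_response(f1, f0, g0)
        _, t2 = normalize_response(f2, f0, g0)
        assert (t1 <= t2) == (f1 <= f2) or t1 == t2


class TestSelectivity:
    def make_sig(self, rows):
        types = ["sound", "air", "drop", "shake"]
        df = pd.DataFrame(rows, columns=types)
        df["responsive"] = df[types].any(axis=1)
        return df, types

    def test_label_definitions(self):
        sig, types = self.make_sig(
            [
                [True, True, True, True],
                [False, False, True, False],
                [True, False, True, False],
                [False, False, False, False],
            ]
        )
        labels = classify_selectivity(sig, types)
        assert labels.tolist() == [
            "general",
            "specific:drop",
            "subgeneral:drop+sound",
            "none",
        ]


class TestIntensity:
    def make_table(self, trial_rates, levels):
        """ResponseTable stub with given per-event 1-s rates."""
        rates = np.asarray(trial_rates)[None, :, None] * np.ones((1, 1, 2))
        sched = EventSchedule(
            [Event("drop", l, 100.0 + 200.0 * i, 0) for i, l in enumerate(levels)],
            baseline_span_s=100.0,
            span_s=100.0 + 200.0 * len(levels) + 100,
        )
        table = ResponseTable(
            rates=rates, bin_width_s=0.5, baseline_hz=np.array([1.0]),
            population_baseline_hz=2.7,
            type_mean_hz=pd.DataFrame({"drop": [np.mean(trial_rates)]}),
            R=pd.DataFrame({"drop": [0.5]}), T=pd.DataFrame({"drop": [0.4]}),
        )
        sig = pd.DataFrame({"drop": [True], "responsive": [True]})
        return table, sched, sig

    def test_identical_rates_invariant(self):
        levels = [1] * 7 + [2] * 7 + [3] * 7
        table, sched, sig = self.make_table([5.0] * 21, levels)
        out = classify_intensity_dependence(table, sched, sig, seed=0)
        assert out.iloc[0] == "invariant"

    def test_proportional_rates_sensitive_up(self):
        levels = [1] * 7 + [2] * 7 + [3] * 7
        rates = [float(l) for l in levels]
        table, sched, sig = self.make_table(rates, levels)
        out = classify_intensity_dependence(table, sched, sig, seed=0)
        assert out.iloc[0] == "sensitive-up"

    def test_decreasing_rates_sensitive_down(self):
        levels = [1] * 7 + [2] * 7 + [3] * 7
        rates = [10.0 / l for l in levels]
        table, sched, sig = self.make_table(rates, levels)
        out = classify_intensity_dependence(table, sched, sig, seed=0)
        assert out.iloc[0] == "sensitive-down"

    def test_single_level_undecidable(self):
        table, sched, sig = self.make_table([5.0] * 7, [1] * 7)
        out = classify_intensity_dependence(table, sched, sig, seed=0)
        assert out.iloc[0] == "n/a"


class TestUnitType:
    def test_csi_constructed_fixture(self):
        # 101 spikes: 30 first-lag ISIs of 5 ms with decreasing amplitude,
        # the rest widely spaced -> CSI = 30/100 = 30%
        times, amps = [0.0], [10.0]
        for i in range(30):
            times.append(times[-1] + 0.005)
            amps.append(amps[-1] - 0.01)
        for _ in range(70):
            times.append(times[-1] + 0.5)
            amps.append(10.0)
        cls, csi = classify_unit_type(np.array(times), np.array(amps), span_s=40.0)
        assert csi == pytest.approx(30.0)

    def test_constant_amplitude_csi_zero(self):
        train = np.arange(0, 1.0, 0.005)  # 5-ms ISIs but no amplitude decrease
        amps = np.ones_like(train)
        _, csi = classify_unit_type(train, amps, span_s=1.0, min_spikes=50)
        assert csi == 0.0

    def test_regular_slow_train_csi_zero(self):
        train = np.arange(0, 20, 0.1)  # 100-ms ISIs, never in the 2-15 ms band
        amps = np.linspace(2, 1, train.size)
        _, csi = classify_unit_type(train, amps, span_s=20.0)
        assert csi == 0.0

    def test_rate_thresholds(self):
        slow = np.arange(0, 100, 0.5)  # 2 Hz
        fast = np.arange(0, 100, 0.05)  # 20 Hz
        assert classify_unit_type(slow, span_s=100)[0] == "pyramidal"
        assert classify_unit_type(fast, span_s=100)[0] == "interneuron"
        assert classify_unit_type(np.array([1.0] * 10), span_s=100)[0] == "unknown"


class TestSmoothRate:
    def test_empty_train_zero(self):
        _, rate = smooth_rate(np.array([]), span_s=5.0)
        assert np.all(rate == 0)

    def test_integral_recovers_spike_count(self, rng):
        train = np.sort(rng.uniform(1, 90, 300))
        t, rate = smooth_rate(train, span_s=100.0)
        integral = np.trapezoid(rate, t)
        assert abs(integral - train.size) / train.size < 0.01

    def test_single_spike_gives_shifted_kernel(self):
        t, rate = smooth_rate(np.array([1.0]), span_s=3.0, tau_s=0.1, dt_s=0.002)
        peak = np.argmax(rate)
        assert t[peak] == pytest.approx(1.0, abs=0.003)
        assert rate[peak] == pytest.approx(1.0 / 0.1, rel=0.05)
        assert np.all(rate[: peak - 1] == 0)  # causal

    def test_agrees_with_binning_for_narrow_kernel(self, drop_session):
        _, sched, spikes, _ = drop_session
        onset = sched.events[0].onset_s
        u = 0
        t, rate = smooth_rate(spikes.trains[u], span_s=spikes.span_s, tau_s=0.02)
        w = (t >= onset) & (t < onset + 1.0)
        binned = spikes.rates_in_windows(np.array([onset]), 1.0)[u, 0]
        if binned > 2:
            assert abs(rate[w].mean() - binned) / binned < 0.25


def test_taxonomy_report_percentages():
    rep = taxonomy_report(250, 1000, invariant_counts={"general": 50, "subgeneral": 30, "specific": 20})
    assert rep["responsive_pct"] == 25.0
    assert rep["invariant_general_pct"] == 50
    assert rep["invariant_subgeneral_pct"] == 30


class TestResponsiveSelection:
    def test_threshold_infinite_empty(self, drop_session):
        from careact import select_responsive

        _, sched, spikes, _ = drop_session
        table = build_response_table(spikes, sched)
        sig = select_responsive(spikes, sched, table, threshold_T=np.inf)
        assert not sig["responsive"].any()

    def test_threshold_zero_no_test_all(self, drop_session):
        from careact import select_responsive

        _, sched, spikes, _ = drop_session
        table = build_response_table(spikes, sched)
        sig = select_responsive(
            spikes, sched, table, threshold_T=0.0, use_significance=False
        )
        assert sig["responsive"].all()

    def test_recovered_fraction_near_truth(self, drop_session):
        cfg, sched, spikes, truth = drop_session
        _, tax = characterize(spikes, sched, seed=3)
        # only drop-responsive truth units can be found in a drop-only session
        u = truth.units
        findable = (u["responsive"] & u["sel_types"].map(lambda s: "drop" in s)).mean()
        assert abs(tax["responsive"].mean() - findable) < 0.10
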