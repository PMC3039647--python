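import numpy as np
import pytest

from careact import (
    SimulationConfig,
    build_schedule,
    generate_population,
    inject_reactivations,
)
from careact.simulate import InvalidConfigError, largest_remainder


class TestSchedule:
    def test_sessions_times_repetitions(self):
        cfg = SimulationConfig(
            seed=1,
            sessions=(("drop", 1), ("drop", 2), ("drop", 3), ("sound", 0), ("shake", 0)),
        )
        sched = build_schedule(cfg)
        assert len(sched) == 5 * 7
        for s in range(5):
            assert sum(ev.session == s for ev in sched.events) == 7

    def test_iti_bounds_and_monotone_onsets(self):
        cfg = SimulationConfig(seed=2)
        sched = build_schedule(cfg)
        onsets = sched.onsets()
        assert np.all(np.diff(onsets) > 0)
        for s in set(ev.session for ev in sched.events):
            o = np.asarray([ev.onset_s for ev in sched.events if ev.session == s])
            gaps = np.diff(o)
            assert np.all(gaps >= cfg.iti_range_s[0] - 1e-9)
            assert np.all(gaps <= cfg.iti_range_s[1] + 1e-9)

    def test_degenerate_iti_gives_exact_gaps(self):
        cfg = SimulationConfig(seed=3, iti_range_s=(60.0, 60.0))
        sched = build_schedule(cfg)
        for s in set(ev.session for ev in sched.events):
            o = np.asarray([ev.onset_s for ev in sched.events if ev.session == s])
            assert np.allclose(np.diff(o), 60.0)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=4)
        a, b = build_schedule(cfg), build_schedule(cfg)
        assert [e.onset_s for e in a.events] == [e.onset_s for e in b.events]

    def test_inverted_iti_bounds_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_schedule(SimulationConfig(iti_range_s=(180.0, 60.0)))


def test_largest_remainder_partitions_exactly():
    for fracs, n in [((0.54, 0.26, 0.20), 284), ((0.45, 0.25, 0.30), 299), ((0.36, 0.64), 1623)]:
        counts = largest_remainder(fracs, n)
        assert counts.sum() == n
        assert np.all(np.abs(counts - np.asarray(fracs) * n) <= 1.0)


class TestPopulation:
    def test_category_counts_match_fractions(self, drop_session):
        cfg, _, _, truth = drop_session
        u = truth.units
        n_resp = largest_remainder([cfg.fraction_responsive, 1 - cfg.fraction_responsive], cfg.n_units)[0]
        assert u["responsive"].sum() == n_resp
        n_inv = (u["intensity_class"] == "invariant").sum()
        assert n_inv == largest_remainder([0.5, 0.5], n_resp)[0]

    def test_baseline_rate_matches_poisson_oracle(self):
        # a 2 Hz unit observed for ~1000 s: empirical rate within 3 SE
        cfg = SimulationConfig(
            n_units=1, seed=5, fraction_responsive=0.0, interneuron_fraction=0.0,
            pyramidal_rate_range=(2.0, 2.0), sessions=(("sound", 0),),
            n_repetitions=2, baseline_span_s=1000.0, tail_span_s=20.0,
        )
        sched = build_schedule(cfg)
        spikes, _ = generate_population(cfg, sched)
        T = spikes.span_s
        rate = spikes.trains[0].size / T
        se = np.sqrt(2.0 / T)
        assert abs(rate - 2.0) < 3 * se

    def test_nonresponsive_units_stay_at_baseline(self, drop_session):
        cfg, sched, spikes, truth = drop_session
        quiet = truth.units.index[~truth.units["responsive"]].to_numpy()
        onsets = sched.onsets()
        rates = spikes.subset(quiet).rates_in_windows(onsets, 1.0).mean(axis=1)
        f0 = truth.units.loc[quiet, "baseline_hz"].to_numpy()
        se = np.sqrt(f0 / len(onsets))
        assert np.mean(np.abs(rates - f0) < 4 * np.maximum(se, 0.05)) > 0.9

    def test_sensitive_up_rates_increase_with_level(self):
        # strong rates so the ordering of trial means is near-certain
        cfg = SimulationConfig(
            n_units=30, seed=6, fraction_responsive=1.0, interneuron_fraction=0.0,
            invariant_split=(1.0, 0, 0), sensitive_split=(1.0, 0, 0),
            sensitive_down_fraction=0.0, pyramidal_rate_range=(3.0, 3.0),
            sessions=(("drop", 1), ("drop", 2), ("drop", 3)),
        )
        sched = build_schedule(cfg)
        spikes, truth = generate_population(cfg, sched)
        sens = truth.units.index[
            truth.units["intensity_class"] == "sensitive-up"
        ].to_numpy()
        means = {
            lvl: spikes.subset(sens).rates_in_windows(sched.onsets("drop", lvl), 1.0).mean(axis=1)
            for lvl in (1, 2, 3)
        }
        frac_ordered = np.mean((means[1] < means[2]) & (means[2] < means[3]))
        assert frac_ordered >= 0.9

    def test_invariant_units_equal_gain_across_levels(self):
        cfg = SimulationConfig(
            n_units=40, seed=7, fraction_responsive=1.0, interneuron_fraction=0.0,
            invariant_split=(1.0, 0, 0), sensitive_split=(1.0, 0, 0),
            fraction_invariant=1.0, pyramidal_rate_range=(3.0, 3.0),
            group_jitter_sd={"general": 0.0, "subgeneral": 0.0, "specific": 0.0},
            sessions=(("drop", 1), ("drop", 2), ("drop", 3)),
        )
        sched = build_schedule(cfg)
        spikes, truth = generate_population(cfg, sched)
        pooled = [
            spikes.rates_in_windows(sched.onsets("drop", lvl), 1.0).mean()
            for lvl in (1, 2, 3)
        ]
        expected = 3.0 * cfg.invariant_gain
        assert np.allclose(pooled, expected, rtol=0.1)

    def test_zero_units_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_units=0).validate()

    def test_spike_counts_poisson_dispersion(self, drop_session):
        # index of dispersion of a non-responsive unit's counts over 100
        # rest windows is compatible with Poisson at alpha = 0.01
        from scipy import stats

        cfg, sched, spikes, truth = drop_session
        quiet = truth.units.index[~truth.units["responsive"]][0]
        starts = np.linspace(5.0, cfg.baseline_span_s - 5.0, 100)
        counts = spikes.counts_in_windows(starts, 2.0)[list(truth.units.index).index(quiet)]
        stat = counts.var(ddof=1) / counts.mean() * (len(counts) - 1)
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=len(counts) - 1)
        assert lo < stat < hi

    def test_deterministic_population(self, drop_config):
        sched = build_schedule(drop_config)
        s1, _ = generate_population(drop_config, sched)
        s2, _ = generate_population(drop_config, sched)
        assert all(np.array_equal(a, b) for a, b in zip(s1.trains, s2.trains))


class TestReactivations:
    def test_bookkeeping_and_range(self, drop_session):
        cfg, sched, spikes, truth = drop_session
        sp2, tr2 = inject_reactivations(spikes, truth, sched, cfg)
        re = tr2.reactivations
        lo, hi = cfg.reactivation_count_range
        assert lo * len(sched) <= len(re) <= hi * len(sched)
        assert (re["amplitude"] == cfg.reactivation_amplitude).all()
        assert (re["time_s"] > 0).all() and (re["time_s"] < sched.span_s).all()
        # injections avoid stimulation windows
        for t in re["time_s"]:
            assert not np.any((t < sched.onsets() + 3.0) & (t + 1.0 > sched.onsets() - 1.0))

    def test_zero_amplitude_leaves_trains_unchanged(self, drop_session):
        cfg, sched, spikes, truth = drop_session
        import dataclasses

        cfg0 = dataclasses.replace(cfg, reactivation_amplitude=0.0)
        sp2, _ = inject_reactivations(spikes, truth, sched, cfg0)
        assert all(np.array_equal(a, b) for a, b in zip(spikes.trains, sp2.trains))

    def test_invariant_units_elevated_sensitive_not(self, drop_session):
        cfg, sched, spikes, truth = drop_session
        sp2, tr2 = inject_reactivations(spikes, truth, sched, cfg)
        times = tr2.reactivations["time_s"].to_numpy()
        u = tr2.units
        has_drop = u["sel_types"].map(lambda s: "drop" in s)
        inv = u.index[(u["intensity_class"] == "invariant") & has_drop].to_numpy()
        sens = u.index[u["intensity_class"].str.startswith("sensitive") & has_drop].to_numpy()
        for idx, elevated in ((inv, True), (sens, False)):
            r_in = sp2.subset(idx).rates_in_windows(times, 1.0).mean()
            f0 = u.loc[idx, "baseline_hz"].mean()
            if elevated:
                assert r_in > 1.3 * f0
            else:
                assert r_in < 1.3 * f0
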