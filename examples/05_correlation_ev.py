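"""Pairwise correlations by period and Explained Variance.

Unit pairs are correlated on 50-ms binned rates during pre-event
baseline, the one-second event windows, and the reactivation windows.
EV is the squared partial correlation of the event- and
reactivation-period pair-correlation vectors controlling for pre; the
reversed control swaps pre and post.
"""

from careact import (
    SimulationConfig,
    build_schedule,
    ev_analysis,
    filter_pairs,
    generate_population,
    inject_reactivations,
    period_correlation_stats,
    period_pair_correlations,
)
from careact.patterns import rest_window_starts

cfg = SimulationConfig(n_units=200, seed=19)
schedule = build_schedule(cfg)
spikes, truth = generate_population(cfg, schedule)
spikes, truth = inject_reactivations(spikes, truth, schedule, cfg)

periods = {
    "pre": (rest_window_starts(schedule, 1, 1.0, seed=1), 1.0),
    "event": (schedule.onsets(), 1.0),
    "reactivation": (truth.reactivations["time_s"].to_numpy() - 1.5, 4.0),
}

u = truth.units
for name, mask, thr in (
    ("invariant", u["intensity_class"] == "invariant", 0.1),
    ("sensitive", u["intensity_class"].str.startswith("sensitive"), 0.05),
):
    idx = u.index[mask].to_numpy()
    pairs = period_pair_correlations(spikes.subset(idx), periods)
    kept = filter_pairs(pairs, thr)
    stats = period_correlation_stats(kept, ["pre", "event", "reactivation"])
    print(f"--- {name} group ({len(kept)} retained pairs)")
    print(stats.to_string(index=False))
    if name == "invariant":
        ev = ev_analysis(kept)
        print(f"EV = {ev['ev']:.3f}, reversed control = {ev['ev_reversed']:.3f}")
# Invariant pairs stay correlated during reactivations (p_vs_pre small in
# both event and reactivation rows) while sensitive pairs return to
# baseline after the events; EV far above its reversed control indicates
# the event-period correlation structure persists post-event.
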