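"""Simulate a startle-session recording and inspect its ground truth.

Builds a 6-session experiment (drop at three heights, plus sound, air
and shake), generates the inhomogeneous-Poisson population with the
default responsive/invariant/selectivity structure, and injects
reduced-amplitude reactivations after the events.
"""

from careact import (
    SimulationConfig,
    build_schedule,
    generate_population,
    inject_reactivations,
)

cfg = SimulationConfig(n_units=150, seed=42)
schedule = build_schedule(cfg)
spikes, truth = generate_population(cfg, schedule)
spikes, truth = inject_reactivations(spikes, truth, schedule, cfg)

print(f"schedule: {len(schedule)} stimuli over {schedule.span_s / 60:.1f} min")
print(f"conditions: {schedule.conditions()}")
print(f"population: {spikes.n_units} units, {spikes.total_spikes()} spikes")

u = truth.units
print(f"responsive: {u['responsive'].sum()} ({100 * u['responsive'].mean():.1f}%)")
print(u[u["responsive"]].groupby("intensity_class").size().to_string())
print(f"injected reactivations: {len(truth.reactivations)}")
# Each reactivation re-expresses an event's firing pattern at 40% amplitude,
# 5-120 s after a stimulus, carried mainly by intensity-invariant units.
print(truth.reactivations.head().to_string(index=False))
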