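"""Synthetic CA1 ensemble generator.

Emulates the population structure the downstream analyses assume: four
startling event types (acoustic sound, air-blow, elevator drop, cage
shake), one of them delivered at three graded intensities, seven
repetitions per session at randomized 1-3 minute inter-trial intervals,
roughly 36% responsive units split ~1:1 into intensity-invariant and
intensity-sensitive groups, selectivity ranging from general (all four
types) through subgeneral (two or three) to specific (one), and
post-event reduced-amplitude reactivations carried predominantly by the
intensity-invariant subpopulation.

The rate model is a piecewise-constant inhomogeneous Poisson process:
each unit fires at its baseline rate ``f0`` except inside one-second
event-response windows, where a responsive unit's rate becomes
``f0 * gain``. Sensitive units have gains strictly monotone in intensity
level; invariant units have the same gain at every level. Co-responding
units are correlated beyond chance through two shared components: a
log-normal trial-amplitude jitter per selectivity group, and a common
sub-second burst envelope that shapes where each response's spikes fall
within the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EVENT_TYPES, Event, EventSchedule, SpikeTrainSet

SELECTIVITY_GROUPS = ("general", "subgeneral", "specific")


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the study design: 6 sessions (drop at levels 1-3 plus
    sound, air and shake at fixed intensity), 7 repetitions each at
    randomized 60-180 s intervals, 36% responsive units with a 1:1
    invariant:sensitive split, invariant selectivity split 54/26/20% and
    sensitive split 45/25/30% (general/subgeneral/specific).

    Event gains are multiples of the unit's own baseline rate, chosen so
    that synthetic event clusters sit a few rest-cluster standard
    deviations from rest, the range observed for real ensembles of this
    size.
    """

    n_units: int = 200
    interneuron_fraction: float = 0.10
    fraction_responsive: float = 0.36
    fraction_invariant: float = 0.50  # of responsive units
    invariant_split: tuple[float, float, float] = (0.54, 0.26, 0.20)
    sensitive_split: tuple[float, float, float] = (0.45, 0.25, 0.30)
    sensitive_down_fraction: float = 0.20  # of sensitive units
    pyramidal_rate_range: tuple[float, float] = (0.2, 3.0)
    interneuron_rate_range: tuple[float, float] = (8.0, 30.0)
    invariant_gain: float = 3.75
    sensitive_up_gains: tuple[float, float, float] = (3.0, 8.0, 20.0)
    sensitive_down_gains: tuple[float, float, float] = (0.6, 0.35, 0.15)
    response_window_s: float = 1.0
    group_jitter_sd: dict = field(
        default_factory=lambda: {"general": 0.3, "subgeneral": 0.18, "specific": 0.08}
    )
    sessions: tuple = (
        ("drop", 1),
        ("drop", 2),
        ("drop", 3),
        ("sound", 0),
        ("air", 2),
        ("shake", 0),
    )
    n_repetitions: int = 7
    iti_range_s: tuple[float, float] = (60.0, 180.0)
    session_gap_s: tuple[float, float] = (300.0, 600.0)
    baseline_span_s: float = 300.0
    tail_span_s: float = 200.0
    # reactivation injection
    reactivation_amplitude: float = 0.4
    reactivation_count_range: tuple[int, int] = (1, 3)
    reactivation_delay_s: tuple[float, float] = (5.0, 120.0)
    reactivation_window_s: float = 1.0
    reactivation_gate_prob: dict = field(
        default_factory=lambda: {"general": 1.0, "subgeneral": 0.85, "specific": 0.45}
    )
    sensitive_gate_prob: float = 0.0
    # amplitude jitter of a reactivation as a whole (lognormal sd); pairwise
    # correlation during reactivations is carried by the burst envelope and
    # participation gating, so this stays small
    reactivation_jitter_sd: float = 0.1
    # shared sub-second burst structure within each reactivation: gamma-weight
    # envelope over 50-ms bins, common to all participating units
    reactivation_envelope_shape: float = 0.25
    reactivation_envelope_bin_s: float = 0.05
    # event responses are onset-weighted population bursts with the same
    # shared-envelope mechanism (gamma weights tilted by an exponential decay)
    event_envelope_shape: float = 0.6
    event_envelope_tau_s: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise InvalidConfigError("n_units must be >= 1")
        for name in ("interneuron_fraction", "fraction_responsive", "fraction_invariant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        for name in ("invariant_split", "sensitive_split"):
            s = getattr(self, name)
            if any(f < 0 for f in s) or not math.isclose(sum(s), 1.0, abs_tol=1e-9):
                raise InvalidConfigError(f"{name} must be non-negative and sum to 1")
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise InvalidConfigError("inverted inter-trial-interval bounds")
        for lo, hi in (self.pyramidal_rate_range, self.interneuron_rate_range):
            if lo < 0 or hi < lo:
                raise InvalidConfigError("invalid baseline rate range")
        if not 0.0 <= self.reactivation_amplitude <= 1.0:
            raise InvalidConfigError("reactivation amplitude must be in [0, 1]")
        g = self.sensitive_up_gains
        if not (g[0] < g[1] < g[2]):
            raise InvalidConfigError("sensitive-up gains must be strictly increasing")
        d = self.sensitive_down_gains
        if not (d[0] > d[1] > d[2]):
            raise InvalidConfigError("sensitive-down gains must be strictly decreasing")


@dataclass
class GroundTruth:
    """Per-unit labels and injected-reactivation bookkeeping.

    ``units`` columns: unit_id, unit_class (pyramidal | interneuron),
    responsive (bool), selectivity (general | subgeneral:<subset> |
    specific:<type> | none), sel_types (tuple of event types),
    intensity_class (invariant | sensitive-up | sensitive-down | n/a).

    ``reactivations`` columns: time_s, event_type, level, amplitude.
    """

    units: pd.DataFrame
    reactivations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["time_s", "event_type", "level", "amplitude"]
        )
    )


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Integer category counts summing to ``n`` that best match ``fractions``."""
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    order = np.argsort(-rem, kind="stable")
    counts[order[:short]] += 1
    return counts


def build_schedule(config: SimulationConfig, seed: int | None = None) -> EventSchedule:
    """Draw a stimulus schedule satisfying the session/repetition design.

    Onsets are strictly increasing; within-session gaps are uniform in the
    configured inter-trial-interval bounds; each (type, level) session
    contains exactly ``n_repetitions`` onsets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    events: list[Event] = []
    t = float(config.baseline_span_s)
    for s_idx, (etype, level) in enumerate(config.sessions):
        if etype not in EVENT_TYPES:
            raise InvalidConfigError(f"unknown event type {etype!r}")
        if s_idx > 0:
            t += rng.uniform(*config.session_gap_s)
        for rep in range(config.n_repetitions):
            if rep > 0:
                t += rng.uniform(*config.iti_range_s)
            events.append(Event(etype, int(level), round(t, 6), s_idx))
        t = events[-1].onset_s
    span = events[-1].onset_s + config.tail_span_s
    return EventSchedule(events=events, baseline_span_s=config.baseline_span_s, span_s=span)


def _assign_units(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_units
    n_int = int(round(config.interneuron_fraction * n))
    unit_class = np.array(["pyramidal"] * n, dtype=object)
    unit_class[rng.choice(n, size=n_int, replace=False)] = "interneuron"

    f0 = np.empty(n)
    for i in range(n):
        lo, hi = (
            config.interneuron_rate_range
            if unit_class[i] == "interneuron"
            else config.pyramidal_rate_range
        )
        f0[i] = rng.uniform(lo, hi)

    # Event cliques are a pyramidal phenomenon; interneurons stay background.
    n_resp = largest_remainder([config.fraction_responsive, 1 - config.fraction_responsive], n)[0]
    pyr = np.flatnonzero(unit_class == "pyramidal")
    if n_resp > pyr.size:
        raise InvalidConfigError("not enough pyramidal units for the responsive fraction")
    resp_idx = rng.choice(pyr, size=n_resp, replace=False)
    responsive = np.zeros(n, dtype=bool)
    responsive[resp_idx] = True

    n_inv = largest_remainder([config.fraction_invariant, 1 - config.fraction_invariant], n_resp)[0]
    resp_perm = rng.permutation(resp_idx)
    inv_idx, sens_idx = resp_perm[:n_inv], resp_perm[n_inv:]

    intensity = np.array(["n/a"] * n, dtype=object)
    intensity[inv_idx] = "invariant"
    n_down = largest_remainder(
        [config.sensitive_down_fraction, 1 - config.sensitive_down_fraction], len(sens_idx)
    )[0]
    sens_perm = rng.permutation(sens_idx)
    intensity[sens_perm[:n_down]] = "sensitive-down"
    intensity[sens_perm[n_down:]] = "sensitive-up"

    selectivity = np.array(["none"] * n, dtype=object)
    sel_types: list[tuple] = [() for _ in range(n)]
    for idx_group, split in ((inv_idx, config.invariant_split), (sens_idx, config.sensitive_split)):
        counts = largest_remainder(split, len(idx_group))
        shuffled = rng.permutation(idx_group)
        pos = 0
        for group, c in zip(SELECTIVITY_GROUPS, counts):
            for u in shuffled[pos : pos + c]:
                if group == "general":
                    types = tuple(EVENT_TYPES)
                    selectivity[u] = "general"
                elif group == "subgeneral":
                    k = int(rng.integers(2, 4))
                    types = tuple(
                        sorted(rng.choice(EVENT_TYPES, size=k, replace=False).tolist())
                    )
                    selectivity[u] = "subgeneral:" + "+".join(types)
                else:
                    types = (str(rng.choice(EVENT_TYPES)),)
                    selectivity[u] = f"specific:{types[0]}"
                sel_types[u] = types
            pos += c

    return pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "unit_class": unit_class,
            "baseline_hz": f0,
            "responsive": responsive,
            "selectivity": selectivity,
            "sel_types": sel_types,
            "intensity_class": intensity,
        }
    )


def selectivity_group(label: str) -> str:
    """Map a selectivity label to its group name (general/subgeneral/specific)."""
    return label.split(":", 1)[0]


def unit_gain(row, event_type: str, level: int, config: SimulationConfig) -> float:
    """Multiplicative event-response gain of one unit for one stimulus.

    Returns 1.0 (no response) for non-responsive units and for event types
    outside the unit's selectivity set.
    """
    if not row.responsive or event_type not in row.sel_types:
        return 1.0
    cls = row.intensity_class
    if cls == "invariant":
        return config.invariant_gain
    gains = config.sensitive_up_gains if cls == "sensitive-up" else config.sensitive_down_gains
    lvl = level if level in (1, 2, 3) else 2  # fixed-intensity stimuli use the middle gain
    return gains[lvl - 1]


def _add_window_spikes(extra: list, rng, rate: float, start: float, width: float):
    lam = rate * width
    if lam <= 0:
        return
    k = rng.poisson(lam)
    if k:
        extra.append(start + rng.uniform(0.0, width, size=k))


def _thin_window(train: np.ndarray, rng, keep_p: float, start: float, end: float) -> np.ndarray:
    i0, i1 = np.searchsorted(train, (start, end))
    if i1 <= i0:
        return train
    keep = np.ones(train.size, dtype=bool)
    keep[i0:i1] = rng.random(i1 - i0) < keep_p
    return train[keep]


def generate_population(
    config: SimulationConfig, schedule: EventSchedule, seed: int | None = None
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate the spike-train population for a schedule.

    Returns the spike trains and fully populated ground-truth labels.
    Deterministic given the seed.
    """
    config.validate()
    if config.n_units == 0:
        raise InvalidConfigError("n_units must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    units = _assign_units(config, rng)

    # Shared per-event amplitude jitter, drawn independently per selectivity
    # group and per intensity category: the source of within-group
    # trial-to-trial correlation. Keeping the invariant and sensitive draws
    # independent keeps their response directions separately jittered, so
    # level ordering of cluster separations is not scrambled by a mixed
    # common-gain axis.
    jitter = {}
    for e_idx in range(len(schedule.events)):
        for group in SELECTIVITY_GROUPS:
            sd = config.group_jitter_sd[group]
            for cat in ("invariant", "sensitive"):
                jitter[(e_idx, group, cat)] = math.exp(
                    sd * rng.standard_normal() - 0.5 * sd * sd
                )

    # One shared burst envelope per event: 50-ms gamma weights tilted toward
    # the onset, so responses are transient and co-fluctuate across units.
    bw = config.reactivation_envelope_bin_s
    n_env = max(int(round(config.response_window_s / bw)), 1)
    decay = np.exp(-np.arange(n_env) * bw / config.event_envelope_tau_s)
    envelopes = []
    for _ in range(len(schedule.events)):
        env = rng.gamma(config.event_envelope_shape, size=n_env) * decay
        s = env.sum()
        envelopes.append(env / s if s > 0 else decay / decay.sum())

    w = config.response_window_s
    span = schedule.span_s
    trains: list[np.ndarray] = []
    for row in units.itertuples():
        f0 = row.baseline_hz
        n_base = rng.poisson(f0 * span)
        train = np.sort(rng.uniform(0.0, span, size=n_base))
        extra: list[np.ndarray] = []
        if row.responsive:
            group = selectivity_group(row.selectivity)
            cat = "invariant" if row.intensity_class == "invariant" else "sensitive"
            for e_idx, ev in enumerate(schedule.events):
                g = unit_gain(row, ev.event_type, ev.level, config)
                if g == 1.0:
                    continue
                g_eff = g * jitter[(e_idx, group, cat)]
                if g_eff >= 1.0:
                    k = rng.poisson(f0 * (g_eff - 1.0) * w)
                    if k:
                        env = envelopes[e_idx]
                        bins = rng.choice(env.size, size=k, p=env)
                        extra.append(
                            ev.onset_s + bins * bw + rng.uniform(0.0, bw, size=k)
                        )
                else:
                    train = _thin_window(train, rng, g_eff, ev.onset_s, ev.onset_s + w)
        if extra:
            train = np.sort(np.concatenate([train] + extra))
        trains.append(train)

    spikes = SpikeTrainSet(trains, unit_ids=units["unit_id"].tolist(), span_s=span)
    return spikes, GroundTruth(units=units)


def inject_reactivations(
    spikes: SpikeTrainSet,
    truth: GroundTruth,
    schedule: EventSchedule,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Inject reduced-amplitude re-expressions of event patterns post-event.

    For each stimulus, 1-3 reactivations are placed uniformly 5-120 s after
    its onset (avoiding stimulation windows and other injections). During a
    one-second reactivation window, participating responsive units re-express
    their event-response gain scaled by ``reactivation_amplitude``.
    Participation is gated by one shared Bernoulli draw per injection per
    selectivity group — probabilities ordered general > subgeneral >
    specific — while intensity-sensitive units participate with near-zero
    probability, so reactivations are carried by the invariant subpopulation.
    """
    config.validate()
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    w = config.reactivation_window_s
    stim = schedule.stimulation_intervals(pre_s=1.0, post_s=3.0)

    def clashes(t: float, accepted: list[float]) -> bool:
        if t < 0 or t + w > spikes.span_s - 1.0:
            return True
        if len(stim) and np.any((t < stim[:, 1]) & (t + w > stim[:, 0])):
            return True
        return any(abs(t - o) < 2.0 + w for o in accepted)

    inj_rows = []
    accepted_times: list[float] = []
    gates: list[dict] = []
    lo, hi = config.reactivation_count_range
    for ev in schedule.events:
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            for _attempt in range(100):
                t = ev.onset_s + rng.uniform(*config.reactivation_delay_s)
                if not clashes(t, accepted_times):
                    break
            else:
                continue
            accepted_times.append(t)
            gate = {
                g: bool(rng.random() < config.reactivation_gate_prob[g])
                for g in SELECTIVITY_GROUPS
            }
            gate["sensitive"] = bool(rng.random() < config.sensitive_gate_prob)
            sd = config.reactivation_jitter_sd
            shared = math.exp(sd * rng.standard_normal() - 0.5 * sd * sd)
            jit = {g: shared for g in SELECTIVITY_GROUPS}
            n_env = max(int(round(w / config.reactivation_envelope_bin_s)), 1)
            env = rng.gamma(config.reactivation_envelope_shape, size=n_env)
            env_sum = env.sum()
            env = env / env_sum if env_sum > 0 else np.full(n_env, 1.0 / n_env)
            gates.append((gate, jit, env))
            inj_rows.append(
                {
                    "time_s": t,
                    "event_type": ev.event_type,
                    "level": ev.level,
                    "amplitude": config.reactivation_amplitude,
                }
            )

    trains = [t.copy() for t in spikes.trains]
    for i, row in enumerate(truth.units.itertuples()):
        if not row.responsive:
            continue
        group = selectivity_group(row.selectivity)
        invariant = row.intensity_class == "invariant"
        extra: list[np.ndarray] = []
        for inj, (gate, jit, env) in zip(inj_rows, gates):
            if inj["event_type"] not in row.sel_types:
                continue
            on = gate[group] if invariant else gate["sensitive"]
            if not on:
                continue
            g = unit_gain(row, inj["event_type"], inj["level"], config) * jit[group]
            rate = row.baseline_hz * (g - 1.0) * inj["amplitude"]
            if rate > 0:
                # spikes follow the injection's shared burst envelope
                k = rng.poisson(rate * w)
                if k:
                    bins = rng.choice(env.size, size=k, p=env)
                    bw = config.reactivation_envelope_bin_s
                    extra.append(
                        inj["time_s"] + bins * bw + rng.uniform(0.0, bw, size=k)
                    )
        if extra:
            trains[i] = np.sort(np.concatenate([trains[i]] + extra))

    new_spikes = SpikeTrainSet(trains, unit_ids=spikes.unit_ids, span_s=spikes.span_s)
    new_truth = GroundTruth(
        units=truth.units.copy(),
        reactivations=pd.DataFrame(inj_rows, columns=["time_s", "event_type", "level", "amplitude"]),
    )
    return new_spikes, new_truth


def make_gaussian_patterns(
    n_classes: int = 5,
    n_features: int = 40,
    n_per_class: int = 20,
    separation: float = 6.0,
    seed: int = 0,
    rest_label: str = "rest",
    equal_norm: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled unit-variance Gaussian pattern clusters for classifier checks.

    Default layout: the rest class at the origin, other classes
    ``separation`` standard deviations away along orthogonal axes. With
    ``equal_norm`` the class means sit on a regular simplex (all pairwise
    distances equal to ``separation`` and all means the same distance
    from the origin), so no permutation-invariant statistic — total rate,
    norm — distinguishes classes.
    """
    if n_classes - 1 > n_features:
        raise ValueError("need n_features >= n_classes - 1")
    rng = np.random.default_rng(seed)
    means = np.zeros((n_classes, n_features))
    if equal_norm:
        V = np.eye(n_classes)  # simplex vertices e_i, edge length sqrt(2)
        V = V - V.mean(axis=0)
        means[:, :n_classes] = V * (separation / math.sqrt(2.0))
    else:
        for c in range(1, n_classes):
            means[c, c - 1] = separation
    labels = []
    X = []
    for c in range(n_classes):
        X.append(rng.standard_normal((n_per_class, n_features)) + means[c])
        labels += [rest_label if c == 0 else f"class_{c}"] * n_per_class
    return np.vstack(X), np.asarray(labels, dtype=object)
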