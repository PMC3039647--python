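"""Peri-event response characterization and unit taxonomy.

Per-unit firing rates are measured in two 500-ms bins immediately after
each stimulus onset, compared to a baseline rate estimated over all rest
time, and normalized with the T-score transform

    R = (f_startle - f0) / (g0 + f0),     T = log(1 + R)

where ``f0`` is the unit's baseline rate and ``g0`` the population-mean
baseline. The transform makes low-firing units proportional to absolute
rate changes (f0 << g0) and high-firing units proportional to relative
changes (f0 >> g0). Natural logarithm throughout.

The three-way taxonomy assigns each unit a responsive flag (rank test of
trial rates against matched pre-event baseline windows combined with a
|T| threshold), a selectivity label (general = all four event types,
subgeneral = two or three, specific = one) and an intensity class
(permutation test on the slope of trial rate versus intensity level:
sensitive-up/-down if significant, invariant otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EventSchedule, SpikeTrainSet

__all__ = [
    "ResponseTable",
    "bin_event_responses",
    "compute_baseline",
    "normalize_response",
    "pre_event_windows",
    "select_responsive",
    "classify_selectivity",
    "classify_intensity_dependence",
    "classify_unit_type",
    "characterize",
    "smooth_rate",
    "taxonomy_report",
]


@dataclass
class ResponseTable:
    """Binned peri-event rates plus baselines and normalized scores.

    Attributes
    ----------
    rates
        ``(n_units, n_events, n_bins)`` array of rates in Hz.
    baseline_hz
        Per-unit baseline rate ``f0``.
    population_baseline_hz
        Population mean baseline ``g0``.
    type_mean_hz, R, T
        ``(n_units, n_types)`` DataFrames indexed by unit, columns per
        event type: mean peri-event rate, normalized response and T-score.
    """

    rates: np.ndarray
    bin_width_s: float
    baseline_hz: np.ndarray
    population_baseline_hz: float
    type_mean_hz: pd.DataFrame
    R: pd.DataFrame
    T: pd.DataFrame


def bin_event_responses(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    bin_width_s: float = 0.5,
    n_bins: int = 2,
) -> np.ndarray:
    """Peri-event rates: ``rates[u, e, b]`` is unit ``u``'s rate in the
    half-open window ``[onset_e + b*bin_width, onset_e + (b+1)*bin_width)``.
    """
    onsets = schedule.onsets()
    if len(onsets) and onsets[-1] + n_bins * bin_width_s > spikes.span_s + 1e-9:
        raise ValueError("event response windows extend beyond recording span")
    window_span = n_bins * bin_width_s
    if len(onsets) > 1 and np.any(np.diff(np.sort(onsets)) < window_span):
        warnings.warn("overlapping event response windows; later event wins for exclusive stats")
    out = np.empty((spikes.n_units, len(onsets), n_bins))
    for b in range(n_bins):
        out[:, :, b] = spikes.rates_in_windows(onsets + b * bin_width_s, bin_width_s)
    return out


def compute_baseline(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    exclusion_s: float = 3.0,
) -> tuple[np.ndarray, float]:
    """Baseline rates over all time excluding ``[onset, onset + exclusion_s)``.

    Returns per-unit ``f0`` and the population mean ``g0``.
    """
    span = spikes.span_s
    iv = schedule.stimulation_intervals(pre_s=0.0, post_s=exclusion_s)
    iv = np.clip(iv, 0.0, span)
    excluded = float(np.sum(iv[:, 1] - iv[:, 0])) if len(iv) else 0.0
    eligible = span - excluded
    if eligible <= 0:
        raise ValueError("no eligible baseline time")
    f0 = np.empty(spikes.n_units)
    for i, t in enumerate(spikes.trains):
        n_in = 0
        if len(iv):
            n_in = int(np.sum(np.searchsorted(t, iv[:, 1]) - np.searchsorted(t, iv[:, 0])))
        f0[i] = (t.size - n_in) / eligible
    g0 = float(np.mean(f0)) if spikes.n_units else 0.0
    return f0, g0


def normalize_response(f_startle, f0, g0):
    """Normalized response ``R`` and T-score ``T = ln(1 + R)``.

    Undefined where ``g0 + f0 == 0``.
    """
    f_startle = np.asarray(f_startle, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    denom = g0 + f0
    if np.any(denom <= 0):
        raise ValueError("g0 + f0 must be positive")
    R = (f_startle - f0) / denom
    return R, np.log1p(R)


def _type_table(rates, schedule, f0, g0):
    types = schedule.event_types()
    ev_types = np.asarray([ev.event_type for ev in schedule.events])
    window_rate = rates.mean(axis=2)  # mean over the two 500-ms bins
    cols = {}
    for et in types:
        cols[et] = window_rate[:, ev_types == et].mean(axis=1)
    mean_hz = pd.DataFrame(cols)
    R, T = normalize_response(mean_hz.to_numpy(), f0[:, None], g0)
    return mean_hz, pd.DataFrame(R, columns=types), pd.DataFrame(T, columns=types)


def build_response_table(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    bin_width_s: float = 0.5,
    n_bins: int = 2,
) -> ResponseTable:
    """Bin responses, estimate baselines and compute per-type T-scores."""
    rates = bin_event_responses(spikes, schedule, bin_width_s, n_bins)
    f0, g0 = compute_baseline(spikes, schedule)
    mean_hz, R, T = _type_table(rates, schedule, f0, g0)
    return ResponseTable(
        rates=rates,
        bin_width_s=bin_width_s,
        baseline_hz=f0,
        population_baseline_hz=g0,
        type_mean_hz=mean_hz,
        R=R,
        T=T,
    )


def pre_event_windows(
    schedule: EventSchedule,
    n_per_event: int = 4,
    width_s: float = 1.0,
    post_margin_s: float = 3.0,
    pre_margin_s: float = 1.0,
) -> dict[int, np.ndarray]:
    """Matched baseline window starts preceding each event.

    For event ``e`` the windows are placed evenly in the rest segment
    between the previous event's exclusion window and ``pre_margin_s``
    before the onset. Deterministic.
    """
    out: dict[int, np.ndarray] = {}
    prev = 0.0
    for e_idx, ev in enumerate(schedule.events):
        lo = prev + post_margin_s if e_idx else 0.0
        hi = ev.onset_s - pre_margin_s - width_s
        if hi <= lo:
            out[e_idx] = np.empty(0)
        else:
            k = n_per_event
            starts = lo + (hi - lo) * (np.arange(k) + 0.5) / k
            out[e_idx] = starts
        prev = ev.onset_s
    return out


def select_responsive(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    table: ResponseTable,
    threshold_T: float = 0.2,
    alpha: float = 0.05,
    use_significance: bool = True,
    n_baseline_per_event: int = 4,
) -> pd.DataFrame:
    """Per-unit, per-event-type responsiveness calls.

    A unit is responsive to a type when the rank-sum (Mann-Whitney)
    comparison of its trial rates against matched pre-event baseline
    windows is significant at ``alpha`` and ``|T|`` for that type reaches
    ``threshold_T``. Trials are pooled across intensity levels. Returns a
    boolean DataFrame (units x types) with a ``responsive`` column.
    """
    types = schedule.event_types()
    window_s = table.rates.shape[2] * table.bin_width_s
    ev_types = np.asarray([ev.event_type for ev in schedule.events])
    trial_rates = table.rates.mean(axis=2)  # (units, events)

    base = pre_event_windows(schedule, n_per_event=n_baseline_per_event, width_s=window_s)
    base_rates = {
        e: spikes.rates_in_windows(starts, window_s) if starts.size else None
        for e, starts in base.items()
    }

    sig = pd.DataFrame(False, index=range(spikes.n_units), columns=types)
    for et in types:
        e_idx = np.flatnonzero(ev_types == et)
        bmats = [base_rates[e] for e in e_idx if base_rates[e] is not None]
        if not bmats:
            continue
        B = np.hstack(bmats)  # (units, n_windows)
        X = trial_rates[:, e_idx]
        t_ok = np.abs(table.T[et].to_numpy()) >= threshold_T
        if not use_significance:
            sig[et] = t_ok if threshold_T > 0 else np.ones(spikes.n_units, dtype=bool)
            continue
        for u in range(spikes.n_units):
            if not t_ok[u]:
                continue
            if np.all(X[u] == X[u][0]) and np.all(B[u] == X[u][0]):
                continue
            p = stats.mannwhitneyu(X[u], B[u], alternative="two-sided").pvalue
            sig.loc[u, et] = bool(p < alpha)
    sig["responsive"] = sig[types].any(axis=1)
    return sig


def classify_selectivity(sig: pd.DataFrame, types: list[str]) -> pd.Series:
    """Selectivity labels from the per-type responsiveness matrix.

    general = responsive to all available types; subgeneral = a strict
    subset of size >= 2; specific = exactly one.
    """
    if len(types) < 4:
        warnings.warn("fewer than 4 event types; selectivity is relative to available types")
    labels = []
    for _, row in sig[types].iterrows():
        hit = sorted(t for t in types if row[t])
        if not hit:
            labels.append("none")
        elif len(hit) == len(types):
            labels.append("general")
        elif len(hit) == 1:
            labels.append(f"specific:{hit[0]}")
        else:
            labels.append("subgeneral:" + "+".join(hit))
    return pd.Series(labels, index=sig.index, name="selectivity")


def _slope_permutation_p(y: np.ndarray, x: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    xc = x - x.mean()
    obs = float(xc @ y)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    null = perms @ xc
    p = (np.sum(np.abs(null) >= abs(obs) - 1e-12) + 1) / (n_perm + 1)
    slope = obs / float(xc @ xc) if xc @ xc > 0 else 0.0
    return slope, float(p)


def classify_intensity_dependence(
    table: ResponseTable,
    schedule: EventSchedule,
    sig: pd.DataFrame,
    parametric_types: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Intensity class per unit from the parametric sessions.

    For each unit responsive to a parametric type with >= 2 levels, the
    least-squares slope of trial rate on intensity rank is tested with a
    permutation p-value; significant slopes give sensitive-up/-down by
    sign, otherwise the unit is invariant. Units without parametric data
    are labelled ``n/a``.
    """
    rng = np.random.default_rng(seed)
    ev_types = np.asarray([ev.event_type for ev in schedule.events])
    ev_levels = np.asarray([ev.level for ev in schedule.events])
    trial_rates = table.rates.mean(axis=2)

    if parametric_types is None:
        parametric_types = [
            et
            for et in schedule.event_types()
            if len(set(ev_levels[ev_types == et])) >= 2
        ]

    out = pd.Series("n/a", index=sig.index, name="intensity_class", dtype=object)
    for u in sig.index:
        if not sig.loc[u, "responsive"]:
            continue
        best = None  # (p, slope)
        for et in parametric_types:
            if et not in sig.columns or not sig.loc[u, et]:
                continue
            mask = ev_types == et
            levels = ev_levels[mask].astype(float)
            if len(set(levels)) < 2:
                continue
            slope, p = _slope_permutation_p(trial_rates[u, mask], levels, n_perm, rng)
            if best is None or p < best[0]:
                best = (p, slope)
        if best is None:
            continue
        p, slope = best
        if p < alpha:
            out.loc[u] = "sensitive-up" if slope > 0 else "sensitive-down"
        else:
            out.loc[u] = "invariant"
    return out


def classify_unit_type(
    train: np.ndarray,
    amplitudes: np.ndarray | None = None,
    pyramidal_max_hz: float = 5.0,
    interneuron_min_hz: float = 8.0,
    span_s: float | None = None,
    min_spikes: int = 100,
) -> tuple[str, float | None]:
    """Putative pyramidal/interneuron call plus complex spike index.

    The complex spike index (CSI, %) is the percentage of first-lag
    inter-spike intervals in 2-15 ms whose second spike has smaller
    amplitude than the first; it requires per-spike amplitudes. The class
    call uses the mean rate: < 5 Hz pyramidal, > 8 Hz interneuron,
    otherwise unknown. Fewer than 100 spikes -> unknown.
    """
    train = np.asarray(train, dtype=float)
    if train.size < min_spikes:
        return "unknown", None
    span = span_s if span_s is not None else (train[-1] - train[0])
    rate = train.size / span if span > 0 else np.inf
    if rate < pyramidal_max_hz:
        cls = "pyramidal"
    elif rate > interneuron_min_hz:
        cls = "interneuron"
    else:
        cls = "unknown"
    csi = None
    if amplitudes is not None:
        amplitudes = np.asarray(amplitudes, dtype=float)
        isi = np.diff(train)
        in_band = (isi >= 0.002) & (isi <= 0.015)
        decreasing = amplitudes[1:] < amplitudes[:-1]
        csi = 100.0 * np.sum(in_band & decreasing) / isi.size if isi.size else 0.0
    return cls, csi


def characterize(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    threshold_T: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[ResponseTable, pd.DataFrame]:
    """Full taxonomy pass: binned responses, T-scores, responsiveness,
    selectivity, intensity dependence and putative unit class.

    Returns the response table and a per-unit taxonomy DataFrame.
    """
    table = build_response_table(spikes, schedule)
    sig = select_responsive(spikes, schedule, table, threshold_T=threshold_T, alpha=alpha)
    types = schedule.event_types()
    selectivity = classify_selectivity(sig, types)
    intensity = classify_intensity_dependence(table, schedule, sig, alpha=alpha, seed=seed)
    unit_cls = []
    csis = []
    for i, train in enumerate(spikes.trains):
        amps = spikes.amplitudes[i] if spikes.amplitudes is not None else None
        cls, csi = classify_unit_type(train, amps, span_s=spikes.span_s)
        unit_cls.append(cls)
        csis.append(csi)
    tax = pd.DataFrame(
        {
            "unit_id": spikes.unit_ids,
            "responsive": sig["responsive"].to_numpy(),
            "selectivity": selectivity.to_numpy(),
            "intensity_class": intensity.to_numpy(),
            "unit_class": unit_cls,
            "csi_pct": csis,
            "baseline_hz": table.baseline_hz,
        }
    )
    for et in types:
        tax[f"T_{et}"] = table.T[et].to_numpy()
    return table, tax


def smooth_rate(
    train: np.ndarray,
    span_s: float,
    tau_s: float = 0.1,
    dt_s: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal firing-rate estimate with a one-sided exponential kernel.

    The kernel ``k(t) = exp(-t/tau)/tau`` for ``t >= 0`` integrates to one,
    so the integral of the rate recovers the spike count. Returns
    ``(times, rate_hz)`` on a grid of step ``dt_s``.
    """
    train = np.asarray(train, dtype=float)
    n = int(np.ceil(span_s / dt_s)) + 1
    times = np.arange(n) * dt_s
    counts = np.zeros(n)
    if train.size:
        idx = np.floor(train / dt_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    m = int(np.ceil(8 * tau_s / dt_s))
    kernel = np.exp(-np.arange(m) * dt_s / tau_s)
    kernel /= kernel.sum() * dt_s  # exact discrete normalization
    rate = np.convolve(counts, kernel)[:n]
    return times, rate


def taxonomy_report(
    responsive_count: int,
    total_count: int,
    invariant_counts: dict[str, int] | None = None,
    sensitive_counts: dict[str, int] | None = None,
) -> dict:
    """Percentage summary of a unit taxonomy census.

    Given the responsive count out of the total and per-selectivity counts
    for the invariant and sensitive groups, returns the responsive fraction
    (one decimal, percent) and per-group selectivity percentages (nearest
    percent), alongside the raw counts.
    """
    report: dict = {
        "total_units": int(total_count),
        "responsive_units": int(responsive_count),
        "responsive_pct": round(100.0 * responsive_count / total_count, 1),
    }
    for name, counts in (("invariant", invariant_counts), ("sensitive", sensitive_counts)):
        if counts is None:
            continue
        group_total = sum(counts.values())
        report[f"{name}_total"] = int(group_total)
        for sel, c in counts.items():
            report[f"{name}_{sel}_count"] = int(c)
            report[f"{name}_{sel}_pct"] = int(round(100.0 * c / group_total))
    return report


def taxonomy_counts(tax: pd.DataFrame) -> dict:
    """Census counts from a taxonomy DataFrame, in ``taxonomy_report`` form."""
    resp = tax[tax["responsive"]]
    out = {"responsive_count": int(len(resp)), "total_count": int(len(tax))}
    for name, mask in (
        ("invariant", resp["intensity_class"] == "invariant"),
        ("sensitive", resp["intensity_class"].str.startswith("sensitive")),
    ):
        sub = resp[mask]
        out[f"{name}_counts"] = {
            g: int((sub["selectivity"].str.split(":").str[0] == g).sum())
            for g in ("general", "subgeneral", "specific")
        }
    return out
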