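"""Population pattern vectors for classification.

A pattern is the concatenation of every unit's firing rates in two
500-ms bins for one window: features ``[0, n_units)`` are the first bin,
``[n_units, 2*n_units)`` the second, so unit ``u`` owns feature columns
``(u, n_units + u)``.
"""

from __future__ import annotations

import numpy as np

from .containers import EventSchedule, SpikeTrainSet


def features_at(
    spikes: SpikeTrainSet,
    starts: np.ndarray,
    bin_width_s: float = 0.5,
    n_bins: int = 2,
) -> np.ndarray:
    """Pattern matrix ``(n_windows, n_bins * n_units)`` at window starts."""
    blocks = [
        spikes.rates_in_windows(np.asarray(starts) + b * bin_width_s, bin_width_s)
        for b in range(n_bins)
    ]
    return np.hstack([blk.T for blk in blocks])


def rest_window_starts(
    schedule: EventSchedule,
    n_per_event: int = 1,
    width_s: float = 1.0,
    seed: int = 0,
    post_margin_s: float = 3.0,
    pre_margin_s: float = 1.0,
) -> np.ndarray:
    """Randomly positioned rest windows in the interval preceding each event."""
    rng = np.random.default_rng(seed)
    starts = []
    prev = 0.0
    for e_idx, ev in enumerate(schedule.events):
        lo = prev + post_margin_s if e_idx else 0.0
        hi = ev.onset_s - pre_margin_s - width_s
        if hi > lo:
            starts.extend(rng.uniform(lo, hi, size=n_per_event))
        prev = ev.onset_s
    return np.sort(np.asarray(starts))


def build_labelled_patterns(
    spikes: SpikeTrainSet,
    schedule: EventSchedule,
    bin_width_s: float = 0.5,
    n_bins: int = 2,
    rest_per_event: int = 1,
    rest_label: str = "rest",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event patterns labelled by condition plus matched rest patterns.

    Returns ``(X, labels)`` with one row per event instance and
    ``rest_per_event`` rest rows per event drawn from random pre-event
    windows.
    """
    onsets = schedule.onsets()
    X_ev = features_at(spikes, onsets, bin_width_s, n_bins)
    labels = [ev.condition for ev in schedule.events]
    rest_starts = rest_window_starts(
        schedule, n_per_event=rest_per_event, width_s=bin_width_s * n_bins, seed=seed
    )
    X_rest = features_at(spikes, rest_starts, bin_width_s, n_bins)
    X = np.vstack([X_ev, X_rest])
    y = np.asarray(labels + [rest_label] * len(rest_starts), dtype=object)
    return X, y


def unit_feature_columns(unit_indices, n_units: int, n_bins: int = 2) -> np.ndarray:
    """Feature-column indices owned by the given units."""
    unit_indices = np.asarray(list(unit_indices), dtype=int)
    return np.concatenate([unit_indices + b * n_units for b in range(n_bins)])
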