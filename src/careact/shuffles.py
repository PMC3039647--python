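"""Shuffle nulls: unit-identity and temporal surrogates.

Both shuffles preserve the total spike count exactly. The unit-identity
shuffle permutes which unit carries which spike train (optionally
re-drawing the permutation per time segment, which destroys the unit <->
response correspondence the discriminant model relies on). The temporal
shuffle bins a +/-2 s window around a reactivation into small bins and
permutes the bin order within each cell, destroying simultaneity while
preserving each cell's window rate.
"""

from __future__ import annotations

import numpy as np

from .containers import SpikeTrainSet


def shuffle_unit_identity(
    spikes: SpikeTrainSet, seed: int = 0, segment_s: float | None = None
) -> SpikeTrainSet:
    """Randomly reassign spike trains among unit ids.

    With ``segment_s`` set, an independent permutation is drawn for every
    consecutive segment of that length, i.e. spike activities are
    shuffled among units at all times rather than once globally.
    """
    if spikes.n_units < 2:
        raise ValueError("need at least 2 units to shuffle identities")
    rng = np.random.default_rng(seed)
    n = spikes.n_units
    if segment_s is None:
        perm = rng.permutation(n)
        trains = [spikes.trains[perm[i]].copy() for i in range(n)]
    else:
        edges = np.arange(0.0, spikes.span_s + segment_s, segment_s)
        pieces: list[list[np.ndarray]] = [[] for _ in range(n)]
        for s0, s1 in zip(edges[:-1], edges[1:]):
            perm = rng.permutation(n)
            for i in range(n):
                t = spikes.trains[perm[i]]
                lo, hi = np.searchsorted(t, (s0, s1))
                pieces[i].append(t[lo:hi])
        trains = [np.concatenate(p) if p else np.empty(0) for p in pieces]
    return SpikeTrainSet(trains, unit_ids=spikes.unit_ids, span_s=spikes.span_s)


def shuffle_temporal(
    spikes: SpikeTrainSet,
    center_s: float,
    window_s: float = 4.0,
    bin_s: float = 0.01,
    seed: int = 0,
) -> SpikeTrainSet:
    """Within-cell bin permutation inside ``[center - w/2, center + w/2)``.

    Spikes keep their offset within their bin; spikes outside the window
    are untouched; each cell's spike count in the window is preserved.
    """
    if not (window_s > 0 and 0 < bin_s <= window_s):
        raise ValueError("need window > 0 and 0 < bin <= window")
    start = center_s - window_s / 2.0
    stop = center_s + window_s / 2.0
    if start < 0 or stop > spikes.span_s:
        raise ValueError("shuffle window outside recording span")
    rng = np.random.default_rng(seed)
    n_bins = int(round(window_s / bin_s))
    trains = []
    for t in spikes.trains:
        lo, hi = np.searchsorted(t, (start, stop))
        inside = t[lo:hi]
        if inside.size:
            idx = np.minimum(((inside - start) / bin_s).astype(int), n_bins - 1)
            offset = inside - start - idx * bin_s
            perm = rng.permutation(n_bins)
            shuffled = start + perm[idx] * bin_s + offset
            new = np.concatenate([t[:lo], np.sort(shuffled), t[hi:]])
        else:
            rng.permutation(n_bins)  # keep the stream aligned across cells
            new = t.copy()
        trains.append(new)
    return SpikeTrainSet(trains, unit_ids=spikes.unit_ids, span_s=spikes.span_s)


def shuffle_report(original: dict, shuffled: dict, accuracy_margin: float = 0.3) -> dict:
    """Side-by-side summary of an analysis before/after shuffling.

    ``original``/``shuffled`` are dicts of comparable statistics (e.g.
    ``accuracy``, ``n_reactivations``). Flags whether classification
    accuracy dropped by at least ``accuracy_margin``.
    """
    report = {"original": dict(original), "shuffled": dict(shuffled)}
    if "accuracy" in original and "accuracy" in shuffled:
        drop = original["accuracy"] - shuffled["accuracy"]
        report["accuracy_drop"] = float(drop)
        report["collapsed"] = bool(drop >= accuracy_margin)
    if "n_reactivations" in original and "n_reactivations" in shuffled:
        report["reactivations_reduced"] = bool(
            shuffled["n_reactivations"] <= original["n_reactivations"]
        )
    return report
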