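"""Plain-text file formats: spike CSV, schedule/truth/report JSON, model JSON.

Spike files are delimited text with a header (``unit_id,spike_time_s``
plus an optional ``amplitude`` column), times in seconds, ascending per
unit after load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Event, EventSchedule, SpikeTrainSet
from .mda import MDAModel
from .simulate import GroundTruth


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    rows = []
    for i, t in enumerate(spikes.trains):
        df = pd.DataFrame({"unit_id": spikes.unit_ids[i], "spike_time_s": t})
        if spikes.amplitudes is not None:
            df["amplitude"] = spikes.amplitudes[i]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "spike_time_s"]
    )
    out.to_csv(path, index=False)


def read_spikes(path, span_s: float | None = None) -> SpikeTrainSet:
    """Load a spike CSV; out-of-order rows are sorted, duplicate times
    within a unit collapsed with a warning."""
    df = pd.read_csv(path)
    required = {"unit_id", "spike_time_s"}
    if not required.issubset(df.columns):
        missing = required - set(df.columns)
        raise ValueError(f"spike file missing column(s): {sorted(missing)}")
    if len(df) and (df["spike_time_s"] < 0).any():
        line = int(df.index[df["spike_time_s"] < 0][0]) + 2  # header + 1-based
        raise ValueError(f"negative spike time at line {line}")
    has_amp = "amplitude" in df.columns
    trains, ids, amps = [], [], []
    for uid, sub in df.groupby("unit_id", sort=True):
        sub = sub.sort_values("spike_time_s")
        t = sub["spike_time_s"].to_numpy(dtype=float)
        keep = np.concatenate([[True], np.diff(t) > 0]) if t.size else np.zeros(0, bool)
        if t.size and not keep.all():
            import warnings

            warnings.warn(f"unit {uid}: collapsed {int((~keep).sum())} duplicate timestamps")
        trains.append(t[keep])
        ids.append(uid)
        if has_amp:
            amps.append(sub["amplitude"].to_numpy(dtype=float)[keep])
    return SpikeTrainSet(trains, unit_ids=ids, amplitudes=amps if has_amp else None,
                         span_s=span_s)


def write_schedule(schedule: EventSchedule, path) -> None:
    payload = {
        "baseline_span_s": schedule.baseline_span_s,
        "span_s": schedule.span_s,
        "events": [
            {"type": ev.event_type, "level": ev.level, "onset_s": ev.onset_s,
             "session": ev.session}
            for ev in schedule.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_schedule(path) -> EventSchedule:
    payload = json.loads(Path(path).read_text())
    events = [
        Event(e["type"], int(e["level"]), float(e["onset_s"]), int(e["session"]))
        for e in payload["events"]
    ]
    return EventSchedule(events, float(payload["baseline_span_s"]), float(payload["span_s"]))


def write_truth(truth: GroundTruth, path) -> None:
    units = truth.units.copy()
    units["sel_types"] = units["sel_types"].map(list)
    payload = {
        "units": units.to_dict(orient="records"),
        "reactivations": truth.reactivations.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    units = pd.DataFrame(payload["units"])
    units["sel_types"] = units["sel_types"].map(tuple)
    re = pd.DataFrame(payload["reactivations"],
                      columns=["time_s", "event_type", "level", "amplitude"])
    return GroundTruth(units=units, reactivations=re)


MODEL_FORMAT_VERSION = 1


def write_model(model: MDAModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classes": list(map(str, model.classes)),
        "lam": model.lam,
        "rest_label": model.rest_label,
        "rest_sd": model.rest_sd,
        "rest_chi_mean": model.rest_chi_mean,
        "rest_chi_sd": model.rest_chi_sd,
        "n_features": model.n_features,
        "W": model.W.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "class_means": model.class_means.tolist(),
        "class_covs": model.class_covs.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> MDAModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    covs = np.asarray(payload["class_covs"])
    return MDAModel(
        W=np.asarray(payload["W"]),
        eigenvalues=np.asarray(payload["eigenvalues"]),
        classes=list(payload["classes"]),
        class_means=np.asarray(payload["class_means"]),
        class_covs=covs,
        class_cov_invs=np.stack([np.linalg.inv(c) for c in covs]),
        lam=float(payload["lam"]),
        rest_label=payload["rest_label"],
        rest_sd=float(payload["rest_sd"]),
        rest_chi_mean=float(payload["rest_chi_mean"]),
        rest_chi_sd=float(payload["rest_chi_sd"]),
        n_features=int(payload["n_features"]),
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default, sort_keys=True))
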