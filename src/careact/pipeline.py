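"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` chains simulate -> characterize -> cluster -> MDA ->
trajectory scan -> shuffle controls -> correlation/EV on a single
dataset and returns (and optionally writes) a versioned JSON summary.
All randomness derives from the single configured seed through numpy's
seed-sequence spawning, so identical configurations produce identical
summaries.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from . import patterns as pat
from .cluster import cluster_responses, order_leaves
from .correlation import ev_analysis, filter_pairs, period_correlation_stats, \
    period_pair_correlations
from .mda import cross_validate, fit_mda, rest_normalized_class_distances
from .responses import characterize, taxonomy_counts, taxonomy_report
from .shuffles import shuffle_report, shuffle_temporal, shuffle_unit_identity
from .simulate import (
    SimulationConfig,
    build_schedule,
    generate_population,
    inject_reactivations,
)
from .trajectory import detect_reactivations, sliding_projection

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles and parameters.

    When ``spikes_path``/``schedule_path`` are unset, data are simulated
    with ``simulation`` (seeded by ``seed``).
    """

    seed: int = 0
    spikes_path: str | None = None
    schedule_path: str | None = None
    out_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    with_reactivations: bool = True
    lam: float = 0.8
    threshold_T: float = 0.2
    alpha: float = 0.05
    theta: float = 2.0
    d_min_s: float = 0.5
    cv_repetitions: int = 200
    correlation_threshold_invariant: float = 0.1
    correlation_threshold_sensitive: float = 0.05
    run_cluster: bool = True
    run_trajectory: bool = True
    run_shuffles: bool = True
    run_correlation: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**payload.pop("simulation", {}))
        cfg = cls(simulation=sim, **payload)
        if "seed" in payload:
            cfg.simulation.seed = cfg.seed
        return cfg


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict."""
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}

    # --- data ---------------------------------------------------------
    if config.spikes_path and config.schedule_path:
        _log("load", f"reading {config.spikes_path}")
        schedule = cio.read_schedule(config.schedule_path)
        spikes = cio.read_spikes(config.spikes_path, span_s=schedule.span_s)
        truth = None
    else:
        _log("simulate", f"{config.simulation.n_units} units, seed {config.seed}")
        sim = config.simulation
        sim.seed = config.seed
        schedule = build_schedule(sim)
        spikes, truth = generate_population(sim, schedule)
        if config.with_reactivations:
            spikes, truth = inject_reactivations(spikes, truth, schedule, sim)
        summary["simulation"] = {
            "n_units": sim.n_units,
            "n_events": len(schedule),
            "span_s": schedule.span_s,
            "n_injected_reactivations": int(len(truth.reactivations)),
        }

    # --- characterize ---------------------------------------------------
    _log("characterize", "binning responses and assigning taxonomy")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, tax = characterize(
            spikes, schedule, threshold_T=config.threshold_T, alpha=config.alpha,
            seed=int(rng_seeds[0]),
        )
    counts = taxonomy_counts(tax)
    summary["taxonomy"] = taxonomy_report(
        counts["responsive_count"], counts["total_count"],
        invariant_counts=counts["invariant_counts"],
        sensitive_counts=counts["sensitive_counts"],
    )
    summary["population_baseline_hz"] = table.population_baseline_hz

    resp_idx = tax.index[tax["responsive"]].to_numpy()
    if config.run_cluster and len(resp_idx) >= 2:
        _log("cluster", f"{len(resp_idx)} responsive units")
        T = table.T.to_numpy()[resp_idx]
        dend = cluster_responses(T)
        order = order_leaves(dend, T)
        summary["cluster"] = {
            "n_units": int(len(resp_idx)),
            "n_merges": len(dend.merges),
            "leaf_order": [int(resp_idx[i]) for i in order],
        }

    if len(resp_idx) < 4:
        _log("mda", "too few responsive units; stopping after characterization")
        return _finish(summary, config)

    # --- MDA -------------------------------------------------------------
    _log("mda", "fitting discriminant model")
    spR = spikes.subset(resp_idx)
    X, y = pat.build_labelled_patterns(
        spR, schedule, rest_per_event=2, seed=int(rng_seeds[1])
    )
    model = fit_mda(X, y, lam=config.lam)
    acc = cross_validate(
        X, y, lam=config.lam, n_rep=config.cv_repetitions, seed=int(rng_seeds[2])
    )
    summary["mda"] = {
        "classes": list(map(str, model.classes)),
        "n_components": model.n_components,
        "lambda": config.lam,
        "cv_accuracy": float(acc.mean()),
        "cv_accuracy_se": float(acc.std(ddof=1) / np.sqrt(len(acc))),
        "rest_normalized_distances": rest_normalized_class_distances(model),
    }

    events = []
    if config.run_trajectory:
        _log("scan", "sliding-window projection and reactivation detection")
        traj = sliding_projection(spR, model)
        events = detect_reactivations(
            traj, model, schedule, theta=config.theta, d_min_s=config.d_min_s,
            spikes=spR,
        )
        summary["reactivations"] = {
            "n_detected": len(events),
            "events": [
                {
                    "time_s": e.time_s,
                    "target": e.target,
                    "peak_score": e.peak_score,
                    "duration_s": e.duration_s,
                }
                for e in events
            ],
        }

    if config.run_shuffles:
        _log("shuffle", "unit-identity and temporal controls")
        sh = shuffle_unit_identity(spikes, seed=int(rng_seeds[3]), segment_s=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, ys = pat.build_labelled_patterns(
                sh.subset(resp_idx), schedule, rest_per_event=2, seed=int(rng_seeds[1])
            )
            acc_s = cross_validate(
                Xs, ys, lam=config.lam, n_rep=config.cv_repetitions,
                seed=int(rng_seeds[4]),
            )
        sh_events = []
        if config.run_trajectory and events:
            c = events[0].time_s + 0.5
            if c - 2.0 >= 0 and c + 4.0 <= spikes.span_s:
                sh_t = shuffle_temporal(spikes, c, seed=int(rng_seeds[5]))
                traj_s = sliding_projection(
                    sh_t.subset(resp_idx), model, t_start=c - 2.0, t_stop=c + 3.0
                )
                sh_events = detect_reactivations(
                    traj_s, model, schedule, theta=config.theta,
                    d_min_s=config.d_min_s, spikes=sh_t.subset(resp_idx),
                )
        summary["shuffles"] = shuffle_report(
            {"accuracy": float(acc.mean()), "n_reactivations": len(events)},
            {"accuracy": float(acc_s.mean()), "n_reactivations": len(sh_events)},
        )

    if config.run_correlation:
        _log("correlate", "pairwise correlations by period")
        react_centers = (
            np.asarray([e.time_s + 0.5 for e in events])
            if events
            else np.empty(0)
        )
        periods = {
            "pre": (pat.rest_window_starts(schedule, 1, 1.0, seed=int(rng_seeds[6])), 1.0),
            "event": (schedule.onsets(), 1.0),
        }
        if react_centers.size >= 2:
            periods["reactivation"] = (react_centers - 2.0, 4.0)
        corr_summary = {}
        for name, mask in (
            ("invariant", tax["intensity_class"] == "invariant"),
            ("sensitive", tax["intensity_class"].str.startswith("sensitive")),
        ):
            idx = tax.index[mask].to_numpy()
            if idx.size < 5:
                continue
            pairs = period_pair_correlations(spikes.subset(idx), periods)
            thr = (
                config.correlation_threshold_invariant
                if name == "invariant"
                else config.correlation_threshold_sensitive
            )
            kept = filter_pairs(pairs, thr)
            stats_df = period_correlation_stats(kept, list(periods))
            entry = {
                "n_pairs_retained": int(len(kept)),
                "period_stats": stats_df.to_dict(orient="records"),
            }
            if name == "invariant" and "reactivation" in periods:
                try:
                    entry["explained_variance"] = ev_analysis(kept)
                except ValueError:
                    pass
            corr_summary[name] = entry
        summary["correlation"] = corr_summary

    return _finish(summary, config)


def _finish(summary: dict, config: RunConfig) -> dict:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_json(summary, out / "summary.json")
        _log("done", f"summary written to {out / 'summary.json'}")
    return summary
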