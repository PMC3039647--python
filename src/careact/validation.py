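"""Study-condition validation experiments.

Each function runs one self-contained, seeded experiment at the
conditions the analyses are designed for (population sizes, 7
repetitions per session, randomized 1-3 min intervals, amplitude-0.4
reactivations) and returns the quantities of scientific interest:
taxonomy recovery rates, classifier accuracy and its collapse under
shuffling, the monotone intensity-separation trend, reactivation
detection operating characteristics, and correlation/explained-variance
structure. They are used both by the test suite and by the acceptance
script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import patterns as pat
from .containers import EventSchedule
from .correlation import (
    ev_analysis,
    filter_pairs,
    period_correlation_stats,
    period_pair_correlations,
)
from .mda import compute_scatter, cross_validate, fit_mda, regularize_within, \
    rest_normalized_class_distances, _class_covariances
from .responses import characterize, taxonomy_report
from .shuffles import shuffle_temporal
from .simulate import (
    GroundTruth,
    SimulationConfig,
    build_schedule,
    generate_population,
    inject_reactivations,
    make_gaussian_patterns,
    selectivity_group,
)
from .trajectory import (
    calibration_params,
    detect_reactivations,
    sliding_projection,
    subpopulation_projection,
)

DROP_SESSIONS = (("drop", 1), ("drop", 2), ("drop", 3))

#: Reference census of the pooled recordings: 583/1623 responsive units;
#: invariant group split 152/75/57 and sensitive group split 134/75/89
#: across general/subgeneral/specific selectivity.
REFERENCE_COUNTS = {
    "responsive": 583,
    "total": 1623,
    "invariant": {"general": 152, "subgeneral": 75, "specific": 57},
    "sensitive": {"general": 134, "subgeneral": 75, "specific": 89},
}


def printed_count_report() -> dict:
    """Taxonomy percentages for the reference unit census."""
    return taxonomy_report(
        REFERENCE_COUNTS["responsive"],
        REFERENCE_COUNTS["total"],
        invariant_counts=REFERENCE_COUNTS["invariant"],
        sensitive_counts=REFERENCE_COUNTS["sensitive"],
    )


def eigensolver_agreement(seed: int = 0, n_features: int = 20, lam: float = 0.5) -> dict:
    """Cross-check the fitted discriminant basis against a dense solver.

    Fits MDA on a random Gaussian fixture and compares its eigenpairs
    with ``numpy.linalg.eig`` applied to the asymmetric matrix
    ``inv(S_W') S_B``, plus the 2-class Fisher closed form.
    """
    rng = np.random.default_rng(seed)
    X, y = make_gaussian_patterns(
        n_classes=4, n_features=n_features, n_per_class=12, separation=4.0, seed=seed
    )
    X += rng.normal(scale=0.1, size=X.shape)
    model = fit_mda(X, y, lam=lam)
    S_B, _S_W, info = compute_scatter(X, y)
    covs = _class_covariances(X, y, info["classes"])
    S_Wp = regularize_within(covs, lam, info["n_i"])
    evals_ref, evecs_ref = np.linalg.eig(np.linalg.solve(S_Wp, S_B))
    order = np.argsort(evals_ref.real)[::-1]
    evals_ref = evals_ref.real[order][: model.n_components]
    evecs_ref = evecs_ref.real[:, order][:, : model.n_components]

    rel_eval = np.max(
        np.abs(model.eigenvalues - evals_ref) / np.maximum(np.abs(evals_ref), 1e-300)
    )
    # eigenvectors agree up to scale: compare absolute cosine
    cos = np.abs(
        np.sum(model.W * (evecs_ref / np.linalg.norm(evecs_ref, axis=0)), axis=0)
    )
    # generalized eigen residual ||S_B v - e S_W' v|| <= tol * ||S_B v||
    res = np.max(
        [
            np.linalg.norm(S_B @ v - e * (S_Wp @ v)) / max(np.linalg.norm(S_B @ v), 1e-300)
            for v, e in zip(model.W.T, model.eigenvalues)
        ]
    )

    X2, y2 = make_gaussian_patterns(
        n_classes=2, n_features=n_features, n_per_class=15, separation=3.0,
        seed=seed + 1, rest_label="rest",
    )
    m2 = fit_mda(X2, y2, lam=lam)
    S_B2, _w, info2 = compute_scatter(X2, y2)
    covs2 = _class_covariances(X2, y2, info2["classes"])
    S_Wp2 = regularize_within(covs2, lam, info2["n_i"])
    fisher = np.linalg.solve(S_Wp2, info2["class_means"][0] - info2["class_means"][1])
    fisher /= np.linalg.norm(fisher)
    fisher_cos = float(abs(fisher @ m2.W[:, 0]))
    return {
        "max_rel_eigenvalue_error": float(rel_eval),
        "min_eigenvector_cosine": float(cos.min()),
        "max_generalized_residual": float(res),
        "two_class_fisher_cosine": fisher_cos,
    }


def _expected_labels(truth: GroundTruth, schedule: EventSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Selectivity/intensity labels the taxonomy should recover, given the
    stimulus types actually delivered (intensity is only decidable for
    units responsive to a parametric type)."""
    ev_levels = {}
    for ev in schedule.events:
        ev_levels.setdefault(ev.event_type, set()).add(ev.level)
    parametric = {t for t, lv in ev_levels.items() if len(lv) >= 2}
    sel, inten = [], []
    for r in truth.units.itertuples():
        if not r.responsive:
            sel.append("none")
            inten.append("n/a")
            continue
        sel.append(r.selectivity)
        inten.append(r.intensity_class if parametric & set(r.sel_types) else "n/a")
    return np.asarray(sel, dtype=object), np.asarray(inten, dtype=object)


def taxonomy_recovery(seed: int = 0, n_units: int = 500) -> dict:
    """Recover the three-way taxonomy on one synthetic population.

    Returns joint (responsive, selectivity, intensity) accuracy, the
    recovered responsive fraction, and per-component accuracies.
    """
    cfg = SimulationConfig(n_units=n_units, seed=seed)
    schedule = build_schedule(cfg)
    spikes, truth = generate_population(cfg, schedule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _table, tax = characterize(spikes, schedule, seed=seed + 1)
    exp_sel, exp_int = _expected_labels(truth, schedule)
    resp_ok = tax["responsive"].to_numpy() == truth.units["responsive"].to_numpy()
    sel_ok = tax["selectivity"].to_numpy() == exp_sel
    int_ok = tax["intensity_class"].to_numpy() == exp_int
    joint = resp_ok & sel_ok & int_ok
    return {
        "joint_accuracy": float(joint.mean()),
        "responsive_accuracy": float(resp_ok.mean()),
        "selectivity_accuracy": float(sel_ok.mean()),
        "intensity_accuracy": float(int_ok.mean()),
        "recovered_responsive_fraction": float(tax["responsive"].mean()),
        "true_responsive_fraction": float(truth.units["responsive"].mean()),
        "n_units": n_units,
    }


def intensity_recovery(seed: int = 0, n_units: int = 200) -> dict:
    """Invariant-vs-sensitive recovery at gain ratio 1:2:4, 2 Hz baseline.

    All units respond to the parametric stimulus so every unit yields an
    intensity call; accuracy is the fraction of units whose
    invariant/sensitive call matches the generator.
    """
    cfg = SimulationConfig(
        n_units=n_units,
        seed=seed,
        fraction_responsive=1.0,
        invariant_split=(1.0, 0.0, 0.0),
        sensitive_split=(1.0, 0.0, 0.0),
        sensitive_down_fraction=0.0,
        pyramidal_rate_range=(2.0, 2.0),
        interneuron_fraction=0.0,
        invariant_gain=2.0,
        sensitive_up_gains=(1.0, 2.0, 4.0),
        sessions=DROP_SESSIONS,
    )
    schedule = build_schedule(cfg)
    spikes, truth = generate_population(cfg, schedule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _table, tax = characterize(spikes, schedule, seed=seed + 1)
    decided = tax["intensity_class"] != "n/a"
    true_sens = truth.units["intensity_class"].str.startswith("sensitive").to_numpy()
    call_sens = tax["intensity_class"].str.startswith("sensitive").to_numpy()
    acc = float((true_sens[decided] == call_sens[decided]).mean())
    return {"accuracy": acc, "n_decided": int(decided.sum()), "n_units": n_units}


def classification_collapse(seed: int = 0, n_rep: int = 100, separation: float = 6.0) -> dict:
    """Cross-validated 5-class accuracy and its collapse under
    unit-identity shuffling.

    Patterns are 5 Gaussian classes (rest plus four events) separated by
    ``separation`` standard deviations. The shuffle re-draws the
    unit-to-feature assignment independently for every sample — spike
    activities exchanged among units at all times — which erases the
    class structure; accuracy must fall to the 1/N chance level.
    """
    X, y = make_gaussian_patterns(
        n_classes=5, n_features=40, n_per_class=20, separation=separation, seed=seed,
        equal_norm=True,
    )
    acc = cross_validate(X, y, lam=0.5, n_rep=n_rep, seed=seed + 1)
    # several independent shuffles: cross-validating one fixed shuffled
    # realization has substantial dataset-level variance
    n_shuffles = 5
    rng = np.random.default_rng(seed + 2)
    acc_s = []
    for _ in range(n_shuffles):
        Xs = np.empty_like(X)
        for i in range(X.shape[0]):
            Xs[i] = X[i, rng.permutation(X.shape[1])]
        acc_s.append(
            cross_validate(
                Xs, y, lam=0.5, n_rep=max(n_rep // n_shuffles, 1),
                seed=int(rng.integers(2**31)),
            )
        )
    acc_s = np.concatenate(acc_s)
    return {
        "accuracy": float(acc.mean()),
        "accuracy_se": float(acc.std(ddof=1) / np.sqrt(len(acc))),
        "shuffled_accuracy": float(acc_s.mean()),
        "shuffled_accuracy_se": float(acc_s.std(ddof=1) / np.sqrt(len(acc_s))),
        "chance": 1.0 / len(set(y.tolist())),
        "n_rep": n_rep,
    }


def monotone_intensity(seed: int = 0, n_runs: int = 100, n_units: int = 400) -> dict:
    """Fraction of seeded runs whose rest-normalized cluster distances
    increase strictly with drop intensity level."""
    n_mono = 0
    for r in range(n_runs):
        cfg = SimulationConfig(n_units=n_units, seed=seed + 1000 + r, sessions=DROP_SESSIONS)
        schedule = build_schedule(cfg)
        spikes, truth = generate_population(cfg, schedule)
        resp = _responsive_with(truth, "drop")
        X, y = pat.build_labelled_patterns(
            spikes.subset(resp), schedule, rest_per_event=2, seed=seed + r
        )
        model = fit_mda(X, y)
        d = rest_normalized_class_distances(model)
        n_mono += d["drop-1"] < d["drop-2"] < d["drop-3"]
    return {"fraction_monotone": n_mono / n_runs, "n_runs": n_runs, "n_units": n_units}


def _responsive_with(truth: GroundTruth, event_type: str) -> np.ndarray:
    u = truth.units
    mask = u["responsive"] & u["sel_types"].map(lambda s: event_type in s)
    return u[mask].index.to_numpy()


def _match(inj_times, t, tol=1.0):
    return np.any(np.abs(inj_times - t) <= tol)


def reactivation_benchmark(
    seed: int = 0,
    n_seeds: int = 20,
    n_units: int = 280,
    n_subpop_seeds: int = 4,
    n_shuffle_events: int = 8,
) -> dict:
    """Injected-reactivation recovery, subpopulation dissociation and the
    temporal-shuffle control, pooled over seeded sessions.

    Per session: simulate a drop-intensity experiment with amplitude-0.4
    reactivations, fit the encoding model on the responsive units, scan
    the whole recording and compare detections against the injection
    times (hit = detection within 1 s). Reports pooled sensitivity,
    false events per minute of scanned rest time, the invariant- vs
    sensitive-subspace reactivation magnitude tests, and the fraction of
    post-shuffle window samples inside the rest 2-sigma boundary.
    """
    hits = 0
    n_inj = 0
    n_false = 0
    rest_minutes = 0.0
    containment: list[float] = []
    inv_peaks, inv_base, sens_peaks, sens_base = [], [], [], []
    levels = []
    for s in range(n_seeds):
        cfg = SimulationConfig(n_units=n_units, seed=seed + 100 + s, sessions=DROP_SESSIONS)
        schedule = build_schedule(cfg)
        sp0, tr0 = generate_population(cfg, schedule)
        spikes, truth = inject_reactivations(sp0, tr0, schedule, cfg)
        resp = _responsive_with(truth, "drop")
        spR = spikes.subset(resp)
        X, y = pat.build_labelled_patterns(spR, schedule, rest_per_event=2, seed=seed + s)
        model = fit_mda(X, y)
        traj = sliding_projection(spR, model)
        events = detect_reactivations(traj, model, schedule, spikes=spR)
        inj_t = truth.reactivations["time_s"].to_numpy()
        hits += sum(_match(inj_t, e.time_s) for e in events)
        n_inj += len(inj_t)
        n_false += sum(not _match(inj_t, e.time_s) for e in events)
        rest_minutes += (schedule.span_s - 4.0 * len(schedule)) / 60.0

        if s < n_subpop_seeds:
            u = truth.units
            inv = [i for i, gi in enumerate(resp) if u.loc[gi, "intensity_class"] == "invariant"]
            sens = [i for i, gi in enumerate(resp) if u.loc[gi, "intensity_class"] != "invariant"]
            for sub_idx, peaks, base in ((inv, inv_peaks, inv_base), (sens, sens_peaks, sens_base)):
                _m, traj_sub = subpopulation_projection(spR, X, y, sub_idx)
                sc = _calibrated(traj_sub, schedule)
                for t, lvl in zip(inj_t, truth.reactivations["level"]):
                    w = (traj_sub.times >= t - 1.0) & (traj_sub.times <= t + 1.0)
                    if w.any():
                        peaks.append(sc[w].max())
                        if sub_idx is inv:
                            levels.append(int(lvl))
                base.extend(_baseline_peaks(traj_sub, sc, schedule, inj_t, len(inj_t)))
            # temporal-shuffle control around detected reactivations
            med, scale = calibration_params(traj, schedule)
            for e in events[:n_shuffle_events]:
                c = e.time_s + 0.5
                if c - 2.0 < 0 or c + 4.0 > spikes.span_s:
                    continue
                sh = shuffle_temporal(spikes, c, window_s=4.0, bin_s=0.01, seed=seed + int(c))
                traj_w = sliding_projection(
                    sh.subset(resp), model, t_start=c - 2.0, t_stop=c + 3.0
                )
                z = (traj_w.rest_score - med) / scale
                keep = np.ones(traj_w.times.size, bool)
                for t0 in inj_t:
                    if abs((t0 + 0.5) - c) < 0.2:
                        continue
                    keep &= ~((traj_w.times > t0 - 1.0) & (traj_w.times < t0 + 1.0))
                containment.append(float((z[keep] <= 2.0).mean()))

    inv_test = stats.mannwhitneyu(inv_peaks, inv_base, alternative="greater")
    sens_test = stats.mannwhitneyu(sens_peaks, sens_base, alternative="greater")
    lv = np.asarray(levels)
    ip = np.asarray(inv_peaks)
    return {
        "sensitivity": hits / n_inj,
        "false_per_min": n_false / rest_minutes,
        "n_injections": n_inj,
        "invariant_magnitude_p": float(inv_test.pvalue),
        "sensitive_magnitude_p": float(sens_test.pvalue),
        "invariant_mean_peak": float(np.mean(inv_peaks)),
        "sensitive_mean_peak": float(np.mean(sens_peaks)),
        "per_level_mean_peak": {
            int(l): float(ip[lv == l].mean()) for l in (1, 2, 3) if np.any(lv == l)
        },
        "shuffle_containment": float(np.mean(containment)),
        "n_seeds": n_seeds,
    }


def _calibrated(traj, schedule):
    med, scale = calibration_params(traj, schedule)
    return (traj.rest_score - med) / scale


def _baseline_peaks(traj, sc, schedule, inj_t, n, width=1.0):
    """Matched non-reactivation samples: max score over windows of the same
    width at evenly spaced rest positions.

    Only positions whose full +/-width neighborhood is eligible are used,
    so baseline maxima are taken over exactly as many samples as the
    reactivation maxima — a truncated window would bias its maximum low
    and fabricate a significant contrast.
    """
    from .trajectory import _excluded_mask

    ok = ~_excluded_mask(traj.times, traj.window_s, schedule)
    for t0 in inj_t:
        ok &= ~((traj.times > t0 - 2.0) & (traj.times < t0 + 2.0))
    half = int(round(width / traj.step_s))
    full = np.zeros_like(ok)
    csum = np.concatenate([[0], np.cumsum(ok)])
    win = csum[2 * half + 1 :] - csum[: -(2 * half + 1)]
    full[half : half + win.size] = win == 2 * half + 1
    cand = np.flatnonzero(full)
    if cand.size == 0:
        return []
    picks = cand[np.linspace(0, cand.size - 1, n).astype(int)]
    return [float(sc[i - half : i + half + 1].max()) for i in picks]


def correlation_benchmark(
    seed: int = 0,
    n_runs: int = 20,
    n_units: int = 200,
    n_pooled: int = 5,
) -> dict:
    """Period-wise correlation structure and explained variance.

    Per run: simulate the full 6-session experiment with reactivations,
    detect them with the encoding model, and correlate unit pairs in
    50-ms bins during pre-event baseline, the one-second event windows
    and +/-2 s around detected reactivations. Reports the
    invariant/sensitive dissociation (pairs pooled over the first
    ``n_pooled`` runs), the general > subgeneral > specific ordering
    fraction and the EV vs. reversed-EV comparison across runs.
    """
    pooled = {"invariant": [], "sensitive": []}
    order_ok = 0
    ev_ok = 0
    evs, ev_revs = [], []
    for r in range(n_runs):
        cfg = SimulationConfig(n_units=n_units, seed=seed + 500 + r)
        schedule = build_schedule(cfg)
        sp0, tr0 = generate_population(cfg, schedule)
        spikes, truth = inject_reactivations(sp0, tr0, schedule, cfg)
        u = truth.units
        resp = u[u["responsive"]].index.to_numpy()
        spR = spikes.subset(resp)
        X, y = pat.build_labelled_patterns(spR, schedule, rest_per_event=2, seed=seed + r)
        model = fit_mda(X, y)
        traj = sliding_projection(spR, model)
        events = detect_reactivations(traj, model, schedule, spikes=spR)
        react_centers = np.asarray([e.time_s + 0.5 for e in events])
        if react_centers.size < 5:
            react_centers = truth.reactivations["time_s"].to_numpy() + 0.5
        periods = {
            "pre": (pat.rest_window_starts(schedule, 1, 1.0, seed=seed + r), 1.0),
            "event": (schedule.onsets(), 1.0),
            "reactivation": (react_centers - 2.0, 4.0),
        }
        run_res = {}
        gmaps = {}
        for name in ("invariant", "sensitive"):
            if name == "invariant":
                idx = u[u["intensity_class"] == "invariant"].index
            else:
                idx = u[u["intensity_class"].str.startswith("sensitive")].index
            spG = spikes.subset(idx.to_numpy())
            pairs = period_pair_correlations(spG, periods)
            gmap = pd.Series(
                {j: selectivity_group(u.loc[i, "selectivity"]) for j, i in enumerate(idx)}
            )
            pairs["group"] = pairs["u"].map(gmap).where(
                pairs["u"].map(gmap) == pairs["v"].map(gmap)
            )
            thr = 0.1 if name == "invariant" else 0.05
            kept = filter_pairs(pairs, thr, non_basal_periods=["event", "reactivation"])
            if r < n_pooled:
                pooled[name].append(kept)
            run_res[name] = pairs
            gmaps[name] = gmap
        # ordering on all within-group pairs: top-k display selection adds
        # selection noise that the group contrast does not need
        within = run_res["invariant"].dropna(subset=["group"])
        og = within.groupby("group")["r_reactivation"].apply(lambda s: s.abs().mean())
        order_ok += bool(
            og.get("general", 0) > og.get("subgeneral", 0) > og.get("specific", 0)
        )
        inv_kept = filter_pairs(
            run_res["invariant"], 0.1, non_basal_periods=["event", "reactivation"]
        )
        ev = ev_analysis(inv_kept)
        evs.append(ev["ev"])
        ev_revs.append(ev["ev_reversed"])
        ev_ok += ev["ev"] > ev["ev_reversed"]

    stats_out = {}
    for name in ("invariant", "sensitive"):
        allp = pd.concat(pooled[name], ignore_index=True)
        st = period_correlation_stats(allp, ["pre", "event", "reactivation"])
        stats_out[name] = {
            "react_p": float(st[st.period == "reactivation"].iloc[0].p_vs_pre),
            "event_p": float(st[st.period == "event"].iloc[0].p_vs_pre),
            "pre_mean_abs_r": float(st[st.period == "pre"].iloc[0].mean_abs_r),
            "react_mean_abs_r": float(st[st.period == "reactivation"].iloc[0].mean_abs_r),
        }
    return {
        "invariant": stats_out["invariant"],
        "sensitive": stats_out["sensitive"],
        "ordering_fraction": order_ok / n_runs,
        "ev_mean": float(np.mean(evs)),
        "ev_reversed_mean": float(np.mean(ev_revs)),
        "ev_exceeds_reversed_fraction": ev_ok / n_runs,
        "n_runs": n_runs,
    }
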