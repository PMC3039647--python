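"""Pairwise cross-correlation by period and Explained Variance.

Unit pairs are correlated on firing-rate sequences binned at 50 ms,
concatenated across the repetitions of a period (pre-event baseline,
the one-second event windows, detected reactivation windows, or matched
post-event non-reactivation windows). The Explained Variance (EV)
statistic is the squared partial correlation of the event- and
post-period pair-correlation vectors controlling for the pre period:

    EV = [ (r_ep,post - r_ep,pre * r_pre,post)
           / sqrt((1 - r_ep,pre^2)(1 - r_pre,post^2)) ]^2

bounded in [0, 1]; the reversed control swaps the roles of pre and post.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpikeTrainSet

__all__ = [
    "binned_rate_matrix",
    "pair_correlation",
    "pair_correlation_matrix",
    "filter_pairs",
    "select_top_pairs",
    "period_correlation_stats",
    "explained_variance",
    "ev_analysis",
]

TOP_PAIR_COUNTS = {"specific": 10, "subgeneral": 20, "general": 30}


def binned_rate_matrix(
    spikes: SpikeTrainSet, window_starts: np.ndarray, width_s: float, bin_s: float = 0.05
) -> np.ndarray:
    """Concatenated binned-rate sequences, ``(n_units, n_windows * n_bins)``.

    Window ``i`` contributes bins ``x_ij`` = rate in ``[start_i + j*bin,
    start_i + (j+1)*bin)``; windows are the repetitions.
    """
    window_starts = np.asarray(window_starts, dtype=float)
    n_bins = int(round(width_s / bin_s))
    starts = (window_starts[:, None] + bin_s * np.arange(n_bins)[None, :]).ravel()
    return spikes.rates_in_windows(starts, bin_s)


def pair_correlation_matrix(B: np.ndarray) -> np.ndarray:
    """Pearson correlation between all unit rows of a binned-rate matrix.

    Zero-variance rows yield NaN rows/columns (flagged, excluded later).
    """
    B = np.asarray(B, dtype=float)
    sd = B.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(B)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, 1.0)
    return R


def pair_correlation(
    spikes: SpikeTrainSet,
    u: int,
    v: int,
    window_starts: np.ndarray,
    width_s: float,
    bin_s: float = 0.05,
    per_repetition_average: bool = False,
) -> float:
    """Correlation of one unit pair over a period's repetitions.

    Default: Pearson correlation of the concatenated per-repetition
    binned-frequency vectors. With ``per_repetition_average`` the
    correlation is computed within each repetition and averaged.
    """
    if u == v:
        raise ValueError("pair must be two distinct units")
    window_starts = np.asarray(window_starts, dtype=float)
    if window_starts.size < 2 and not per_repetition_average:
        raise ValueError("need >= 2 repetitions")
    sub = spikes.subset([u, v])
    if per_repetition_average:
        rs = []
        for s in window_starts:
            B = binned_rate_matrix(sub, np.asarray([s]), width_s, bin_s)
            if B[0].std() == 0 or B[1].std() == 0:
                continue
            rs.append(np.corrcoef(B)[0, 1])
        return float(np.mean(rs)) if rs else float("nan")
    B = binned_rate_matrix(sub, window_starts, width_s, bin_s)
    return float(pair_correlation_matrix(B)[0, 1])


def _pair_frame(R: np.ndarray, unit_ids=None) -> pd.DataFrame:
    n = R.shape[0]
    iu, iv = np.triu_indices(n, k=1)
    ids = list(range(n)) if unit_ids is None else list(unit_ids)
    return pd.DataFrame(
        {"u": [ids[i] for i in iu], "v": [ids[j] for j in iv], "r": R[iu, iv]}
    )


def period_pair_correlations(
    spikes: SpikeTrainSet,
    periods: dict[str, tuple[np.ndarray, float]],
    bin_s: float = 0.05,
    unit_ids=None,
) -> pd.DataFrame:
    """Pair-correlation table across periods.

    ``periods`` maps a period name to ``(window_starts, width_s)``.
    Returns a DataFrame with columns ``u``, ``v`` and one ``r_<period>``
    column per period.
    """
    out = None
    for name, (starts, width) in periods.items():
        B = binned_rate_matrix(spikes, starts, width, bin_s)
        df = _pair_frame(pair_correlation_matrix(B), unit_ids)
        df = df.rename(columns={"r": f"r_{name}"})
        out = df if out is None else out.merge(df, on=["u", "v"])
    return out


def filter_pairs(
    pairs: pd.DataFrame, threshold: float, non_basal_periods: list[str] | None = None
) -> pd.DataFrame:
    """Retain pairs whose best non-basal-period |r| reaches ``threshold``.

    Pairs with undefined (NaN) correlations in all tested periods drop out.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cols = (
        [f"r_{p}" for p in non_basal_periods]
        if non_basal_periods is not None
        else [c for c in pairs.columns if c.startswith("r_") and c != "r_pre"]
    )
    best = pairs[cols].abs().max(axis=1)
    return pairs[best >= threshold].reset_index(drop=True)


def select_top_pairs(
    pairs: pd.DataFrame,
    groups: pd.Series,
    rank_column: str = "r_event",
    counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Top pairs per selectivity group by event-period |r|.

    ``groups`` maps unit id -> selectivity group; a pair belongs to a
    group when both units do. Default counts: 10 specific / 20 subgeneral
    / 30 general. Returns fewer (with a warning) when a group is small.
    """
    counts = dict(TOP_PAIR_COUNTS if counts is None else counts)
    frames = []
    for group, k in counts.items():
        mask = pairs["u"].map(groups).eq(group) & pairs["v"].map(groups).eq(group)
        sub = pairs[mask].copy()
        sub = sub.reindex(sub[rank_column].abs().sort_values(ascending=False).index)
        if len(sub) < k:
            warnings.warn(f"group {group!r} has only {len(sub)} pairs (requested {k})")
        sub = sub.head(k)
        sub["group"] = group
        frames.append(sub)
    return pd.concat(frames, ignore_index=True) if frames else pairs.iloc[0:0]


def period_correlation_stats(
    pairs: pd.DataFrame,
    periods: list[str],
    group_column: str | None = None,
    baseline_period: str = "pre",
) -> pd.DataFrame:
    """Mean |r| per period (per group) with a paired rank test vs. the
    baseline period (Wilcoxon signed-rank on |r|)."""
    def one(sub: pd.DataFrame, group) -> list[dict]:
        rows = []
        base = sub[f"r_{baseline_period}"].abs()
        for p in periods:
            r = sub[f"r_{p}"].abs()
            ok = base.notna() & r.notna()
            row = {
                "group": group,
                "period": p,
                "mean_abs_r": float(r[ok].mean()),
                "n_pairs": int(ok.sum()),
            }
            if p != baseline_period and ok.sum() >= 5 and not np.allclose(
                r[ok], base[ok]
            ):
                row["p_vs_pre"] = float(
                    stats.wilcoxon(r[ok], base[ok], alternative="greater").pvalue
                )
            else:
                row["p_vs_pre"] = float("nan")
            rows.append(row)
        return rows

    rows = []
    if group_column is None:
        rows += one(pairs, "all")
    else:
        for g, sub in pairs.groupby(group_column):
            rows += one(sub, g)
    return pd.DataFrame(rows)


def explained_variance(r_ep_post: float, r_ep_pre: float, r_pre_post: float) -> float:
    """EV: squared partial correlation of event and post controlling pre."""
    for r in (r_ep_pre, r_pre_post):
        if abs(r) >= 1.0:
            raise ValueError("partial correlation undefined at |r| = 1")
    num = r_ep_post - r_ep_pre * r_pre_post
    den = np.sqrt((1.0 - r_ep_pre**2) * (1.0 - r_pre_post**2))
    return float((num / den) ** 2)


def ev_analysis(pairs: pd.DataFrame, event: str = "event", pre: str = "pre",
                post: str = "reactivation") -> dict:
    """EV of a pair table plus the reversed (pre-as-outcome) control.

    Correlates the pair-correlation vectors across pairs between periods,
    then applies the EV formula. Pairs with NaN in any period drop out.
    """
    cols = [f"r_{pre}", f"r_{event}", f"r_{post}"]
    sub = pairs[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete pairs for EV")
    r_pre = sub[f"r_{pre}"].to_numpy()
    r_ev = sub[f"r_{event}"].to_numpy()
    r_post = sub[f"r_{post}"].to_numpy()
    r_ep_post = float(np.corrcoef(r_ev, r_post)[0, 1])
    r_ep_pre = float(np.corrcoef(r_ev, r_pre)[0, 1])
    r_pre_post = float(np.corrcoef(r_pre, r_post)[0, 1])
    return {
        "r_event_post": r_ep_post,
        "r_event_pre": r_ep_pre,
        "r_pre_post": r_pre_post,
        "ev": explained_variance(r_ep_post, r_ep_pre, r_pre_post),
        "ev_reversed": explained_variance(r_ep_pre, r_ep_post, r_pre_post),
        "n_pairs": int(len(sub)),
    }
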