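"""Agglomerative clustering of unit response vectors.

Units are clustered on their per-type T-score vectors by repeatedly
merging the two nearest groups under Euclidean distance between group
centroids, recomputing the merged group's mean at every step. Leaves are
then ordered for display by orienting subtrees at each merge so the
adjacent boundary leaves are as similar as possible, producing the
general-to-specific heatmap layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Dendrogram:
    """Merge history: ``(step, left_id, right_id, distance, new_size)``.

    Original leaves are ids ``0..N-1``; the cluster created at step ``s``
    gets id ``N + s``. Exactly ``N - 1`` merges for ``N`` leaves.
    """

    merges: list[tuple[int, int, int, float, int]]
    n_leaves: int
    members: dict[int, list[int]]  # cluster id -> leaf ids in merge order


def cluster_responses(T_matrix: np.ndarray) -> Dendrogram:
    """Centroid-linkage agglomeration of response vectors.

    Ties in the nearest-pair search break on the smallest (left, right)
    id pair, so the result is deterministic.
    """
    X = np.asarray(T_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("T_matrix must be 2-D (units x event types)")
    if not np.all(np.isfinite(X)):
        raise ValueError("T_matrix contains non-finite values")
    n = X.shape[0]
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    cent = X.copy()  # row j is the centroid of active[j]
    merges: list[tuple[int, int, int, float, int]] = []
    for step in range(n - 1):
        diff = cent[:, None, :] - cent[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        iu = np.triu_indices(len(active), k=1)
        flat = D[iu]
        dmin = flat.min()
        ties = np.flatnonzero(flat == dmin)
        # smallest (left id, right id) among tied nearest pairs
        pairs = [
            tuple(sorted((active[iu[0][t]], active[iu[1][t]]))) for t in ties
        ]
        a, b = min(pairs)
        new_id = n + step
        members[new_id] = members[a] + members[b]
        new_centroid = X[members[new_id]].mean(axis=0)
        merges.append((step, a, b, float(dmin), len(members[new_id])))
        keep = [j for j, c in enumerate(active) if c not in (a, b)]
        active = [active[j] for j in keep] + [new_id]
        cent = np.vstack([cent[keep], new_centroid])
    return Dendrogram(merges=merges, n_leaves=n, members=members)


def order_leaves(dend: Dendrogram, T_matrix: np.ndarray) -> list[int]:
    """Display order of leaves.

    At each merge the two subtrees keep their internal order but may be
    flipped; the orientation minimizing the Euclidean distance between
    the two boundary leaves at the junction is kept (ties prefer no
    flip). For a single pair, the lower id comes first.
    """
    X = np.asarray(T_matrix, dtype=float)
    order: dict[int, list[int]] = {i: [i] for i in range(dend.n_leaves)}
    for step, a, b, _d, _sz in dend.merges:
        left, right = order[a], order[b]
        best = None
        for fl in (False, True):
            for fr in (False, True):
                lo = left[::-1] if fl else left
                ro = right[::-1] if fr else right
                cost = float(np.linalg.norm(X[lo[-1]] - X[ro[0]]))
                key = (cost, fl, fr)
                if best is None or key < best[0:3]:
                    best = (cost, fl, fr, lo + ro)
        order[dend.n_leaves + step] = best[3]
    return order[dend.n_leaves + len(dend.merges) - 1] if dend.merges else order[0]


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels (0..k-1) after stopping at ``k`` clusters."""
    if not 1 <= k <= dend.n_leaves:
        raise ValueError("k out of range")
    alive = set(range(dend.n_leaves))
    for step, a, b, _d, _sz in dend.merges:
        if len(alive) == k:
            break
        alive.discard(a)
        alive.discard(b)
        alive.add(dend.n_leaves + step)
    labels = np.empty(dend.n_leaves, dtype=int)
    for j, cid in enumerate(sorted(alive)):
        labels[dend.members[cid]] = j
    return labels
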