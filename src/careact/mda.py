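"""Regularized Multiple Discriminant Analysis (MDA) for ensemble patterns.

Population activity around each stimulus is summarized as a feature
vector (the two 500-ms-bin firing rates of every unit, concatenated) and
labelled by condition (rest, or event type x intensity). MDA finds at
most ``N - 1`` projection directions for ``N`` classes by solving the
generalized eigenproblem of the between-class scatter

    S_B = sum_i n_i (m_i - m)(m_i - m)^t

against the regularized within-class scatter assembled from shrunken
per-class covariances

    Omega_i' = (1 - lambda) Omega_i + lambda * c_i * I,
    S_W' = sum_i n_i Omega_i'

with ``lambda`` in [0, 1]. Shrinkage renders S_W' invertible under the
chronic under-sampling of ensemble recordings (many more units than
trials). By default the identity is scaled by the mean diagonal of
Omega_i (``c_i``) so the shrinkage target respects the units' rate
scales; ``scale_aware=False`` uses the plain identity.

Classes are modelled as multivariate Gaussians in the projection
subspace; classification is by minimal Mahalanobis distance, and
distances from rest are reported in units of the rest cluster's standard
deviation so separations are comparable across data sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "MDAModel",
    "compute_scatter",
    "regularize_within",
    "fit_mda",
    "classify",
    "cross_validate",
    "select_lambda",
    "rest_normalized_class_distances",
]


@dataclass
class MDAModel:
    """Fitted discriminant subspace and per-class Gaussians.

    ``W`` has one column per kept discriminant direction (at most
    ``N - 1``); ``class_means``/``class_covs`` live in the subspace.
    ``rest_sd`` is the isotropic rest-cluster standard deviation
    ``sqrt(trace(cov_rest)/k)`` used for rest-normalized distances, and
    ``rest_chi_mean``/``rest_chi_sd`` calibrate the rest-distance score
    used for trajectory detection (mean/sd of the rest training samples'
    Mahalanobis distance from their own centroid).
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    classes: list
    class_means: np.ndarray
    class_covs: np.ndarray
    class_cov_invs: np.ndarray
    lam: float
    rest_label: str
    rest_sd: float
    rest_chi_mean: float
    rest_chi_sd: float
    n_features: int
    feature_means: np.ndarray = field(default=None)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def rest_index(self) -> int:
        return self.classes.index(self.rest_label)

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, model has {self.n_features}"
            )
        return X @ self.W

    def mahalanobis(self, Z: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of subspace points to every class
        Gaussian; shape ``(n_samples, n_classes)``."""
        Z = np.atleast_2d(Z)
        out = np.empty((Z.shape[0], len(self.classes)))
        for i in range(len(self.classes)):
            d = Z - self.class_means[i]
            out[:, i] = np.sqrt(np.einsum("ij,jk,ik->i", d, self.class_cov_invs[i], d))
        return out

    def rest_score(self, Z: np.ndarray) -> np.ndarray:
        """Rest-distance score: the Mahalanobis distance from the rest
        Gaussian, standardized against the rest training samples' own
        distance distribution. Scores near 0 are typical rest activity;
        a score of 2 marks the rest cluster's 2-sigma boundary."""
        d = self.mahalanobis(Z)[:, self.rest_index]
        return (d - self.rest_chi_mean) / self.rest_chi_sd


def compute_scatter(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, dict]:
    """Between- and within-class scatter matrices.

    Returns ``(S_B, S_W, info)`` where ``info`` carries the class list,
    per-class counts, means and the global mean. Every class must have
    at least 2 samples.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=str)
    m = X.mean(axis=0)
    p = X.shape[1]
    S_B = np.zeros((p, p))
    S_W = np.zeros((p, p))
    means, counts = [], []
    for c in classes:
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mi = Xi.mean(axis=0)
        d = mi - m
        S_B += Xi.shape[0] * np.outer(d, d)
        R = Xi - mi
        S_W += R.T @ R
        means.append(mi)
        counts.append(Xi.shape[0])
    info = {
        "classes": classes,
        "n_i": np.asarray(counts),
        "class_means": np.vstack(means),
        "global_mean": m,
    }
    return S_B, S_W, info


def _class_covariances(X, labels, classes):
    covs = []
    for c in classes:
        Xi = X[np.asarray(labels) == c]
        R = Xi - Xi.mean(axis=0)
        covs.append(R.T @ R / Xi.shape[0])
    return covs


def shrink_covariance(cov: np.ndarray, lam: float, scale_aware: bool = True) -> np.ndarray:
    """``(1 - lambda) * cov + lambda * c * I`` with ``c`` the mean diagonal
    (scale-aware target) or 1 for the plain identity."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    c = float(np.mean(np.diag(cov))) if scale_aware else 1.0
    if c <= 0:
        c = 1.0
    return (1.0 - lam) * cov + lam * c * np.eye(cov.shape[0])


def regularize_within(covs, lam: float, n_i, scale_aware: bool = True) -> np.ndarray:
    """Reassemble the regularized within-class scatter ``sum_i n_i Omega_i'``.

    At ``lam = 0`` this reproduces S_W exactly; at ``lam = 1`` each class
    contributes only its (scaled) identity.
    """
    n_i = np.asarray(n_i)
    p = covs[0].shape[0]
    S = np.zeros((p, p))
    for ni, cov in zip(n_i, covs):
        S += ni * shrink_covariance(cov, lam, scale_aware=scale_aware)
    return S


def fit_mda(
    X: np.ndarray,
    labels,
    lam: float = 0.8,
    rest_label: str = "rest",
    scale_aware: bool = True,
    n_components: int | None = None,
) -> MDAModel:
    """Fit the regularized discriminant subspace and class Gaussians.

    Solves ``S_B v = e S_W' v`` as a symmetric-definite generalized
    eigenproblem and keeps the top eigenvectors up to ``min(N - 1,
    rank(S_B))``. Subspace class covariances receive the same shrinkage
    so Mahalanobis classification stays defined for small classes.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    S_B, S_W, info = compute_scatter(X, labels)
    classes = info["classes"]
    if rest_label not in classes:
        raise ValueError(f"rest class {rest_label!r} absent from labels")
    covs = _class_covariances(X, labels, classes)
    S_Wp = regularize_within(covs, lam, info["n_i"], scale_aware=scale_aware)
    S_B = 0.5 * (S_B + S_B.T)
    S_Wp = 0.5 * (S_Wp + S_Wp.T)
    try:
        evals, evecs = linalg.eigh(S_B, S_Wp)
    except linalg.LinAlgError as err:
        raise ValueError(
            "regularized within-class scatter is singular; increase lambda"
        ) from err
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    max_k = len(classes) - 1
    tol = max(evals[0], 0.0) * 1e-10 + 1e-12
    rank = int(np.sum(evals > tol))
    k = min(max_k, max(rank, 1))
    if n_components is not None:
        k = min(k, n_components)
    W = evecs[:, :k]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    evals = evals[:k]

    Z = X @ W
    labels_arr = np.asarray(labels)
    means, covs_z, inv_z = [], [], []
    for c in classes:
        Zi = Z[labels_arr == c]
        mu = Zi.mean(axis=0)
        R = Zi - mu
        C = shrink_covariance(R.T @ R / Zi.shape[0], max(lam, 1e-3))
        means.append(mu)
        covs_z.append(C)
        inv_z.append(np.linalg.inv(C))
    means = np.vstack(means)
    covs_z = np.stack(covs_z)
    inv_z = np.stack(inv_z)

    ri = classes.index(rest_label)
    rest_feature_mean = X[labels_arr == rest_label].mean(axis=0)
    rest_sd = float(np.sqrt(np.trace(covs_z[ri]) / W.shape[1]))
    Zr = Z[labels_arr == rest_label]
    d = Zr - means[ri]
    chi = np.sqrt(np.einsum("ij,jk,ik->i", d, inv_z[ri], d))
    chi_sd = float(chi.std(ddof=1)) if chi.size > 1 else 1.0

    return MDAModel(
        W=W,
        eigenvalues=evals,
        classes=classes,
        class_means=means,
        class_covs=covs_z,
        class_cov_invs=inv_z,
        lam=lam,
        rest_label=rest_label,
        rest_sd=rest_sd,
        rest_chi_mean=float(chi.mean()),
        rest_chi_sd=max(chi_sd, 1e-9),
        n_features=X.shape[1],
        feature_means=rest_feature_mean,
    )


def classify(model: MDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each pattern to the Mahalanobis-nearest class.

    Returns ``(labels, distances)`` where ``distances`` is in units of the
    rest cluster's standard deviation (distance of the projected point
    from the rest centroid). Ties go to the lowest class index.
    """
    Z = model.project(X)
    D = model.mahalanobis(Z)
    idx = np.argmin(D, axis=1)
    labels = np.asarray([model.classes[i] for i in idx], dtype=object)
    rest_dist = (
        np.linalg.norm(Z - model.class_means[model.rest_index], axis=1) / model.rest_sd
    )
    return labels, rest_dist


def rest_normalized_class_distances(model: MDAModel) -> dict:
    """Distance of each class centroid from the rest centroid, in rest-SD
    units — the per-condition separation summary."""
    ri = model.rest_index
    out = {}
    for i, c in enumerate(model.classes):
        if i == ri:
            continue
        d = np.linalg.norm(model.class_means[i] - model.class_means[ri])
        out[c] = float(d / model.rest_sd)
    return out


def cross_validate(
    X: np.ndarray,
    labels,
    lam: float = 0.8,
    n_rep: int = 1000,
    seed: int = 0,
    scale_aware: bool = True,
    rest_label: str = "rest",
) -> np.ndarray:
    """Held-out accuracy over random train/test partitions.

    Each repetition holds out one randomly chosen sample per class (the
    test set has one pattern per condition plus one rest pattern), refits
    on the remainder and scores the held-out points. Returns the
    per-repetition accuracies.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=str)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in idx_by_class.items():
        if idx.size < 2:
            raise ValueError(f"class {c!r} needs >= 2 samples for cross-validation")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_rep)
    for r in range(n_rep):
        test = np.asarray([rng.choice(idx_by_class[c]) for c in classes])
        mask = np.ones(len(labels), dtype=bool)
        mask[test] = False
        model = fit_mda(
            X[mask], labels[mask], lam=lam, rest_label=rest_label, scale_aware=scale_aware
        )
        pred, _ = classify(model, X[test])
        acc[r] = float(np.mean(pred == labels[test]))
    return acc


def select_lambda(
    X: np.ndarray,
    labels,
    grid=(0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8),
    n_rep: int = 50,
    seed: int = 0,
    rest_label: str = "rest",
) -> float:
    """Grid-search the shrinkage parameter by cross-validated accuracy.

    Ties (and unfittable grid points, scored 0) resolve to the smallest
    lambda.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    best_lam, best_acc = None, -1.0
    for lam in sorted(grid):
        try:
            acc = float(
                np.mean(cross_validate(X, labels, lam=lam, n_rep=n_rep, seed=seed,
                                       rest_label=rest_label))
            )
        except (ValueError, linalg.LinAlgError):
            acc = 0.0
        if acc > best_acc + 1e-12:
            best_lam, best_acc = lam, acc
    return float(best_lam)
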