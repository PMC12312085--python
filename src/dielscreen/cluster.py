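"""Longitudinal k-means with temporal-correlation-weighted dissimilarity.

The dissimilarity between two trajectories is the Chouakria-Douzal
adaptive distance

    D(a, b) = phi_k(CORT(a, b)) * delta(a, b)

where ``delta`` is the Euclidean distance between the trajectories,
``CORT`` is the first-order temporal correlation of their difference
vectors,

    CORT(a, b) = sum_t da_t * db_t / (||da|| * ||db||),   da = diff(a),

and ``phi_k(u) = 2 / (1 + exp(k * u))`` is a tuning function that
down-weights distances between trajectories whose increments agree
(k >= 0; k = 0 recovers plain Euclidean k-means).  CORT is defined as 0
when either difference vector is all-zero, so flat trajectories fall
back to the Euclidean distance.

The k-means variant follows the longitudinal-clustering procedure of the
kml family: trajectories are assigned to the centroid minimising the
adaptive distance, but centroids are updated as the pointwise mean of
their members (a true barycentre under the adaptive distance has no
closed form).  The number of clusters is selected by maximising the
Calinski-Harabasz criterion, with the Ray-Turi criterion reported
alongside; both are computed with Euclidean geometry on the scaled
trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CORT_K = 2.0
DEFAULT_N_RESTARTS = 20
DEFAULT_MAX_ITER = 100
DEFAULT_K_RANGE = range(2, 9)
DEFAULT_MEMBERSHIP_THRESHOLD = 0.90


# -- dissimilarity ------------------------------------------------------


def cort(a: np.ndarray, b: np.ndarray) -> float:
    """First-order temporal correlation of two equal-length series."""
    da, db = np.diff(a), np.diff(b)
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        return 0.0
    return float(da @ db / (na * nb))


def cort_dissimilarity(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    cort_k: float = DEFAULT_CORT_K,
) -> float:
    """Adaptive dissimilarity phi_k(CORT(a, b)) * ||a - b||."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValidationError(
            f"trajectories must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise ValidationError("trajectories need at least 2 time points")
    return float(cort_dissimilarity_matrix(a[None, :], b[None, :], cort_k)[0, 0])


def cort_dissimilarity_matrix(
    X: np.ndarray, C: np.ndarray, cort_k: float = DEFAULT_CORT_K
) -> np.ndarray:
    """Pairwise adaptive dissimilarities between rows of X and rows of C."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ValidationError("trajectory lengths differ")
    dX = np.diff(X, axis=1)
    dC = np.diff(C, axis=1)
    nX = np.linalg.norm(dX, axis=1)
    nC = np.linalg.norm(dC, axis=1)
    denom = np.outer(nX, nC)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (dX @ dC.T) / np.where(denom > 0, denom, 1.0), 0.0)
    phi = 2.0 / (1.0 + np.exp(cort_k * corr))
    return phi * cdist(X, C)


# -- model container ----------------------------------------------------


@dataclass
class ClusterModel:
    """Fitted longitudinal k-means model.

    ``centroids`` is the k x m matrix of cluster mean trajectories in
    scaled space; ``assignments`` maps feature_id to cluster label
    (0..k-1); ``membership_prob`` holds the per-feature posterior
    probability of each cluster; ``criteria`` the Calinski-Harabasz and
    Ray-Turi validity values.
    """

    k: int
    centroids: np.ndarray
    assignments: pd.Series
    membership_prob: pd.DataFrame
    criteria: dict[str, float]
    cort_k: float = DEFAULT_CORT_K
    n_restarts: int = DEFAULT_N_RESTARTS
    max_iter: int = DEFAULT_MAX_ITER
    seed: int = 0
    inertia: float = np.nan
    converged: bool = True
    selection_table: pd.DataFrame | None = None

    @property
    def m(self) -> int:
        return self.centroids.shape[1]

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(range(self.k), fill_value=0)


# -- fitting ------------------------------------------------------------


def _relocate(
    X: np.ndarray,
    init_idx: np.ndarray,
    cort_k: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """One k-means run from a given initialisation.

    Returns (labels, centroids, inertia, converged).  Ties in the
    assignment step break to the lowest cluster index; an emptied cluster
    is re-seeded with the trajectory farthest from its current centroid.
    """
    k = len(init_idx)
    C = X[init_idx].copy()
    labels = np.full(len(X), -1)
    converged = False
    for _ in range(max_iter):
        D = cort_dissimilarity_matrix(X, C, cort_k)
        new_labels = D.argmin(axis=1)
        # repair empty clusters with the farthest-from-centroid trajectory;
        # each repair consumes a distinct trajectory
        own = D[np.arange(len(X)), new_labels].copy()
        for j in range(k):
            if not (new_labels == j).any():
                far = int(np.argmax(own))
                logger.debug("empty cluster %d re-seeded with trajectory %d", j, far)
                new_labels[far] = j
                own[far] = -np.inf
        if (new_labels == labels).all():
            converged = True
            break
        labels = new_labels
        C = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    D = cort_dissimilarity_matrix(X, C, cort_k)
    inertia = float(D[np.arange(len(X)), labels].sum())
    return labels, C, inertia, converged


def fit_kmeans(
    trajectories: pd.DataFrame,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    cort_k: float = DEFAULT_CORT_K,
) -> ClusterModel:
    """Fit k clusters to scaled trajectories (rows of the DataFrame).

    Runs ``n_restarts`` random initialisations (k distinct trajectories
    each) and keeps the run with the lowest total within-cluster
    dissimilarity.  Deterministic for fixed (data, k, seed).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = len(trajectories)
    if n <= k:
        raise ValidationError(f"need more trajectories ({n}) than clusters ({k})")
    X = trajectories.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    for _ in range(n_restarts):
        init_idx = rng.choice(n, size=k, replace=False)
        labels, C, inertia, conv = _relocate(X, init_idx, cort_k, max_iter)
        if best is None or inertia < best[0]:
            best = (inertia, labels, C, conv)
    assert best is not None
    inertia, labels, C, conv = best
    if not conv:
        warnings.warn(
            f"k-means did not converge within {max_iter} iterations", RuntimeWarning
        )
    # enforce the centroid-mean invariant on the returned model
    C = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])

    assignments = pd.Series(labels, index=trajectories.index, name="cluster")
    model = ClusterModel(
        k=k,
        centroids=C,
        assignments=assignments,
        membership_prob=pd.DataFrame(index=trajectories.index),
        criteria={},
        cort_k=cort_k,
        n_restarts=n_restarts,
        max_iter=max_iter,
        seed=seed,
        inertia=inertia,
        converged=conv,
    )
    model.criteria = validity_criteria(model, trajectories)
    model.membership_prob = membership_probabilities(model, trajectories)
    return model


# -- validity criteria --------------------------------------------------


def validity_criteria(
    model: ClusterModel, trajectories: pd.DataFrame
) -> dict[str, float]:
    """Calinski-Harabasz and Ray-Turi criteria (Euclidean geometry).

    CH = [B / (k-1)] / [W / (n-k)] with B/W the between/within-cluster
    sums of squares; Ray-Turi = (W/n) / min over cluster pairs of the
    squared inter-centroid distance.  A degenerate fit with W = 0 yields
    CH = +inf, flagged via the ``degenerate`` key.
    """
    if model.k < 2:
        raise ValidationError("validity criteria require k >= 2")
    X = trajectories.to_numpy(dtype=float)
    labels = model.assignments.loc[trajectories.index].to_numpy()
    n, k = len(X), model.k
    grand = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for j in range(k):
        members = X[labels == j]
        if len(members) == 0:
            continue
        W += float(((members - model.centroids[j]) ** 2).sum())
        B += len(members) * float(((model.centroids[j] - grand) ** 2).sum())
    # W is compared against B at a relative tolerance: a numerically-zero
    # within-cluster scatter (noiseless members coinciding with their
    # centroids) must register as degenerate rather than yield an
    # arbitrarily large finite CH that grows with k
    degenerate = W <= 1e-12 * max(B, 1.0)
    with np.errstate(divide="ignore"):
        ch = np.inf if degenerate else (B / (k - 1)) / (W / (n - k))
    pair_d2 = cdist(model.centroids, model.centroids) ** 2
    np.fill_diagonal(pair_d2, np.inf)
    min_sep = float(pair_d2.min())
    rt = (W / n) / min_sep if min_sep > 0 else np.inf
    return {
        "calinski_harabasz": float(ch),
        "ray_turi": float(rt),
        "degenerate": bool(degenerate),
    }


# -- membership probabilities -------------------------------------------


def membership_probabilities(
    model: ClusterModel, trajectories: pd.DataFrame
) -> pd.DataFrame:
    """Gaussian-kernel posterior over clusters for each trajectory.

    p(i, j) is proportional to exp(-d(i, j)^2 / (2 s^2)) with d the
    adaptive dissimilarity to centroid j and s the pooled mean
    within-cluster dissimilarity.  Probabilities sum to 1 per trajectory;
    when s = 0 (every member coincides with its centroid) the nearest
    cluster receives probability 1.  The formula is monotone in distance
    and reduces to hard assignment as noise vanishes.
    """
    X = trajectories.to_numpy(dtype=float)
    D = cort_dissimilarity_matrix(X, model.centroids, model.cort_k)
    labels = model.assignments.loc[trajectories.index].to_numpy()
    s = float(D[np.arange(len(X)), labels].mean())
    if s == 0.0:
        P = np.zeros_like(D)
        P[np.arange(len(X)), D.argmin(axis=1)] = 1.0
    else:
        logits = -(D**2) / (2.0 * s**2)
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
    return pd.DataFrame(P, index=trajectories.index, columns=range(model.k))


def filter_by_membership(
    model: ClusterModel, threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD
) -> pd.Index:
    """Feature ids whose maximum cluster probability strictly exceeds the threshold."""
    keep = model.membership_prob.max(axis=1) > threshold
    return model.membership_prob.index[keep]


# -- model selection ----------------------------------------------------


def select_k(
    trajectories: pd.DataFrame,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    cort_k: float = DEFAULT_CORT_K,
) -> ClusterModel:
    """Fit every k in ``k_range`` and return the model maximising CH.

    The Ray-Turi criterion is reported alongside in the model's
    ``selection_table`` for diagnostics; ties on CH break to the smaller
    k.
    """
    ks = [k for k in k_range if 2 <= k < len(trajectories)]
    if not ks:
        raise ValidationError("k_range contains no feasible cluster counts")
    models: list[ClusterModel] = []
    rows = []
    for k in ks:
        m = fit_kmeans(
            trajectories,
            k,
            n_restarts=n_restarts,
            max_iter=max_iter,
            seed=seed,
            cort_k=cort_k,
        )
        models.append(m)
        rows.append(
            {
                "k": k,
                "calinski_harabasz": m.criteria["calinski_harabasz"],
                "ray_turi": m.criteria["ray_turi"],
                "inertia": m.inertia,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    best_idx = int(np.argmax(table["calinski_harabasz"].to_numpy()))
    best = models[best_idx]
    best.selection_table = table
    return best
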