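"""Centroid-based classification of non-target feature trajectories.

Each scaled non-target trajectory is compared against the exported
cluster centroids with the squared Euclidean distance

    D(i, j) = sum_t (x_{i,t} - c_{j,t})^2

(no square root — the squared form is the classification metric).  A
feature is retained only when the assignment is unambiguous and close:

* ratio rule — the second-nearest centroid must be > 1.5x farther than
  the nearest (``ratio = d_second / d_nearest``);
* median rule — the nearest distance must not exceed the median of the
  clustered target compounds' distances to their own centroids.

Re-assigning the clustered targets themselves through the same
machinery serves as a quality control: the clustering metric
(temporal-correlation-weighted) and the prediction metric (squared
Euclidean) are different geometries, so the agreement fraction
quantifies how often they disagree rather than assuming they never do.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cluster import ClusterModel
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RATIO_THRESHOLD = 1.5

#: reasons recorded for non-retained features
REASON_OK = "ok"
REASON_AMBIGUOUS = "ambiguous_ratio"
REASON_FAR = "above_median_threshold"


def centroid_distances(
    traj: Sequence[float] | np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Squared Euclidean distance from one trajectory to each centroid."""
    traj = np.asarray(traj, dtype=float)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if traj.ndim != 1 or traj.shape[0] != centroids.shape[1]:
        raise ValidationError(
            f"trajectory length {traj.shape} does not match centroid length "
            f"{centroids.shape[1]}"
        )
    return ((traj[None, :] - centroids) ** 2).sum(axis=1)


def distance_matrix(Z: pd.DataFrame, centroids: np.ndarray) -> pd.DataFrame:
    """Squared Euclidean distances, features x clusters."""
    if Z.shape[1] != centroids.shape[1]:
        raise ValidationError("trajectory length does not match centroid length")
    D = cdist(Z.to_numpy(dtype=float), centroids, metric="sqeuclidean")
    return pd.DataFrame(D, index=Z.index, columns=range(centroids.shape[0]))


def target_own_distances(model: ClusterModel, Z_targets: pd.DataFrame) -> pd.Series:
    """Each clustered target's squared Euclidean distance to its own centroid."""
    D = distance_matrix(Z_targets, model.centroids)
    labels = model.assignments.loc[Z_targets.index]
    return pd.Series(
        D.to_numpy()[np.arange(len(D)), labels.to_numpy()],
        index=Z_targets.index,
        name="own_distance",
    )


def assign_and_filter(
    distances: pd.DataFrame,
    target_distances: Sequence[float] | pd.Series,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    median_mode: str = "global",
    target_clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify features from their per-cluster distance matrix.

    ``target_distances`` are the clustered target compounds' own-centroid
    distances; their median is the closeness threshold.  With
    ``median_mode="per_cluster"`` a separate median per cluster is used
    (requires ``target_clusters``, the targets' fitted labels).

    Returns a DataFrame with columns ``nearest, second_nearest,
    d_nearest, d_second, ratio, threshold, retained, reason``.  The ratio
    is second-nearest over nearest, so it is >= 1 and "> 1.5" means the
    runner-up is at least 50 % farther; an exact-match feature
    (d_nearest = 0) has infinite ratio.
    """
    if distances.shape[1] < 2:
        raise ValidationError("ratio rule needs at least 2 clusters")
    td = pd.Series(target_distances)
    if td.empty:
        raise ValidationError("target_distances must be non-empty")
    if median_mode not in ("global", "per_cluster"):
        raise ValidationError("median_mode must be 'global' or 'per_cluster'")
    if median_mode == "per_cluster" and target_clusters is None:
        raise ValidationError("per_cluster median mode requires target_clusters")

    D = distances.to_numpy(dtype=float)
    order = np.argsort(D, axis=1, kind="stable")  # stable -> lowest index on ties
    nearest = order[:, 0]
    second = order[:, 1]
    d1 = D[np.arange(len(D)), nearest]
    d2 = D[np.arange(len(D)), second]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d1 > 0, d2 / np.where(d1 > 0, d1, 1.0), np.inf)

    if median_mode == "global":
        thr = np.full(len(D), float(td.median()))
    else:
        per = td.groupby(target_clusters.loc[td.index]).median()
        thr = per.reindex(range(distances.shape[1])).fillna(td.median()).to_numpy()[
            nearest
        ]

    ambiguous = ratio <= ratio_threshold
    far = d1 > thr
    retained = ~ambiguous & ~far
    reason = np.where(retained, REASON_OK, np.where(ambiguous, REASON_AMBIGUOUS, REASON_FAR))

    out = pd.DataFrame(
        {
            "nearest": distances.columns.to_numpy()[nearest],
            "second_nearest": distances.columns.to_numpy()[second],
            "d_nearest": d1,
            "d_second": d2,
            "ratio": ratio,
            "threshold": thr,
            "retained": retained,
            "reason": reason,
        },
        index=distances.index,
    )
    for fid, row in out[~out["retained"]].iterrows():
        logger.debug("prediction drop %s: %s (ratio=%.3f, d=%.3f)",
                     fid, row["reason"], row["ratio"], row["d_nearest"])
    return out


def predict_clusters(
    Z: pd.DataFrame,
    model: ClusterModel,
    Z_targets: pd.DataFrame,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    median_mode: str = "global",
) -> pd.DataFrame:
    """End-to-end prediction: distances, assignment and both filters."""
    D = distance_matrix(Z, model.centroids)
    td = target_own_distances(model, Z_targets)
    return assign_and_filter(
        D,
        td,
        ratio_threshold=ratio_threshold,
        median_mode=median_mode,
        target_clusters=model.assignments,
    )


def reassign_targets_qc(model: ClusterModel, Z_targets: pd.DataFrame) -> float:
    """Fraction of clustered targets re-assigned to their fitted cluster.

    Runs the squared-Euclidean argmin on every clustered target and
    compares with the fitted (temporal-correlation-based) label; ties in
    the argmin break to the lowest cluster index.  Disagreements are
    logged individually.
    """
    D = distance_matrix(Z_targets, model.centroids)
    predicted = D.to_numpy().argmin(axis=1)
    fitted = model.assignments.loc[Z_targets.index].to_numpy()
    agree = predicted == fitted
    for fid, p, f in zip(Z_targets.index, predicted, fitted):
        if p != f:
            logger.info("target %s re-assigned to cluster %d (fitted %d)", fid, p, f)
    return float(agree.mean()) if len(agree) else float("nan")
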