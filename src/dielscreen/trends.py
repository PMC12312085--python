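"""Per-cluster trend summaries: smoothing, flow correlation, composition.

Smoothing is visualization-grade only: a penalized cubic smoothing
spline (smoothing parameter chosen by generalized cross-validation) is
fitted through the pointwise means of a cluster's member trajectories,
separately per sampling day so that day-to-day differences (e.g., the
rain-event night) stay visible.  The confidence band is a pointwise
normal band from the cross-member spread.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import spearmanr

from .cluster import ClusterModel
from .errors import ValidationError

MIN_POINTS_FOR_SPLINE = 8


def fit_cluster_smoother(
    members: pd.DataFrame, day_length: int = 24
) -> pd.DataFrame:
    """Smooth a cluster's member trajectories (members x m).

    Returns a DataFrame with columns ``time, mean, smooth, lower, upper``
    where ``smooth`` is the per-day GCV smoothing spline through the
    pointwise means and ``lower``/``upper`` a pointwise 95 % band from the
    member spread.  Falls back to the pointwise mean (with a warning)
    when fewer than 8 distinct time points are available per segment.
    """
    if members.empty:
        raise ValidationError("cluster has no members to smooth")
    Y = members.to_numpy(dtype=float)
    m = Y.shape[1]
    t = np.arange(m, dtype=float)
    mean = Y.mean(axis=0)
    n = Y.shape[0]
    if n > 1:
        half = 1.96 * Y.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        half = np.zeros(m)

    smooth = np.empty(m)
    starts = list(range(0, m, day_length)) if m > day_length else [0]
    for s in starts:
        seg = slice(s, min(s + day_length, m))
        ts, ys = t[seg], mean[seg]
        if len(ts) < MIN_POINTS_FOR_SPLINE:
            warnings.warn(
                f"segment at t={s} has <{MIN_POINTS_FOR_SPLINE} time points; "
                "using the pointwise mean",
                RuntimeWarning,
            )
            smooth[seg] = ys
            continue
        spline = make_smoothing_spline(ts, ys)  # lam=None -> GCV
        smooth[seg] = spline(ts)

    return pd.DataFrame(
        {
            "time": t.astype(int),
            "mean": mean,
            "smooth": smooth,
            "lower": smooth - half,
            "upper": smooth + half,
        }
    )


def spearman_flow_correlation(
    center: np.ndarray | pd.Series, flow: np.ndarray | pd.Series
) -> float:
    """Spearman rank correlation of a cluster center with the flow rate.

    Average ranks on ties.  Returns NaN (with a warning) for constant
    input, where the correlation is undefined.
    """
    center = np.asarray(center, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if center.shape != flow.shape:
        raise ValidationError("center and flow must have equal length")
    if np.ptp(center) == 0 or np.ptp(flow) == 0:
        warnings.warn("constant input: Spearman correlation undefined", RuntimeWarning)
        return float("nan")
    rho, _ = spearmanr(center, flow)
    return float(rho)


def composition_summary(
    model: ClusterModel, feature_meta: pd.DataFrame
) -> pd.DataFrame:
    """Compound-class counts per cluster for the clustered (annotated) targets.

    Features without a compound class are counted as ``unclassified``.
    Adds cluster sizes and the percentage of clustered targets per
    cluster; class counts per cluster sum to the cluster size.
    """
    classes = (
        feature_meta.loc[model.assignments.index, "compound_class"]
        .fillna("unclassified")
        .astype(str)
    )
    df = pd.DataFrame({"cluster": model.assignments, "compound_class": classes})
    counts = (
        df.groupby(["cluster", "compound_class"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(range(model.k), fill_value=0)
    counts["size"] = counts.sum(axis=1)
    total = counts["size"].sum()
    counts["pct_of_targets"] = 100.0 * counts["size"] / total if total else 0.0
    return counts


def cluster_trends(
    model: ClusterModel,
    Z: pd.DataFrame,
    flow: pd.Series | np.ndarray | None = None,
    feature_meta: pd.DataFrame | None = None,
    day_length: int = 24,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Smooth every cluster and tabulate flow correlation and composition.

    Returns ``(smooths, summary)`` where ``smooths[j]`` is the smoother
    output for cluster j and ``summary`` has one row per cluster with its
    size, Spearman rho vs flow (NaN when no flow given) and, when feature
    metadata is supplied, the compound-class counts.
    """
    smooths: dict[int, pd.DataFrame] = {}
    rows = []
    for j in range(model.k):
        ids = model.assignments.index[model.assignments == j]
        rho = float("nan")
        if len(ids):
            smooths[j] = fit_cluster_smoother(Z.loc[ids], day_length=day_length)
            if flow is not None:
                rho = spearman_flow_correlation(model.centroids[j], np.asarray(flow))
        rows.append({"cluster": j, "size": len(ids), "rho_vs_flow": rho})
    summary = pd.DataFrame(rows).set_index("cluster")
    if feature_meta is not None:
        summary = summary.join(
            composition_summary(model, feature_meta).drop(columns=["size"])
        )
    return smooths, summary
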