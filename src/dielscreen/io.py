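"""Reading and writing feature tables and clustering outputs.

The on-disk dialect is plain CSV (comma-delimited, header row, UTF-8) in
the style of an MZmine aligned-peak-list export: one row per feature with
``feature_id, mz, rt, ion_mode, annotation, compound_class, is_target,
is_internal_standard`` followed by one intensity column per sample.
Sample metadata travels in a companion CSV with columns
``sample_id, day, hour, sample_type, flow_rate``.

Intensities are written with 6 significant digits, which exceeds
instrument signal precision and keeps read/write round-trips stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datamodel import FEATURE_META_COLUMNS, FeatureTable
from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterModel

#: significant digits used for intensity / centroid export
EXPORT_PRECISION = 6
_FLOAT_FMT = f"%.{EXPORT_PRECISION}g"


def read_feature_table(path: str | Path, meta_path: str | Path) -> FeatureTable:
    """Read a feature table CSV plus its sample-metadata CSV.

    Missing intensity cells become non-detects (0).  Raises
    :class:`ValidationError` on duplicate feature ids, on sample-id
    mismatch between the two files, and on negative intensities.
    """
    raw = pd.read_csv(path, dtype={"feature_id": str})
    if "feature_id" not in raw.columns:
        raise ValidationError(f"{path}: missing feature_id column")
    if raw["feature_id"].duplicated().any():
        dups = sorted(set(raw.loc[raw["feature_id"].duplicated(), "feature_id"]))
        raise ValidationError(f"{path}: duplicate feature_id(s): {dups}")
    raw = raw.set_index("feature_id")

    meta = pd.read_csv(meta_path, dtype={"sample_id": str}).set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValidationError(f"{meta_path}: duplicate sample_id(s)")

    intensity_cols = [c for c in raw.columns if c not in FEATURE_META_COLUMNS]
    missing = set(meta.index) - set(intensity_cols)
    extra = set(intensity_cols) - set(meta.index)
    if missing or extra:
        raise ValidationError(
            f"sample_id mismatch between table and metadata: "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )

    # reorder columns to the metadata order; empty cells -> non-detect
    intensities = raw[list(meta.index)].apply(pd.to_numeric).fillna(0.0)

    feature_meta = raw.reindex(columns=FEATURE_META_COLUMNS)
    for flag in ("is_target", "is_internal_standard"):
        feature_meta[flag] = (
            feature_meta[flag].fillna(False).astype(bool)
            if flag in feature_meta
            else False
        )
    return FeatureTable(intensities, feature_meta, meta)


def write_feature_table(
    table: FeatureTable, path: str | Path, meta_path: str | Path
) -> None:
    """Write a feature table and its sample metadata as CSV."""
    out = table.feature_meta.join(table.intensities)
    out.index.name = "feature_id"
    out.to_csv(path, float_format=_FLOAT_FMT)
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def merge_ion_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Merge ESI+ / ESI- tables, deduplicating annotated compounds.

    A compound annotated in both modes keeps only the row whose mean
    intensity across type=sample columns is higher; at exactly equal
    means the positive-mode row wins.  Unannotated features from both
    modes are concatenated unchanged (non-target deduplication across
    modes is out of scope).
    """
    if not pos.sample_meta.equals(neg.sample_meta):
        raise ValidationError("sample metadata differs between ion modes")

    def annotated_means(t: FeatureTable) -> pd.Series:
        ann = t.feature_meta["annotation"]
        ids = ann.dropna().index
        return pd.Series(
            t.sample_intensities().loc[ids].mean(axis=1).to_numpy(),
            index=ann.dropna().to_numpy(),
        )

    pos_means = annotated_means(pos)
    neg_means = annotated_means(neg)
    shared = pos_means.index.intersection(neg_means.index)
    # keep positive mode unless the negative-mode mean is strictly higher
    drop_from_pos = shared[neg_means[shared] > pos_means[shared]]
    drop_from_neg = shared.difference(drop_from_pos)

    def keep_ids(t: FeatureTable, drop_annotations: pd.Index) -> list[str]:
        ann = t.feature_meta["annotation"]
        return [fid for fid in t.feature_ids if ann[fid] not in set(drop_annotations)]

    pos_keep = pos.select_features(keep_ids(pos, drop_from_pos))
    neg_keep = neg.select_features(keep_ids(neg, drop_from_neg))

    merged_int = pd.concat([pos_keep.intensities, neg_keep.intensities])
    merged_meta = pd.concat([pos_keep.feature_meta, neg_keep.feature_meta])
    if merged_meta.index.duplicated().any():
        raise ValidationError("feature_id collision between ion-mode tables")
    return FeatureTable(merged_int, merged_meta, pos.sample_meta.copy())


# -- clustering outputs -------------------------------------------------


def write_cluster_outputs(
    model: "ClusterModel",
    predictions: pd.DataFrame | None,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Export per-feature assignments and the k x m centroid matrix.

    Writes ``assignments.csv`` (cluster label, membership probability and,
    when predictions are supplied, centroid distances / ratio / retained
    flag for non-target features) and ``centroids.csv``.  Returns the two
    paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assign = pd.DataFrame(
        {
            "cluster": model.assignments,
            "membership_prob": model.membership_prob.max(axis=1),
            "source": "target",
        }
    )
    if predictions is not None and len(predictions):
        pred = predictions.copy()
        pred = pred.rename(columns={"nearest": "cluster"})
        pred["membership_prob"] = np.nan
        pred["source"] = "predicted"
        assign = pd.concat([assign, pred[assign.columns.intersection(pred.columns)]])
        extra = predictions[
            [c for c in ("d_nearest", "d_second", "ratio", "retained", "reason") if c in predictions]
        ]
        assign = assign.join(extra)
    assign.index.name = "feature_id"
    assign_path = out_dir / "assignments.csv"
    assign.to_csv(assign_path, float_format=_FLOAT_FMT)

    cent = pd.DataFrame(
        model.centroids,
        index=pd.Index(range(model.k), name="cluster"),
        columns=[f"t{t}" for t in range(model.centroids.shape[1])],
    )
    cent_path = out_dir / "centroids.csv"
    cent.to_csv(cent_path, float_format=_FLOAT_FMT)
    return assign_path, cent_path


def read_centroids(path: str | Path) -> np.ndarray:
    """Read a centroid matrix written by :func:`write_cluster_outputs`."""
    return pd.read_csv(path, index_col="cluster").to_numpy()
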