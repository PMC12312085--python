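"""Core in-memory containers for aligned LC-HRMS feature tables.

A :class:`FeatureTable` bundles the intensity matrix (features x samples)
with per-feature metadata (m/z, retention time, ionization mode,
annotation) and per-sample metadata (sampling day/hour, sample type,
influent flow rate).  Intensities are non-negative; a value of 0 encodes a
non-detect.  Column order of the intensity matrix always equals the row
order of the sample metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ValidationError

FEATURE_META_COLUMNS = [
    "mz",
    "rt",
    "ion_mode",
    "annotation",
    "compound_class",
    "is_target",
    "is_internal_standard",
]
SAMPLE_META_COLUMNS = ["day", "hour", "sample_type", "flow_rate"]

SAMPLE_TYPES = ("sample", "blank", "qc")

ConfigurationMode = Literal["per_day", "hourly_average", "continuous_72h", "randomized"]


@dataclass
class FeatureTable:
    """Intensity matrix plus feature and sample metadata.

    Parameters
    ----------
    intensities
        DataFrame of non-negative signal intensities, indexed by
        ``feature_id``, one column per ``sample_id``.  ``0`` encodes a
        non-detect.
    feature_meta
        DataFrame indexed by ``feature_id`` with columns
        ``mz`` (Da), ``rt`` (minutes), ``ion_mode`` ({"pos", "neg"}),
        ``annotation``, ``compound_class``, ``is_target``,
        ``is_internal_standard``.
    sample_meta
        DataFrame indexed by ``sample_id`` with columns ``day`` (1..3, 0
        for non-hourly samples such as blanks), ``hour`` (0..23),
        ``sample_type`` ({"sample", "blank", "qc"}) and ``flow_rate``
        (volume/hour; may be NaN for blanks).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if not self.feature_meta.index.is_unique:
            dups = self.feature_meta.index[self.feature_meta.index.duplicated()]
            raise ValidationError(f"duplicate feature_id(s): {sorted(set(dups))}")
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ValidationError("intensity rows do not match feature_meta index")
        if list(self.intensities.columns) != list(self.sample_meta.index):
            raise ValidationError(
                "intensity column order must equal sample_meta row order"
            )
        vals = self.intensities.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            bad = self.intensities.index[(self.intensities < 0).any(axis=1)]
            raise ValidationError(f"negative intensities for feature(s): {list(bad)}")
        bad_type = set(self.sample_meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValidationError(f"unknown sample_type(s): {sorted(bad_type)}")
        hourly = self.sample_meta[self.sample_meta["sample_type"] == "sample"]
        if hourly.duplicated(subset=["day", "hour"]).any():
            dup = hourly[hourly.duplicated(subset=["day", "hour"], keep=False)]
            raise ValidationError(
                f"more than one hourly sample per (day, hour): {list(dup.index)}"
            )

    # -- convenience accessors -----------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    def sample_ids(self, sample_type: str = "sample") -> list[str]:
        mask = self.sample_meta["sample_type"] == sample_type
        return list(self.sample_meta.index[mask])

    def sample_intensities(self, sample_type: str = "sample") -> pd.DataFrame:
        """Intensity sub-matrix restricted to one sample type."""
        return self.intensities[self.sample_ids(sample_type)]

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            intensities=self.intensities.loc[ids].copy(),
            feature_meta=self.feature_meta.loc[ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        """Return a copy with a replaced (same-shape) intensity matrix."""
        return FeatureTable(
            intensities=intensities,
            feature_meta=self.feature_meta.loc[intensities.index].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    @property
    def n_features(self) -> int:
        return len(self.intensities)

    @property
    def n_samples(self) -> int:
        return len(self.sample_meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_s = len(self.sample_ids("sample"))
        n_b = len(self.sample_ids("blank"))
        return (
            f"FeatureTable({self.n_features} features x {self.n_samples} samples "
            f"[{n_s} sample / {n_b} blank])"
        )


@dataclass
class SampleConfigurationSpec:
    """How the 72 hourly samples are arranged before clustering.

    ``continuous_72h`` keeps one trajectory of 72 points per feature
    (day-major, hour-minor); ``hourly_average`` averages the three days
    into 24 points; ``per_day`` yields three separate 24-point sets;
    ``randomized`` permutes each feature's 72-point order independently
    (permutation null / negative control) and requires a seed.
    """

    mode: ConfigurationMode = "continuous_72h"
    flow_normalize: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        valid = ("per_day", "hourly_average", "continuous_72h", "randomized")
        if self.mode not in valid:
            raise ValidationError(f"unknown configuration mode {self.mode!r}")
        if self.mode == "randomized" and self.seed is None:
            raise ValidationError("randomized mode requires a seed")


def empty_feature_meta(feature_ids: Iterable[str]) -> pd.DataFrame:
    """Feature metadata frame with default (unannotated) values."""
    idx = pd.Index(list(feature_ids), name="feature_id")
    return pd.DataFrame(
        {
            "mz": np.nan,
            "rt": np.nan,
            "ion_mode": "pos",
            "annotation": pd.Series([None] * len(idx), index=idx, dtype=object),
            "compound_class": pd.Series([None] * len(idx), index=idx, dtype=object),
            "is_target": False,
            "is_internal_standard": False,
        },
        index=idx,
    )
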