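"""Feature filtering, imputation, transformation and data configuration.

The fixed pipeline order is::

    blank_filter -> detection_frequency_filter -> variance_filter
        -> impute_nondetects -> (optional flow_normalize)
        -> assemble_configuration -> scale_trajectories

Each stage only removes or transforms features, never invents them.

Filtering rules
---------------
* blank rule: a feature is kept iff its mean intensity over hourly
  samples is at least 1.5x its mean intensity in procedure blanks;
* detection frequency: kept iff detected (intensity > 0) in >= 85 % of
  hourly samples;
* temporal variance: kept iff the relative standard deviation of its raw
  intensities (non-detects excluded, sample sd with n-1) exceeds 45 %,
  i.e. 1.5x the largest variation observed for internal standards;
* remaining non-detects are replaced by one quarter of the feature's
  minimal detected value.

Scaling standardizes each trajectory's log2 intensities to mean 0 and
unit (sample) standard deviation, which makes clustering insensitive to
per-feature response factors and absolute abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, SampleConfigurationSpec
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BLANK_FACTOR = 1.5
DEFAULT_DF_THRESHOLD = 0.85
DEFAULT_RSD_THRESHOLD = 0.45
DEFAULT_IMPUTATION_DIVISOR = 4.0


def blank_filter(
    table: FeatureTable, factor: float = DEFAULT_BLANK_FACTOR
) -> FeatureTable:
    """Remove features whose sample mean is below ``factor`` x blank mean.

    Features absent from blanks (blank mean 0) are always kept.  Requires
    at least one blank sample; to skip the step, do not call it.
    """
    blank_ids = table.sample_ids("blank")
    if not blank_ids:
        raise ValidationError(
            "no blank samples in table; omit blank_filter explicitly to skip it"
        )
    sample_mean = table.sample_intensities().mean(axis=1)
    blank_mean = table.intensities[blank_ids].mean(axis=1)
    keep = sample_mean >= factor * blank_mean
    for fid in table.feature_ids[~keep]:
        logger.debug(
            "blank_filter drop %s: sample_mean=%.4g < %.2g x blank_mean=%.4g",
            fid, sample_mean[fid], factor, blank_mean[fid],
        )
    return table.select_features(table.feature_ids[keep])


def detection_frequency_filter(
    table: FeatureTable, threshold: float = DEFAULT_DF_THRESHOLD
) -> FeatureTable:
    """Keep features detected in at least ``threshold`` of hourly samples.

    The boundary is inclusive: a feature detected in exactly 85 % of the
    samples is retained.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("detection-frequency threshold must be in (0, 1]")
    samples = table.sample_intensities()
    frac = (samples > 0).sum(axis=1) / samples.shape[1]
    keep = frac >= threshold
    for fid in table.feature_ids[~keep]:
        logger.debug("detection_frequency_filter drop %s: DF=%.3f", fid, frac[fid])
    return table.select_features(table.feature_ids[keep])


def variance_filter(
    table: FeatureTable, rsd_threshold: float = DEFAULT_RSD_THRESHOLD
) -> FeatureTable:
    """Keep features whose raw-intensity RSD strictly exceeds the threshold.

    RSD = sd / mean over hourly samples, computed on detected values only
    with the sample (n-1) standard deviation.  Features with fewer than
    two detects cannot have a variance and are removed (logged).
    """
    samples = table.sample_intensities()
    keep = []
    for fid, row in samples.iterrows():
        detected = row[row > 0]
        if len(detected) < 2:
            logger.debug("variance_filter drop %s: <2 detects", fid)
            continue
        rsd = detected.std(ddof=1) / detected.mean()
        if rsd > rsd_threshold:
            keep.append(fid)
        else:
            logger.debug("variance_filter drop %s: RSD=%.3f", fid, rsd)
    return table.select_features(keep)


def impute_nondetects(
    table: FeatureTable, divisor: float = DEFAULT_IMPUTATION_DIVISOR
) -> FeatureTable:
    """Replace each non-detect by min(detected values of that feature)/4.

    The minimum is per feature, so imputed values differ across features;
    detected values and blank/QC columns are left unchanged.
    """
    sample_ids = table.sample_ids("sample")
    intens = table.intensities.copy()
    block = intens[sample_ids]
    mins = block.where(block > 0).min(axis=1)
    if mins.isna().any():
        bad = list(mins.index[mins.isna()])
        raise ValidationError(
            f"feature(s) with no detected values (should have been filtered): {bad}"
        )
    fill = pd.DataFrame(
        np.tile((mins / divisor).to_numpy()[:, None], (1, len(sample_ids))),
        index=block.index,
        columns=sample_ids,
    )
    intens[sample_ids] = block.where(block > 0, fill)
    return table.with_intensities(intens)


def flow_normalize(table: FeatureTable, direction: str = "multiply") -> FeatureTable:
    """Convert concentration-like signals into load-like signals.

    ``multiply`` (default): intensity(f, t) * flow(t) / mean(flow), so
    dilution-driven intensity dips are flattened.  ``divide`` applies the
    inverse rescaling.  The mean-flow scaling keeps units comparable with
    the unnormalized table; constant flow leaves the table unchanged.
    """
    if direction not in ("multiply", "divide"):
        raise ValidationError("direction must be 'multiply' or 'divide'")
    sample_ids = table.sample_ids("sample")
    flow = table.sample_meta.loc[sample_ids, "flow_rate"]
    if flow.isna().any() or (flow <= 0).any():
        bad = list(flow.index[flow.isna() | (flow <= 0)])
        raise ValidationError(f"missing or non-positive flow_rate for: {bad}")
    rel = flow / flow.mean()
    if direction == "divide":
        rel = 1.0 / rel
    intens = table.intensities.copy()
    intens[sample_ids] = intens[sample_ids] * rel.to_numpy()[None, :]
    return table.with_intensities(intens)


# -- data configurations -----------------------------------------------


def assemble_configuration(
    table: FeatureTable, spec: SampleConfigurationSpec
) -> dict[str, pd.DataFrame]:
    """Arrange hourly samples into trajectory matrices (features x m).

    Returns a mapping from configuration label to trajectory matrix:
    ``continuous_72h`` -> one 72-column matrix ordered day-major,
    hour-minor; ``hourly_average`` -> one 24-column matrix of means over
    the three days; ``per_day`` -> three 24-column matrices (``day1``..);
    ``randomized`` -> one 72-column matrix with the sample order permuted
    by the spec's seed.
    """
    meta = table.sample_meta
    hourly = meta[meta["sample_type"] == "sample"].sort_values(["day", "hour"])
    days = sorted(hourly["day"].unique())

    if spec.mode in ("continuous_72h", "randomized", "hourly_average"):
        expected = {(d, h) for d in (1, 2, 3) for h in range(24)}
        present = set(zip(hourly["day"], hourly["hour"]))
        gaps = sorted(expected - present)
        if gaps:
            raise ValidationError(f"missing (day, hour) samples: {gaps}")

    ordered = table.intensities[list(hourly.index)]

    if spec.mode == "continuous_72h":
        return {"continuous_72h": ordered.copy()}
    if spec.mode == "randomized":
        # permutation null: shuffle each feature's sample order
        # independently, destroying cross-series temporal association
        # while preserving every trajectory's value multiset (a shared
        # column permutation would leave the cluster analysis unchanged)
        rng = np.random.default_rng(spec.seed)
        vals = ordered.to_numpy().copy()
        for i in range(vals.shape[0]):
            vals[i] = vals[i, rng.permutation(vals.shape[1])]
        shuffled = pd.DataFrame(
            vals,
            index=ordered.index,
            columns=[f"r{t:02d}" for t in range(vals.shape[1])],
        )
        return {"randomized": shuffled}
    if spec.mode == "hourly_average":
        by_hour = {}
        for h in range(24):
            cols = hourly.index[hourly["hour"] == h]
            by_hour[h] = ordered[list(cols)].mean(axis=1)
        avg = pd.DataFrame(by_hour)
        avg.columns = [f"H{h:02d}" for h in range(24)]
        return {"hourly_average": avg}
    # per_day
    out = {}
    for d in days:
        cols = hourly.index[hourly["day"] == d]
        out[f"day{d}"] = ordered[list(cols)].copy()
    return out


# -- Eq-1 scaling -------------------------------------------------------


def scale_trajectories(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Standardize each trajectory's log2 intensities: z = (log2 x - mu) / sigma.

    mu and sigma are the mean and sample (n-1) standard deviation of the
    feature's log2 intensities across the time points, so each returned
    row has mean 0 and unit standard deviation.  All values must be
    strictly positive (run imputation first); a constant trajectory
    (sigma = 0) is an error because it should have been removed by the
    variance filter.
    """
    vals = trajectories.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValidationError("no trajectories to scale")
    if (vals <= 0).any():
        bad = trajectories.index[(vals <= 0).any(axis=1)]
        raise ValidationError(
            f"non-positive values; impute non-detects before scaling: {list(bad)}"
        )
    logv = np.log2(vals)
    mu = logv.mean(axis=1, keepdims=True)
    sigma = logv.std(axis=1, ddof=1, keepdims=True)
    if (sigma == 0).any():
        bad = trajectories.index[(sigma == 0).ravel()]
        raise ValidationError(f"constant trajectories cannot be scaled: {list(bad)}")
    return pd.DataFrame(
        (logv - mu) / sigma, index=trajectories.index, columns=trajectories.columns
    )


def scale_trajectory(values: pd.Series) -> pd.Series:
    """Scale a single trajectory; see :func:`scale_trajectories`."""
    z = scale_trajectories(values.to_frame().T)
    return z.iloc[0]


# -- convenience pipeline ----------------------------------------------


@dataclass
class PreprocessParams:
    """Thresholds of the filtering pipeline with their standard defaults."""

    blank_factor: float = DEFAULT_BLANK_FACTOR
    df_threshold: float = DEFAULT_DF_THRESHOLD
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD
    imputation_divisor: float = DEFAULT_IMPUTATION_DIVISOR
    apply_blank_filter: bool = True
    flow_normalize: bool = False
    flow_direction: str = "multiply"


@dataclass
class PreprocessResult:
    table: FeatureTable
    scaled: dict[str, pd.DataFrame]
    funnel: dict[str, int] = field(default_factory=dict)


def run_preprocess(
    table: FeatureTable,
    spec: SampleConfigurationSpec,
    params: PreprocessParams | None = None,
) -> PreprocessResult:
    """Run the full filtering/scaling pipeline; records the feature funnel."""
    params = params or PreprocessParams()
    funnel = {"input": table.n_features}
    if params.apply_blank_filter and table.sample_ids("blank"):
        table = blank_filter(table, params.blank_factor)
        funnel["blank_filter"] = table.n_features
    table = detection_frequency_filter(table, params.df_threshold)
    funnel["detection_frequency_filter"] = table.n_features
    table = variance_filter(table, params.rsd_threshold)
    funnel["variance_filter"] = table.n_features
    table = impute_nondetects(table, params.imputation_divisor)
    if params.flow_normalize or spec.flow_normalize:
        table = flow_normalize(table, params.flow_direction)
    configs = assemble_configuration(table, spec)
    scaled = {label: scale_trajectories(m) for label, m in configs.items()}
    return PreprocessResult(table=table, scaled=scaled, funnel=funnel)
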