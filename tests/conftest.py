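import numpy as np
import pandas as pd
import pytest

import dielscreen as ds


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study: 5 archetypes x 20 features, rsd 0.20."""
    cfg = ds.SyntheticConfig(seed=1)
    table, truth = ds.generate_dataset(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    cfg, table, truth = default_dataset
    spec = ds.SampleConfigurationSpec(mode="continuous_72h")
    res = ds.run_preprocess(table, spec)
    return res


@pytest.fixture(scope="session")
def scaled_patterns(default_dataset, preprocessed):
    """Scaled trajectories of the surviving pattern features plus labels."""
    _, _, truth = default_dataset
    Z = preprocessed.scaled["continuous_72h"]
    keep = Z.index[~truth.loc[Z.index].isin(["noise", "internal_standard"])]
    return Z.loc[keep], truth.loc[keep]


@pytest.fixture(scope="session")
def fitted_model(scaled_patterns):
    Z, _ = scaled_patterns
    return ds.select_k(Z, seed=1)


def tiny_table(
    intensities: np.ndarray,
    n_blanks: int = 0,
    blank_value: float = 0.0,
    flow: np.ndarray | None = None,
    feature_ids: list[str] | None = None,
) -> ds.FeatureTable:
    """Hand-built feature table: hourly samples (day-major) plus blanks."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_hourly = intensities.shape
    fids = feature_ids or [f"F{i:03d}" for i in range(n_feat)]
    sample_ids = [f"D{t // 24 + 1}H{t % 24:02d}" for t in range(n_hourly)]
    meta = pd.DataFrame(
        {
            "day": [t // 24 + 1 for t in range(n_hourly)],
            "hour": [t % 24 for t in range(n_hourly)],
            "sample_type": "sample",
            "flow_rate": flow if flow is not None else np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = intensities
    if n_blanks:
        bids = [f"BK{i}" for i in range(n_blanks)]
        bmeta = pd.DataFrame(
            {"day": 0, "hour": 0, "sample_type": "blank", "flow_rate": np.nan},
            index=pd.Index(bids, name="sample_id"),
        )
        meta = pd.concat([meta, bmeta])
        vals = np.hstack([vals, np.full((n_feat, n_blanks), blank_value)])
    idx = pd.Index(fids, name="feature_id")
    from dielscreen.datamodel import empty_feature_meta

    return ds.FeatureTable(
        pd.DataFrame(vals, index=idx, columns=meta.index),
        empty_feature_meta(fids),
        meta,
    )
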