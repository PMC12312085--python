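"""End-to-end pipeline: preprocess, cluster targets, predict non-targets,
summarize trends, and write every output with provenance.

One seed governs all stochastic steps (clustering restarts and the
randomized-order control); identical inputs, configuration and seed give
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import (
    DEFAULT_CORT_K,
    DEFAULT_MAX_ITER,
    DEFAULT_MEMBERSHIP_THRESHOLD,
    DEFAULT_N_RESTARTS,
    filter_by_membership,
    select_k,
)
from .datamodel import FeatureTable, SampleConfigurationSpec
from .errors import DielscreenError, StageError, ValidationError
from .io import read_feature_table, write_cluster_outputs, write_feature_table
from .predict import DEFAULT_RATIO_THRESHOLD, predict_clusters, reassign_targets_qc
from .preprocess import PreprocessParams, run_preprocess
from .trends import cluster_trends

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: paths, thresholds, and the single seed."""

    feature_table: str = ""
    sample_meta: str = ""
    out_dir: str = "dielscreen_out"
    # preprocess
    blank_factor: float = 1.5
    df_threshold: float = 0.85
    rsd_threshold: float = 0.45
    imputation_divisor: float = 4.0
    configuration: str = "continuous_72h"
    flow_normalize: bool = False
    flow_direction: str = "multiply"
    # clustering
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = DEFAULT_N_RESTARTS
    max_iter: int = DEFAULT_MAX_ITER
    cort_k: float = DEFAULT_CORT_K
    membership_threshold: float = DEFAULT_MEMBERSHIP_THRESHOLD
    # prediction
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD
    median_threshold_mode: str = "global"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    model: object
    predictions: pd.DataFrame
    funnel: dict[str, int]
    qc_agreement: float
    files: list[Path] = field(default_factory=list)


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": "dielscreen",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
    }


def run_pipeline(
    config: PipelineConfig, table: FeatureTable | None = None
) -> PipelineResult:
    """Execute preprocess -> cluster -> predict -> trends and write outputs.

    ``table`` may be passed directly (e.g., freshly simulated); otherwise
    it is read from the configured paths.  Writes, into ``out_dir``:
    ``filtered_table.csv``/``filtered_samples.csv``, ``assignments.csv``,
    ``centroids.csv``, ``predictions.csv``, ``trends_summary.csv``,
    ``cluster_smooth.csv``, plus the resolved config and a provenance
    record.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if table is None:
        try:
            table = read_feature_table(config.feature_table, config.sample_meta)
        except DielscreenError as e:
            raise StageError("read", str(e)) from e

    # -- preprocess ----------------------------------------------------
    try:
        spec = SampleConfigurationSpec(
            mode=config.configuration,
            flow_normalize=config.flow_normalize,
            seed=config.seed,
        )
        params = PreprocessParams(
            blank_factor=config.blank_factor,
            df_threshold=config.df_threshold,
            rsd_threshold=config.rsd_threshold,
            imputation_divisor=config.imputation_divisor,
            apply_blank_filter=bool(table.sample_ids("blank")),
            flow_normalize=config.flow_normalize,
            flow_direction=config.flow_direction,
        )
        pre = run_preprocess(table, spec, params)
    except DielscreenError as e:
        raise StageError("preprocess", str(e)) from e

    label, Z = next(iter(pre.scaled.items()))
    meta = pre.table.feature_meta
    target_ids = Z.index[meta.loc[Z.index, "is_target"]]
    nontarget_ids = Z.index[
        ~meta.loc[Z.index, "is_target"] & ~meta.loc[Z.index, "is_internal_standard"]
    ]
    if len(target_ids) < config.k_max + 1:
        raise StageError(
            "cluster",
            f"only {len(target_ids)} target trajectories survive filtering; "
            f"need more than k_max={config.k_max}",
        )

    # -- cluster targets ----------------------------------------------
    try:
        model = select_k(
            Z.loc[target_ids],
            k_range=range(config.k_min, config.k_max + 1),
            seed=config.seed,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            cort_k=config.cort_k,
        )
        confident = filter_by_membership(model, config.membership_threshold)
        logger.info(
            "clustered %d targets into k=%d; %d pass the %.0f%% membership filter",
            len(target_ids), model.k, len(confident),
            100 * config.membership_threshold,
        )
    except DielscreenError as e:
        raise StageError("cluster", str(e)) from e

    # -- predict non-targets -------------------------------------------
    try:
        if len(confident) == 0:
            logger.warning(
                "no target passes the membership filter; using all clustered "
                "targets for the prediction threshold"
            )
            confident = pd.Index(target_ids)
        Z_conf = Z.loc[confident]
        predictions = (
            predict_clusters(
                Z.loc[nontarget_ids],
                model,
                Z_conf,
                ratio_threshold=config.ratio_threshold,
                median_mode=config.median_threshold_mode,
            )
            if len(nontarget_ids)
            else pd.DataFrame(
                columns=[
                    "nearest", "second_nearest", "d_nearest", "d_second",
                    "ratio", "threshold", "retained", "reason",
                ]
            )
        )
        qc_agreement = reassign_targets_qc(model, Z_conf)
        if qc_agreement < 1.0:
            logger.warning(
                "target re-assignment QC: %.3f of targets keep their cluster "
                "under the squared-Euclidean prediction metric", qc_agreement,
            )
    except DielscreenError as e:
        raise StageError("predict", str(e)) from e

    # -- trends ---------------------------------------------------------
    try:
        sample_ids = pre.table.sample_ids("sample")
        flow = pre.table.sample_meta.loc[sample_ids, "flow_rate"]
        flow_vec = None
        if flow.notna().all() and Z.shape[1] == len(flow):
            flow_vec = flow.to_numpy()
        smooths, summary = cluster_trends(
            model, Z.loc[target_ids], flow=flow_vec, feature_meta=meta
        )
    except DielscreenError as e:
        raise StageError("trends", str(e)) from e

    # -- write outputs ---------------------------------------------------
    files: list[Path] = []
    ft_path = out_dir / "filtered_table.csv"
    sm_path = out_dir / "filtered_samples.csv"
    write_feature_table(pre.table, ft_path, sm_path)
    files += [ft_path, sm_path]

    a_path, c_path = write_cluster_outputs(model, predictions, out_dir)
    files += [a_path, c_path]

    p_path = out_dir / "predictions.csv"
    predictions.rename_axis("feature_id").to_csv(p_path)
    files.append(p_path)

    t_path = out_dir / "trends_summary.csv"
    summary.to_csv(t_path)
    files.append(t_path)

    s_path = out_dir / "cluster_smooth.csv"
    pd.concat(
        {j: s.set_index("time") for j, s in smooths.items()}, names=["cluster"]
    ).to_csv(s_path)
    files.append(s_path)

    cfg_path = out_dir / "resolved_config.yaml"
    config.to_yaml(cfg_path)
    files.append(cfg_path)
    prov_path = out_dir / "provenance.json"
    prov = _provenance(config)
    prov["funnel"] = pre.funnel
    prov["configuration"] = label
    prov["selected_k"] = int(model.k)
    prov["qc_agreement"] = qc_agreement
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2)
    files.append(prov_path)

    return PipelineResult(
        out_dir=out_dir,
        model=model,
        predictions=predictions,
        funnel=pre.funnel,
        qc_agreement=qc_agreement,
        files=files,
    )
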