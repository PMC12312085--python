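"""Synthetic influent-wastewater feature tables with known diel structure.

The generator emulates the study design the analysis pipeline assumes:
72 hourly composite samples over 3 consecutive days, features following
one of five recurring diel discharge archetypes, multiplicative
lognormal measurement noise, low-variance internal standards, procedure
blanks, sporadic non-detects, and an optional rain-event flow surge on
the first night.

Archetypes
----------
``DA``
    Daytime-activity plateau, elevated between 10:00 and 20:00
    (showering, washing machines, dishwashers).
``MP``
    Morning peak, Gaussian bump centred at 07:30 with sd 1.0 h
    (first morning urine void, 06:00-09:00 elevation).
``BG1``
    Dilution-driven background: inversely proportional to the influent
    flow, so it dips during the rain surge and tracks low night flow.
``BG2``
    Slow evening drift: a broad sinusoid peaking late in the evening,
    independent of flow.
``BG3``
    Runoff pattern: proportional to the rain-event flow surge only;
    flat when no rain event is simulated.
``BG_flat``
    Constant mean level; used for internal standards and for
    pure-noise features, never as a cluster archetype.

All archetype curves are strictly positive and are normalised so that
``amplitude`` is the fold-change of the curve maximum over its baseline.
Generation is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import FeatureTable
from .errors import ValidationError

#: hourly time axis over the three sampling days
N_DAYS = 3
HOURS_PER_DAY = 24
N_TIMEPOINTS = N_DAYS * HOURS_PER_DAY

#: the five clusterable diel archetypes
ARCHETYPES = ("DA", "MP", "BG1", "BG2", "BG3")

#: compound classes attached to annotated targets of each archetype
ARCHETYPE_CLASSES = {
    "DA": "household product",
    "MP": "pharmaceutical",
    "BG1": "industrial chemical",
    "BG2": "food ingredient",
    "BG3": "rubber additive",
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic-data generator.

    ``noise_rsd`` is the relative standard deviation of the multiplicative
    lognormal measurement noise on ordinary features; ``is_rsd`` the same
    for internal standards (default 0.25, within the 13-30 % range
    observed for isotope-labelled standards in hourly influent samples).
    ``target_fraction`` of each archetype's features are flagged as
    annotated targets; the rest stay unannotated non-targets with the
    same ground-truth label.  ``nondetect_rate`` censors that fraction of
    the lowest values of each low-abundance feature to 0.
    """

    n_features_per_archetype: int = 20
    n_noise_features: int = 50
    n_internal_standards: int = 10
    n_blanks: int = 3
    noise_rsd: float = 0.20
    is_rsd: float = 0.25
    nondetect_rate: float = 0.05
    target_fraction: float = 0.5
    amplitude: float = 5.0
    rain_event: bool = True
    rain_start: int = 20  # hour index on the 72-h axis (day 1, 20:00)
    rain_end: int = 28  # exclusive (day 2, 04:00)
    surge_factor: float = 2.0
    mean_flow: float = 1000.0  # m^3/h
    flow_swing: float = 0.4  # relative diurnal amplitude of the flow
    baseline_log10_range: tuple[float, float] = (3.0, 6.0)
    blank_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_rsd", "is_rsd"):
            v = getattr(self, name)
            if not 0 <= v < 1:  # 0 = noiseless limit, used in tests
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.nondetect_rate < 1:
            raise ValidationError("nondetect_rate must be in [0, 1)")
        for name in (
            "n_features_per_archetype",
            "n_noise_features",
            "n_internal_standards",
            "n_blanks",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.amplitude <= 1:
            raise ValidationError("amplitude must exceed 1 (fold-change over baseline)")


def generate_flow_profile(config: SyntheticConfig) -> pd.Series:
    """Influent flow rate (volume/hour) at each of the 72 hourly samples.

    A diurnal sinusoid with an afternoon maximum (17:00) and a night
    minimum (05:00), repeated identically over the three days; when
    ``rain_event`` is set, hours 20-27 of the 72-h axis (day 1, 20:00 to
    day 2, 04:00) are multiplied by ``surge_factor``.
    """
    t = np.arange(N_TIMEPOINTS)
    hour = t % HOURS_PER_DAY
    flow = config.mean_flow * (
        1.0 + config.flow_swing * np.sin(2 * np.pi * (hour - 11) / HOURS_PER_DAY)
    )
    if config.rain_event:
        window = (t >= config.rain_start) & (t < config.rain_end)
        flow = np.where(window, flow * config.surge_factor, flow)
    return pd.Series(flow, index=_sample_ids_72(), name="flow_rate")


def _sample_ids_72() -> pd.Index:
    ids = [
        f"D{d}H{h:02d}" for d in range(1, N_DAYS + 1) for h in range(HOURS_PER_DAY)
    ]
    return pd.Index(ids, name="sample_id")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def archetype_curves(config: SyntheticConfig) -> pd.DataFrame:
    """Noiseless mean curves of the five archetypes on the 72-h axis.

    Each curve is ``1 + (amplitude - 1) * s(t)`` with the shape ``s``
    normalised to [0, 1], so every curve is strictly positive and has the
    configured peak-over-baseline fold-change.
    """
    t = np.arange(N_TIMEPOINTS)
    hour = t % HOURS_PER_DAY
    flow = generate_flow_profile(config).to_numpy()

    shapes: dict[str, np.ndarray] = {}
    # DA: smooth plateau between 10:00 and 20:00
    shapes["DA"] = _logistic((hour - 10.0) / 1.2) * _logistic((20.0 - hour) / 1.2)
    # MP: Gaussian morning bump centred 07:30, sd 1.0 h
    shapes["MP"] = np.exp(-0.5 * (hour - 7.5) ** 2)
    # BG1: dilution pattern, monotone in 1/flow; the cubic sharpening keeps
    # the temporal variation of the curve above the 45 % variance-filter
    # threshold while preserving rank order (dips during the rain surge)
    inv = (1.0 / flow) ** 3
    shapes["BG1"] = (inv - inv.min()) / (inv.max() - inv.min())
    # BG2: slow drift peaking in the late evening (23:00), squared for the
    # same reason
    shapes["BG2"] = (0.5 * (1.0 + np.cos(2 * np.pi * (hour - 23.0) / HOURS_PER_DAY))) ** 2
    # BG3: proportional to the rain surge only
    no_rain = generate_flow_profile(replace(config, rain_event=False)).to_numpy()
    surge = flow / no_rain - 1.0
    shapes["BG3"] = surge / surge.max() if surge.max() > 0 else np.zeros_like(surge)

    curves = {
        name: 1.0 + (config.amplitude - 1.0) * _normalise(s)
        for name, s in shapes.items()
    }
    return pd.DataFrame(curves, index=_sample_ids_72()).T


def _normalise(s: np.ndarray) -> np.ndarray:
    rng_ = s.max() - s.min()
    return (s - s.min()) / rng_ if rng_ > 0 else np.zeros_like(s)


def _lognormal_noise(
    rng: np.random.Generator, rsd: float, size: tuple[int, ...]
) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given RSD.

    sigma^2 = ln(1 + rsd^2) gives exactly the requested relative standard
    deviation; the -sigma^2/2 mean offset makes E[noise] = 1.
    """
    sigma = np.sqrt(np.log1p(rsd**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_dataset(config: SyntheticConfig) -> tuple[FeatureTable, pd.Series]:
    """Generate a feature table and its ground-truth labels.

    Returns ``(table, truth)`` where ``truth`` maps each feature_id to its
    archetype name, ``"noise"`` or ``"internal_standard"``.  Intensity of
    feature *f* at hourly sample *t* is
    ``baseline_f * curve_archetype(t) * lognormal(rsd)``; baselines are
    drawn log-uniformly over ``baseline_log10_range`` (three orders of
    magnitude by default, mimicking the dynamic range of wastewater
    features).  Blanks carry only a small constant background.
    """
    n_pattern = config.n_features_per_archetype * len(ARCHETYPES)
    n_total = n_pattern + config.n_noise_features + config.n_internal_standards
    if n_total == 0:
        raise ValidationError("configuration generates zero features")

    rng = np.random.default_rng(config.seed)
    curves = archetype_curves(config)
    flow = generate_flow_profile(config)
    sample_ids = _sample_ids_72()

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    labels: list[str] = []
    ids: list[str] = []

    lo, hi = config.baseline_log10_range
    for name in ARCHETYPES:
        curve = curves.loc[name].to_numpy()
        n = config.n_features_per_archetype
        baselines = 10.0 ** rng.uniform(lo, hi, size=n)
        noise = _lognormal_noise(rng, config.noise_rsd, (n, N_TIMEPOINTS))
        block = baselines[:, None] * curve[None, :] * noise
        n_targets = int(round(config.target_fraction * n))
        for i in range(n):
            fid = f"{name}_{i:03d}"
            ids.append(fid)
            labels.append(name)
            is_target = i < n_targets
            meta_rows.append(
                {
                    "mz": rng.uniform(100, 1000),
                    "rt": rng.uniform(1, 15),
                    "ion_mode": "pos",
                    "annotation": f"target_{fid}" if is_target else None,
                    "compound_class": ARCHETYPE_CLASSES[name] if is_target else None,
                    "is_target": is_target,
                    "is_internal_standard": False,
                }
            )
        rows.append(block)

    # pure-noise features: flat mean, per-feature RSD drawn below the 45 %
    # variance-filter threshold so they are designed to be eliminated
    if config.n_noise_features:
        n = config.n_noise_features
        baselines = 10.0 ** rng.uniform(lo, hi, size=n)
        rsds = rng.uniform(0.05, 0.35, size=n)
        block = np.empty((n, N_TIMEPOINTS))
        for i in range(n):
            block[i] = baselines[i] * _lognormal_noise(
                rng, rsds[i], (N_TIMEPOINTS,)
            )
        rows.append(block)
        for i in range(n):
            fid = f"NOISE_{i:03d}"
            ids.append(fid)
            labels.append("noise")
            meta_rows.append(
                {
                    "mz": rng.uniform(100, 1000),
                    "rt": rng.uniform(1, 15),
                    "ion_mode": "pos",
                    "annotation": None,
                    "compound_class": None,
                    "is_target": False,
                    "is_internal_standard": False,
                }
            )

    # internal standards: spiked at a constant level, flat, low variance
    if config.n_internal_standards:
        n = config.n_internal_standards
        block = 1.0e5 * _lognormal_noise(rng, config.is_rsd, (n, N_TIMEPOINTS))
        rows.append(block)
        for i in range(n):
            fid = f"IS_{i:03d}"
            ids.append(fid)
            labels.append("internal_standard")
            meta_rows.append(
                {
                    "mz": rng.uniform(100, 1000),
                    "rt": rng.uniform(1, 15),
                    "ion_mode": "pos",
                    "annotation": f"IS_{i:03d}",
                    "compound_class": "internal standard",
                    "is_target": False,
                    "is_internal_standard": True,
                }
            )

    intens = np.vstack(rows)

    # censor the lowest values of low-abundance features to non-detects
    if config.nondetect_rate > 0:
        is_is = np.array([lab == "internal_standard" for lab in labels])
        means = intens.mean(axis=1)
        ordinary = ~is_is
        if ordinary.any():
            cutoff = np.quantile(means[ordinary], 0.25)
            n_censor = int(np.ceil(config.nondetect_rate * N_TIMEPOINTS))
            for i in np.where(ordinary & (means <= cutoff))[0]:
                low = np.argsort(intens[i])[:n_censor]
                intens[i, low] = 0.0

    feature_index = pd.Index(ids, name="feature_id")
    feature_meta = pd.DataFrame(meta_rows, index=feature_index)

    # sample metadata: 72 hourly samples + procedure blanks
    days = np.repeat(np.arange(1, N_DAYS + 1), HOURS_PER_DAY)
    hours = np.tile(np.arange(HOURS_PER_DAY), N_DAYS)
    sample_meta = pd.DataFrame(
        {
            "day": days,
            "hour": hours,
            "sample_type": "sample",
            "flow_rate": flow.to_numpy(),
        },
        index=sample_ids,
    )
    blank_ids = [f"BK{i}" for i in range(1, config.n_blanks + 1)]
    if blank_ids:
        blank_meta = pd.DataFrame(
            {
                "day": 0,
                "hour": 0,
                "sample_type": "blank",
                "flow_rate": np.nan,
            },
            index=pd.Index(blank_ids, name="sample_id"),
        )
        sample_meta = pd.concat([sample_meta, blank_meta])
        blanks = np.full((n_total, config.n_blanks), config.blank_level)
        intens = np.hstack([intens, blanks])

    intensities = pd.DataFrame(intens, index=feature_index, columns=sample_meta.index)
    table = FeatureTable(intensities, feature_meta, sample_meta)
    truth = pd.Series(labels, index=feature_index, name="label")
    return table, truth
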