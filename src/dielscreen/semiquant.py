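"""Semi-quantification via internal-standard pairing and weighted calibration.

Each compound is paired with the internal standard (IS) closest in
retention time; concentrations are then estimated from a straight-line
calibration fitted by weighted least squares with weights 1/x
(x = calibration concentration), which balances the relative influence
of low and high calibration levels.  Responses may be raw intensities or
analyte/IS intensity ratios — both are supported.

All outputs are labelled semi-quantified: surrogate calibration cannot
replace compound-specific validated quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: label attached to every concentration output
QUANT_LABEL = "semi-quantified"


def match_internal_standards(
    feature_meta: pd.DataFrame, is_meta: pd.DataFrame
) -> pd.Series:
    """Map each compound to the internal standard nearest in retention time.

    Ties in |rt difference| break to the earlier-eluting IS.  Both frames
    need an ``rt`` column (minutes); index = feature/compound ids.
    """
    if is_meta.empty:
        raise ValidationError("no internal standards available for matching")
    is_rt = is_meta["rt"].sort_values(kind="stable")  # earlier-eluting first
    mapping = {}
    for fid, rt in feature_meta["rt"].items():
        diffs = (is_rt - rt).abs()
        mapping[fid] = diffs.idxmin()  # first minimum -> earlier-eluting IS
    return pd.Series(mapping, name="is_id")


@dataclass(frozen=True)
class CalibrationModel:
    """Straight-line calibration fitted with 1/x weighting."""

    compound_id: str
    is_id: str | None
    slope: float
    intercept: float
    calibration_points: tuple[tuple[float, float], ...]
    weighting: str = "1/x"

    @property
    def usable(self) -> bool:
        return self.slope > 0


def fit_calibration(
    points: Sequence[tuple[float, float]],
    compound_id: str = "",
    is_id: str | None = None,
) -> CalibrationModel:
    """Weighted least-squares line through (concentration, response) pairs.

    Minimises sum_i w_i (y_i - a - b x_i)^2 with w_i = 1/x_i.  Requires at
    least 3 points with strictly positive concentrations (the weight is
    undefined at x = 0).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValidationError("calibration needs at least 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if (x <= 0).any():
        raise ValidationError("calibration concentrations must be > 0 (1/x weighting)")
    w = 1.0 / x
    # weighted normal equations for intercept a and slope b
    S = np.array(
        [[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]]
    )
    rhs = np.array([(w * y).sum(), (w * x * y).sum()])
    a, b = np.linalg.solve(S, rhs)
    return CalibrationModel(
        compound_id=compound_id,
        is_id=is_id,
        slope=float(b),
        intercept=float(a),
        calibration_points=tuple(pts),
    )


class QuantResult(NamedTuple):
    concentration: float  # ng/L (same unit as the calibration levels)
    floored: bool  # True when a negative estimate was clipped to 0
    label: str = QUANT_LABEL


def quantify(response: float, model: CalibrationModel) -> QuantResult:
    """Invert the calibration: concentration = (response - intercept) / slope.

    Negative estimates are floored at 0 and flagged.
    """
    if model.slope <= 0:
        raise ValidationError(
            f"calibration for {model.compound_id!r} has non-positive slope"
        )
    conc = (response - model.intercept) / model.slope
    if conc < 0:
        return QuantResult(0.0, True)
    return QuantResult(float(conc), False)


def quantify_series(responses: pd.Series, model: CalibrationModel) -> pd.DataFrame:
    """Quantify many responses; returns concentration and floored flag."""
    results = [quantify(r, model) for r in responses]
    return pd.DataFrame(
        {
            "concentration": [r.concentration for r in results],
            "floored": [r.floored for r in results],
            "label": QUANT_LABEL,
        },
        index=responses.index,
    )
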