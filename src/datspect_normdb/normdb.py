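"""Age-dependent normal ranges and scan-level normality classification.

Healthy SBR declines roughly linearly with age, so the normal database is an
ordinary least-squares fit of SBR on age with bounds at ``bound_multiplier``
times the standard error of the predicted mean,
``s * sqrt(1/n + (age - mean_age)^2 / Sxx)``; the lower bound is the
threshold of normality. Setting ``prediction_interval=True`` adds the usual
``+1`` under the square root for a single-observation interval instead.

A scan is abnormal when at least one region inspected by the chosen rule is
below its lower limit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ModelError, ValidationError

RULES: dict[str, tuple[tuple[str, str], ...]] = {
    "striatum_either_side": (("left", "striatum"), ("right", "striatum")),
    "putamen_either_side": (("left", "putamen"), ("right", "putamen")),
    # per-side striatal SBRs by default; any available striatal region counts
    "southampton_striatal": (),
}


@dataclass(frozen=True)
class NormalRangeModel:
    slope: float  # SBR per year, expected negative on healthy data
    intercept: float  # SBR at age 0
    n: int
    mean_age: float
    sxx: float  # sum of squared age deviations
    residual_se: float
    bound_multiplier: float = 2.0
    prediction_interval: bool = False
    quantifier: str = ""
    mode: str = ""
    calibrated: bool = False
    structure: str = ""
    side: str = ""

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ModelError("a normal-range model needs n >= 3")
        if self.sxx <= 0:
            raise ModelError("degenerate age spread (sxx <= 0)")
        if self.residual_se < 0:
            raise ModelError("residual_se must be >= 0")

    def predict(self, age: float) -> float:
        return self.intercept + self.slope * age

    def se_pred(self, age: float) -> float:
        leverage = 1.0 / self.n + (age - self.mean_age) ** 2 / self.sxx
        if self.prediction_interval:
            leverage += 1.0
        return self.residual_se * math.sqrt(leverage)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormalRangeModel":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelError(f"malformed normal-range JSON: {exc}") from exc
        return cls(**payload)


def fit_normal_range(
    ages: Sequence[float],
    sbrs: Sequence[float],
    bound_multiplier: float = 2.0,
    prediction_interval: bool = False,
    **meta: object,
) -> NormalRangeModel:
    """OLS fit of SBR on age with everything needed to evaluate bounds later."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(sbrs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ModelError("ages and SBRs must be 1D sequences of equal length")
    n = x.size
    if n < 3:
        raise ModelError("at least 3 healthy subjects are required")
    mean_age = float(x.mean())
    sxx = float(((x - mean_age) ** 2).sum())
    if sxx <= 0:
        raise ModelError("degenerate ages: no spread to fit an age relationship")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    residual_se = float(np.sqrt((residuals**2).sum() / (n - 2)))
    if slope >= 0:
        warnings.warn(
            f"fitted age slope {slope:.4g} is not negative; healthy SBR is "
            "expected to decline with age",
            stacklevel=2,
        )
    return NormalRangeModel(
        slope=float(slope),
        intercept=float(intercept),
        n=int(n),
        mean_age=mean_age,
        sxx=sxx,
        residual_se=residual_se,
        bound_multiplier=float(bound_multiplier),
        prediction_interval=bool(prediction_interval),
        **meta,  # type: ignore[arg-type]
    )


def lower_limit(model: NormalRangeModel, age: float) -> float:
    """The threshold of normality at a given age."""
    return model.predict(age) - model.bound_multiplier * model.se_pred(age)


def upper_limit(model: NormalRangeModel, age: float) -> float:
    return model.predict(age) + model.bound_multiplier * model.se_pred(age)


def classify_region(sbr: float, model: NormalRangeModel, age: float) -> bool:
    """True when the SBR is abnormal (strictly below the lower limit).

    A value exactly on the limit is classified normal: the boundary gets the
    benefit of the doubt.
    """
    if not math.isfinite(sbr):
        raise ValidationError("SBR must be finite")
    return sbr < lower_limit(model, age)


@dataclass(frozen=True)
class ScanVerdict:
    subject_id: str
    rule: str
    region_flags: Mapping[tuple[str, str], bool]
    scan_abnormal: bool


def classify_scan(
    per_region_results: Mapping[tuple[str, str], bool],
    rule: str,
    subject_id: str = "",
) -> ScanVerdict:
    """Scan is abnormal iff at least one region inspected by the rule is."""
    if rule not in RULES:
        raise ValidationError(f"unknown classification rule {rule!r}")
    if rule == "southampton_striatal":
        regions = tuple(
            key for key in per_region_results if key[1] == "striatum"
        )
        if not regions:
            raise ModelError(
                f"rule {rule!r}: no striatal region results available"
            )
    else:
        regions = RULES[rule]
        missing = [key for key in regions if key not in per_region_results]
        if missing:
            raise ModelError(f"rule {rule!r}: missing region results for {missing}")
    flags = {key: bool(per_region_results[key]) for key in regions}
    return ScanVerdict(
        subject_id=subject_id,
        rule=rule,
        region_flags=flags,
        scan_abnormal=any(flags.values()),
    )
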