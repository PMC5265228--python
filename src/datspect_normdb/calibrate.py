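"""Scanner characterisation: linear measured-vs-true SBR calibration.

A phantom of known true SBRs imaged on a given scanner with a given
reconstruction yields measured SBRs that are (to good approximation) an
affine function of truth. Fitting that line per scanner/reconstruction/
quantifier and inverting it converts patient measurements onto a common
"true SBR" scale, so normal data from many scanners can be pooled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError
from .quantify import SBRRecord


@dataclass(frozen=True)
class CalibrationLine:
    """measured = slope * true + intercept for one scanner/mode/quantifier."""

    scanner_id: str
    mode: str
    quantifier: str
    structure: str
    slope: float
    intercept: float
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"calibration slope must be positive (got {self.slope:.4g}) — "
                "unusable scanner characterisation"
            )
        if self.n_points < 2:
            raise CalibrationError("a calibration line needs at least 2 points")
        if self.residual_sd < 0:
            raise CalibrationError("residual_sd must be >= 0")


def fit_calibration(
    measured: Sequence[float],
    true_values: Sequence[float],
    *,
    scanner_id: str = "",
    mode: str = "",
    quantifier: str = "",
    structure: str = "",
) -> CalibrationLine:
    """Ordinary least-squares fit of measured SBR on true phantom SBR."""
    m = np.asarray(measured, dtype=float)
    t = np.asarray(true_values, dtype=float)
    if m.shape != t.shape or m.ndim != 1:
        raise CalibrationError("measured and true value lists must match in length")
    n = m.size
    if n < 2:
        raise CalibrationError("at least 2 phantom points are required")
    if np.ptp(t) == 0:
        raise CalibrationError("true phantom SBRs are all identical (degenerate fit)")
    slope, intercept = np.polyfit(t, m, 1)
    residuals = m - (slope * t + intercept)
    residual_sd = float(np.sqrt((residuals**2).sum() / (n - 2))) if n > 2 else 0.0
    if slope <= 0:
        raise CalibrationError(
            f"fitted slope {slope:.4g} <= 0 for scanner {scanner_id!r}"
        )
    return CalibrationLine(
        scanner_id=scanner_id,
        mode=mode,
        quantifier=quantifier,
        structure=structure,
        slope=float(slope),
        intercept=float(intercept),
        n_points=int(n),
        residual_sd=residual_sd,
    )


def apply_calibration(measured_sbr: float, line: CalibrationLine) -> float:
    """Invert the calibration line: true = (measured - intercept) / slope."""
    return (measured_sbr - line.intercept) / line.slope


Key = tuple[str, str, str, str]  # scanner, mode, quantifier, structure

SHARED_STRUCTURE = "*"


class CalibrationSet:
    """Lookup table of calibration lines keyed by scanner/mode/quantifier/structure.

    A line stored with structure ``"*"`` is shared across structures
    (shared-line mode).
    """

    def __init__(self, lines: Iterable[CalibrationLine] = ()) -> None:
        self._lines: dict[Key, CalibrationLine] = {}
        for line in lines:
            self.add(line)

    def add(self, line: CalibrationLine) -> None:
        key = (line.scanner_id, line.mode, line.quantifier, line.structure)
        if key in self._lines:
            raise CalibrationError(f"duplicate calibration line for {key}")
        self._lines[key] = line

    def lookup(
        self, scanner_id: str, mode: str, quantifier: str, structure: str
    ) -> CalibrationLine:
        line = self._lines.get((scanner_id, mode, quantifier, structure))
        if line is None:
            line = self._lines.get((scanner_id, mode, quantifier, SHARED_STRUCTURE))
        if line is None:
            raise CalibrationError(
                f"no calibration line for scanner {scanner_id!r}, mode {mode!r}, "
                f"quantifier {quantifier!r}, structure {structure!r}"
            )
        return line

    def __len__(self) -> int:
        return len(self._lines)

    def __iter__(self):
        return iter(self._lines.values())

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps([asdict(line) for line in self._lines.values()], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationSet":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CalibrationError(f"malformed calibration JSON: {exc}") from exc
        if not isinstance(payload, list):
            raise CalibrationError("calibration JSON must be a list of lines")
        return cls(CalibrationLine(**entry) for entry in payload)


def pool_calibrated(
    records: Iterable[SBRRecord],
    lines: CalibrationSet | None,
    passthrough: bool = False,
) -> list[SBRRecord]:
    """Fill ``calibrated_sbr`` on every record.

    In pass-through (non-calibrated) mode the raw measured SBR is copied
    unchanged, implementing the "use the raw values as is" strategy.
    """
    out = []
    for record in records:
        if passthrough:
            calibrated = record.measured_sbr
        else:
            if lines is None:
                raise CalibrationError("a CalibrationSet is required unless passthrough")
            line = lines.lookup(
                record.scanner_id, record.mode, record.quantifier, record.structure
            )
            calibrated = apply_calibration(record.measured_sbr, line)
        out.append(replace(record, calibrated_sbr=calibrated))
    return out
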