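"""Diagnostic-performance statistics for paired classifier comparisons.

Confusion tables with one-decimal sensitivity/specificity, nonparametric
ROC AUC with a DeLong confidence interval, the paired (correlated-ROC)
DeLong AUC-difference test, and the two-tailed McNemar chi-square test on
discordant pairs.

Score orientation: SBR-like scores, where *lower* means more abnormal, are
the package-wide convention; scores are negated internally so an AUC above
0.5 means the score discriminates in the expected direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import EvaluationError, ValidationError
from .normdb import RULES, ScanVerdict
from .quantify import SBRRecord


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer")

    @property
    def n_abnormal(self) -> int:
        return self.tp + self.fn

    @property
    def n_normal(self) -> int:
        return self.tn + self.fp


def confusion(
    verdicts: Iterable[ScanVerdict],
    truth: Mapping[str, bool],
) -> ConfusionTable:
    """Cross-tabulate scan verdicts against truth (True = abnormal)."""
    tp = fp = tn = fn = 0
    for verdict in verdicts:
        if verdict.subject_id not in truth:
            raise EvaluationError(f"no truth label for subject {verdict.subject_id!r}")
        is_abnormal = bool(truth[verdict.subject_id])
        if verdict.scan_abnormal and is_abnormal:
            tp += 1
        elif verdict.scan_abnormal and not is_abnormal:
            fp += 1
        elif not verdict.scan_abnormal and is_abnormal:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def round_percent(value: float) -> float:
    """Round to one decimal, half away from zero (table convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def sensitivity(table: ConfusionTable) -> float:
    """100 * TP / (TP + FN), one decimal."""
    if table.n_abnormal == 0:
        raise EvaluationError("sensitivity undefined: no truth-abnormal subjects")
    return round_percent(100.0 * table.tp / table.n_abnormal)


def specificity(table: ConfusionTable) -> float:
    """100 * TN / (TN + FP), one decimal."""
    if table.n_normal == 0:
        raise EvaluationError("specificity undefined: no truth-normal subjects")
    return round_percent(100.0 * table.tn / table.n_normal)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_abnormal: int
    n_normal: int


@dataclass(frozen=True)
class PairedAucResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties averaged."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _oriented(scores: Sequence[float], higher_is_abnormal: bool) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        raise ValidationError("scores must be a 1D sequence")
    if not np.isfinite(x).all():
        raise ValidationError("scores must be finite")
    return x if higher_is_abnormal else -x


def _delong_components(
    score_sets: Sequence[np.ndarray], labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k paired score sets.

    Scores must already be oriented so higher = more abnormal; positives are
    the truth-abnormal subjects.
    """
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise EvaluationError("both classes must be present for ROC analysis")
    k = len(score_sets)
    aucs = np.empty(k)
    v01 = np.empty((k, m))  # structural components over positives
    v10 = np.empty((k, n))  # structural components over negatives
    for r, x in enumerate(score_sets):
        pos = x[labels]
        neg = x[~labels]
        tx = _midrank(pos)
        ty = _midrank(neg)
        tz = _midrank(np.concatenate([pos, neg]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.atleast_2d(np.cov(v01)) if m > 1 else np.zeros((k, k))
    s10 = np.atleast_2d(np.cov(v10)) if n > 1 else np.zeros((k, k))
    cov = s01 / m + s10 / n
    return aucs, cov


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    *,
    higher_is_abnormal: bool = False,
    ci_level: float = 0.95,
) -> RocResult:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong confidence interval."""
    y = np.asarray(labels, dtype=bool)
    x = _oriented(scores, higher_is_abnormal)
    if x.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    aucs, cov = _delong_components([x], y)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    zq = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    return RocResult(
        auc=float(aucs[0]),
        se=se,
        ci_low=max(0.0, float(aucs[0] - zq * se)),
        ci_high=min(1.0, float(aucs[0] + zq * se)),
        n_abnormal=int(y.sum()),
        n_normal=int((~y).sum()),
    )


def compare_auc_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    *,
    higher_is_abnormal: bool = False,
) -> PairedAucResult:
    """DeLong test for the difference of two correlated AUCs (two-sided)."""
    y = np.asarray(labels, dtype=bool)
    xa = _oriented(scores_a, higher_is_abnormal)
    xb = _oriented(scores_b, higher_is_abnormal)
    if xa.shape != xb.shape or xa.shape != y.shape:
        raise EvaluationError("paired score sets and labels must have equal length")
    aucs, cov = _delong_components([xa, xb], y)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        if math.isclose(diff, 0.0, abs_tol=1e-12):
            return PairedAucResult(float(aucs[0]), float(aucs[1]), 0.0, 1.0)
        raise EvaluationError("degenerate DeLong variance: cannot test AUC difference")
    z = diff / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return PairedAucResult(float(aucs[0]), float(aucs[1]), z, p)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float


def mcnemar_test(
    n_discordant_a_only: int,
    n_discordant_b_only: int,
    continuity_correction: bool = False,
) -> McNemarResult:
    """Two-tailed McNemar chi-square test on discordant-pair counts.

    chi2 = (|b - c| - correction)^2 / (b + c) with 1 df; depends on the
    discordant counts only.
    """
    b, c = n_discordant_a_only, n_discordant_b_only
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    if b + c == 0:
        raise EvaluationError("McNemar test undefined: no discordant pairs")
    adjustment = 1.0 if continuity_correction else 0.0
    statistic = (abs(b - c) - adjustment) ** 2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic=float(statistic), p_value=p)


@dataclass(frozen=True)
class PairedOutcome:
    """Per-subject truth plus the verdicts of two methods (paired design)."""

    subject_id: str
    truth_abnormal: bool
    verdict_a: bool
    verdict_b: bool


def discordant_counts(
    outcomes: Iterable[PairedOutcome], *, on: str = "sensitivity"
) -> tuple[int, int]:
    """(b, c): subjects correct under A only / under B only.

    ``on`` restricts to truth-abnormal subjects ("sensitivity") or
    truth-normal subjects ("specificity").
    """
    if on not in ("sensitivity", "specificity"):
        raise ValidationError("on must be 'sensitivity' or 'specificity'")
    want_abnormal = on == "sensitivity"
    b = c = 0
    for outcome in outcomes:
        if outcome.truth_abnormal != want_abnormal:
            continue
        correct_a = outcome.verdict_a == outcome.truth_abnormal
        correct_b = outcome.verdict_b == outcome.truth_abnormal
        if correct_a and not correct_b:
            b += 1
        elif correct_b and not correct_a:
            c += 1
    return b, c


# ---------------------------------------------------------------------------
# scan-level ROC score
# ---------------------------------------------------------------------------


def scan_score(records: Iterable[SBRRecord], rule: str) -> float:
    """One continuous score per scan: the minimum SBR over the rule's regions.

    The most-affected side drives the diagnosis, so the minimum is the
    natural scan-level score (lower = more abnormal).
    """
    if rule not in RULES:
        raise ValidationError(f"unknown classification rule {rule!r}")
    by_region = {(r.side, r.structure): r for r in records}
    if rule == "southampton_striatal":
        keys = [key for key in by_region if key[1] == "striatum"]
        if not keys:
            raise EvaluationError(f"rule {rule!r}: no striatal records")
    else:
        keys = list(RULES[rule])
        missing = [key for key in keys if key not in by_region]
        if missing:
            raise EvaluationError(f"rule {rule!r}: missing records for {missing}")
    return min(by_region[key].value for key in keys)
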