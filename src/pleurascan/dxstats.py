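"""Diagnostic-accuracy evaluation machinery.

Covers the full reader-study workflow: unanimity-based consensus
adjudication with an ACEP image-quality gate, 2x2 confusion matrices with
an explicit policy for algorithm-indeterminate calls, test characteristics
(sensitivity, specificity, PPV, NPV) with exact Clopper-Pearson 95%
confidence intervals, Cohen's kappa with a large-sample CI and the
conventional agreement bands (0.40-0.75 fair to good, > 0.75 excellent),
and reports stratified by image quality, imaging mode, or transducer.

Conventions: "positive" means pneumothorax. Proportions with a zero
denominator are reported as explicitly undefined (``None``), never as 0.
Percentages round half away from zero to integer percent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .errors import (
    SingleRaterError,
    UndefinedKappaError,
    UnknownStratumError,
    UnmatchedExamsError,
)
from .imaging import INDETERMINATE, NEGATIVE, POSITIVE, RatingRecord

STRATA = ("quality", "mode", "transducer")
INDETERMINATE_POLICIES = ("exclude", "as_error")


def round_percent(x: float) -> int:
    """Round a proportion to integer percent, half away from zero."""
    return int(math.floor(100.0 * x + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Proportion:
    """A binomial proportion with its exact confidence interval."""

    point: float
    lower: float
    upper: float
    k: int
    n: int

    def as_percent(self) -> tuple[int, int, int]:
        return (
            round_percent(self.point),
            round_percent(self.lower),
            round_percent(self.upper),
        )


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity/PPV/NPV; ``None`` marks an undefined entry."""

    sensitivity: Optional[Proportion]
    specificity: Optional[Proportion]
    ppv: Optional[Proportion]
    npv: Optional[Proportion]
    level: float = 0.95

    def as_dict(self) -> dict:
        out: dict = {"level": self.level}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            p: Optional[Proportion] = getattr(self, name)
            out[name] = (
                None
                if p is None
                else {
                    "point": p.point,
                    "lower": p.lower,
                    "upper": p.upper,
                    "k": p.k,
                    "n": p.n,
                }
            )
        return out


@dataclass(frozen=True)
class ExamAdjudication:
    exam_id: str
    included: bool
    consensus_label: Optional[str] = None
    excluded_reason: Optional[str] = None  # "non_unanimous" | "quality_below_3"
    median_quality: Optional[float] = None


@dataclass(frozen=True)
class AdjudicationResult:
    exams: tuple[ExamAdjudication, ...]

    @property
    def included(self) -> list[ExamAdjudication]:
        return [e for e in self.exams if e.included]

    @property
    def excluded(self) -> list[ExamAdjudication]:
        return [e for e in self.exams if not e.included]

    def consensus_labels(self) -> dict[str, str]:
        return {e.exam_id: e.consensus_label for e in self.included}


def adjudicate(
    ratings: Iterable[RatingRecord], quality_rule: bool = True
) -> AdjudicationResult:
    """Consensus adjudication of a multi-rater ratings table.

    An exam is included when every rater gives the same label and, under
    the quality rule, the median rater quality score is at least 3 (scores
    of 1-2 on the ACEP scale are deemed non-diagnostic). Non-unanimous
    exams are flagged for plenary review, not resolved here. Each exam
    needs at least two raters.
    """
    by_exam: dict[str, list[RatingRecord]] = {}
    for rec in ratings:
        by_exam.setdefault(rec.exam_id, []).append(rec)
    out = []
    for exam_id in sorted(by_exam):
        recs = by_exam[exam_id]
        if len(recs) < 2:
            raise SingleRaterError(f"exam {exam_id} has only {len(recs)} rater(s)")
        qualities = [r.quality_score for r in recs if r.quality_score is not None]
        med_q = float(median(qualities)) if qualities else None
        labels = {r.label for r in recs}
        if len(labels) > 1:
            out.append(
                ExamAdjudication(
                    exam_id, False, excluded_reason="non_unanimous", median_quality=med_q
                )
            )
            continue
        if quality_rule:
            if med_q is None:
                raise SingleRaterError(
                    f"exam {exam_id}: quality rule requires quality scores"
                )
            if med_q < 3:
                out.append(
                    ExamAdjudication(
                        exam_id,
                        False,
                        excluded_reason="quality_below_3",
                        median_quality=med_q,
                    )
                )
                continue
        out.append(
            ExamAdjudication(
                exam_id, True, consensus_label=labels.pop(), median_quality=med_q
            )
        )
    return AdjudicationResult(exams=tuple(out))


def confusion(
    pred: Mapping[str, str],
    ref: Mapping[str, str],
    indeterminate_policy: str = "exclude",
) -> ConfusionMatrix:
    """Build a 2x2 matrix of predictions against a reference standard.

    Reference-indeterminate exams are always dropped. Algorithm-
    indeterminate calls follow the policy: ``exclude`` drops them,
    ``as_error`` counts them against the predictor (FN on a positive
    reference, FP on a negative one).
    """
    if indeterminate_policy not in INDETERMINATE_POLICIES:
        raise ValueError(
            f"indeterminate_policy must be one of {INDETERMINATE_POLICIES}"
        )
    ref_kept = {e: l for e, l in ref.items() if l != INDETERMINATE}
    pred_kept = {e: l for e, l in pred.items() if e not in ref or ref[e] != INDETERMINATE}
    if set(pred_kept) != set(ref_kept):
        missing = set(ref_kept) ^ set(pred_kept)
        raise UnmatchedExamsError(
            f"prediction/reference exam sets differ on {sorted(missing)[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    tp = fp = tn = fn = 0
    for exam_id, truth in ref_kept.items():
        p = pred_kept[exam_id]
        if p == INDETERMINATE:
            if indeterminate_policy == "exclude":
                continue
            p = NEGATIVE if truth == POSITIVE else POSITIVE
        if truth == POSITIVE:
            tp, fn = (tp + 1, fn) if p == POSITIVE else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == NEGATIVE else (tn, fp + 1)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion.

    Computed from the beta-quantile form of the binomial tail inversion;
    the lower bound is exactly 0 when k = 0 and the upper exactly 1 when
    k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in 0..n; got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def _proportion(k: int, n: int, level: float) -> Optional[Proportion]:
    if n == 0:
        return None
    lower, upper = exact_binomial_ci(k, n, level)
    return Proportion(point=k / n, lower=lower, upper=upper, k=k, n=n)


def characteristics(cm: ConfusionMatrix, level: float = 0.95) -> TestCharacteristics:
    """Sensitivity, specificity, PPV and NPV with exact CIs.

    Zero-denominator entries come back as ``None`` — undefined, never 0.
    """
    return TestCharacteristics(
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn, level),
        specificity=_proportion(cm.tn, cm.tn + cm.fp, level),
        ppv=_proportion(cm.tp, cm.tp + cm.fp, level),
        npv=_proportion(cm.tn, cm.tn + cm.fn, level),
        level=level,
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    lower: float
    upper: float
    observed_agreement: float
    expected_agreement: float
    band: str
    n: int


def kappa_band(kappa: float) -> str:
    """Conventional interpretation bands for Cohen's kappa."""
    if kappa > 0.75:
        return "excellent"
    if kappa >= 0.40:
        return "fair to good"
    return "poor"


def cohen_kappa(
    rater_a: Sequence[str], rater_b: Sequence[str], level: float = 0.95
) -> KappaResult:
    """Cohen's kappa between two raters with a large-sample CI.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from marginal
    products; computed in integer arithmetic so simple tables come out
    exact. The CI uses the large-sample standard error
    sqrt(p_o (1 - p_o) / n) / (1 - p_e), clipped to [-1, 1].
    """
    if len(rater_a) != len(rater_b):
        raise ValueError("rater label lists must have equal length")
    n = len(rater_a)
    if n == 0:
        raise ValueError("rater label lists must be non-empty")
    agree = sum(1 for x, y in zip(rater_a, rater_b) if x == y)
    marg_a = Counter(rater_a)
    marg_b = Counter(rater_b)
    cats = set(marg_a) | set(marg_b)
    expected_sum = sum(marg_a[c] * marg_b[c] for c in cats)  # n^2 * p_e
    denom = n * n - expected_sum  # n^2 * (1 - p_e)
    if denom == 0:
        raise UndefinedKappaError(
            "expected agreement is 1 (constant raters with identical marginals)"
        )
    kappa = (n * agree - expected_sum) / denom
    p_o = agree / n
    p_e = expected_sum / (n * n)
    se = math.sqrt(p_o * (1.0 - p_o) / n) / (1.0 - p_e)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return KappaResult(
        kappa=kappa,
        lower=max(-1.0, kappa - z * se),
        upper=min(1.0, kappa + z * se),
        observed_agreement=p_o,
        expected_agreement=p_e,
        band=kappa_band(kappa),
        n=n,
    )


@dataclass(frozen=True)
class StratumResult:
    confusion: ConfusionMatrix
    characteristics: TestCharacteristics


def _meta_field(meta, name: str):
    if isinstance(meta, Mapping):
        return meta.get(name)
    return getattr(meta, name, None)


_STRATUM_FIELDS = {
    "quality": "quality_score",
    "mode": "mode",
    "transducer": "transducer",
}


def stratified_report(
    pred: Mapping[str, str],
    ref: Mapping[str, str],
    metadata: Mapping[str, object],
    strata: Sequence[str] = STRATA,
    indeterminate_policy: str = "exclude",
    level: float = 0.95,
) -> dict:
    """Overall plus per-stratum confusion matrices and test characteristics.

    ``metadata`` maps exam_id to an :class:`~pleurascan.imaging.ExamMetadata`
    (or a dict with the same field names). Strata with zero denominators are
    reported with undefined entries, never dropped. Stratum matrices over a
    partition sum cell-wise to the overall matrix.
    """
    for s in strata:
        if s not in _STRATUM_FIELDS:
            raise UnknownStratumError(f"unknown stratum {s!r}; expected {STRATA}")
    overall_cm = confusion(pred, ref, indeterminate_policy)
    report: dict = {
        "overall": StratumResult(overall_cm, characteristics(overall_cm, level)),
        "strata": {},
    }
    for s in strata:
        field_name = _STRATUM_FIELDS[s]
        levels: dict[object, dict[str, str]] = {}
        for exam_id in ref:
            value = _meta_field(metadata.get(exam_id), field_name)
            levels.setdefault(value, {})[exam_id] = ref[exam_id]
        per_level = {}
        for value in sorted(levels, key=lambda v: (v is None, str(v))):
            sub_ref = levels[value]
            sub_pred = {e: pred[e] for e in sub_ref if e in pred}
            cm = confusion(sub_pred, sub_ref, indeterminate_policy)
            per_level[value] = StratumResult(cm, characteristics(cm, level))
        report["strata"][s] = per_level
    return report


def report_to_dict(report: dict) -> dict:
    """JSON-serializable form of a stratified report."""

    def entry(sr: StratumResult) -> dict:
        cm = sr.confusion
        return {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "characteristics": sr.characteristics.as_dict(),
        }

    return {
        "overall": entry(report["overall"]),
        "strata": {
            s: {str(level): entry(sr) for level, sr in per_level.items()}
            for s, per_level in report["strata"].items()
        },
    }


def report_to_rows(report: dict) -> list[dict]:
    """Flat rows (one per stratum level and statistic) for CSV export."""
    rows = []

    def emit(stratum: str, level_value, sr: StratumResult) -> None:
        for stat in ("sensitivity", "specificity", "ppv", "npv"):
            p: Optional[Proportion] = getattr(sr.characteristics, stat)
            rows.append(
                {
                    "stratum": stratum,
                    "level": level_value,
                    "statistic": stat,
                    "value": None if p is None else p.point,
                    "lower": None if p is None else p.lower,
                    "upper": None if p is None else p.upper,
                    "k": None if p is None else p.k,
                    "n": None if p is None else p.n,
                }
            )

    emit("overall", "", report["overall"])
    for s, per_level in report["strata"].items():
        for level_value, sr in per_level.items():
            emit(s, level_value, sr)
    return rows
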