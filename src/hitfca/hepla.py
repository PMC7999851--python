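"""The heparin-induced platelet activation index and its interpretation.

One assay run is four tubes read on the same donor platelet-rich plasma
(PRP): NEG (donor platelets alone, baseline), POS (platelets + TRAP
agonist, maximal activation), and the patient tubes H0.3 and H100
(therapeutic 0.3 IU/mL and inhibitory 100 IU/mL heparin). The index

    %HEPLA = 100 * (%H0.3 - %H100) / (%POS - %NEG)

expresses heparin-dependent activation as a fraction of the donor
platelets' activation potential: pathogenic anti-PF4/heparin antibodies
activate at the therapeutic dose but not at the inhibitory dose, so the
numerator grows with antibody pathogenicity while the denominator
normalises donor-to-donor reactivity.

Interpretation follows a three-way decision rule: %HEPLA above 13% is
positive; below 9.6% it is negative unless %H100 exceeds 23% — a high
%H100 means activation was not heparin-inhibitable, so the low index is
untrustworthy and the run is indeterminate; the 9.6-13% band is a gray
zone (indeterminate). Indeterminate first-round runs are repeated with
new PRPs; persistent indeterminacy is inconclusive. Across PRPs the
"believe the positive" rule applies: donor platelets may simply be
unresponsive (low-affinity FcgRIIA variant, ~25% of unselected donors),
so a single positive PRP outweighs negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .activation import TubeActivation
from .errors import DataError, ParameterError

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"

VERDICT_REPEAT = "indeterminate_repeat_required"
VERDICT_INCONCLUSIVE = "inconclusive"

ROUND_INITIAL = "initial"
ROUND_REPEAT = "repeat"

_RUN_ROLES = ("NEG", "POS", "H03", "H100")


@dataclass(frozen=True)
class ReferenceLimits:
    """All decision constants, in percent activation / percent index.

    Defaults are the assay's published reference values: PRP validity
    limits from 25 healthy-donor batches (mean +/- 2 SD of %NEG, mean
    - 2 SD of %POS), the %HEPLA decision thresholds, the high-%H100 rule,
    control qualification ranges, CV acceptability bounds, and the 3-hour
    PRP freshness window.
    """

    neg_low: float = 2.9
    neg_high: float = 19.3
    pos_low: float = 84.9
    hepla_negative: float = 9.6
    hepla_positive: float = 13.0
    h100_high: float = 23.0
    qch_min: float = 50.0
    qcm_range: tuple[float, float] = (13.0, 50.0)
    qcb_max: float = 9.6
    cv_desired: float = 10.0
    cv_max: float = 25.0
    max_prp_age_min: float = 180.0

    def __post_init__(self) -> None:
        if not (self.neg_low < self.neg_high < self.pos_low):
            raise ParameterError("require neg_low < neg_high < pos_low")
        if not (self.hepla_negative < self.hepla_positive):
            raise ParameterError("require hepla_negative < hepla_positive")
        for name in ("neg_low", "neg_high", "pos_low", "hepla_negative",
                     "hepla_positive", "h100_high", "qch_min", "qcb_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ParameterError(f"{name} = {v} outside [0, 100]")


@dataclass
class AssayRun:
    """Four tube activations from one patient sample on one PRP."""

    tubes: dict[str, TubeActivation]
    prp_prepared_at: datetime | None = None
    measured_at: datetime | None = None
    prp_id: str = "PRP-1"
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        missing = [r for r in _RUN_ROLES if r not in self.tubes]
        extra = [r for r in self.tubes if r not in _RUN_ROLES]
        if missing or extra:
            raise DataError(f"run must hold exactly {_RUN_ROLES}; missing={missing} extra={extra}")

    def pct(self, role: str) -> float:
        return self.tubes[role].percent_activated

    @property
    def age_minutes(self) -> float | None:
        if self.prp_prepared_at is None or self.measured_at is None:
            return None
        return (self.measured_at - self.prp_prepared_at).total_seconds() / 60.0


@dataclass
class HeplaResult:
    """Per-run percentages, the index, PRP validity and interpretation."""

    pct_neg: float
    pct_pos: float
    pct_h03: float
    pct_h100: float
    hepla: float
    prp_valid: bool = True
    validity_reasons: list[str] = field(default_factory=list)
    interpretation: str | None = None
    h100_high_flag: bool = False
    prp_id: str = "PRP-1"
    sample_id: str = "sample"


@dataclass
class FinalResult:
    """Aggregation of one or more PRP results into a final call."""

    results: list[HeplaResult]
    verdict: str
    round: str


def compute_hepla(run: AssayRun) -> float:
    """Evaluate the index; negative values are preserved, not clamped."""
    neg, pos = run.pct("NEG"), run.pct("POS")
    if pos <= neg:
        raise DataError(
            f"%POS ({pos:.1f}) must exceed %NEG ({neg:.1f}); PRP unusable for the index"
        )
    return 100.0 * (run.pct("H03") - run.pct("H100")) / (pos - neg)


def check_stability(run: AssayRun, limits: ReferenceLimits | None = None) -> dict:
    """PRP freshness: measured within the 3-hour window (boundary passes)."""
    limits = limits or ReferenceLimits()
    age = run.age_minutes
    if age is None:
        return {"status": "warn", "reason": "PRP age unknown (missing timestamps)"}
    status = "pass" if age <= limits.max_prp_age_min else "fail"
    return {"status": status, "age_minutes": age}


def validate_prp(run: AssayRun, limits: ReferenceLimits | None = None) -> tuple[bool, list[str]]:
    """Check the NEG/POS controls and PRP age against the reference limits.

    Each violated rule is named: platelets reacting below the NEG floor
    are "poorly reactive", above the NEG ceiling "over-reactive" (often
    excessive handling), a POS below its floor is a "weak positive
    response", and an out-of-window PRP is "stale PRP".
    """
    limits = limits or ReferenceLimits()
    reasons = []
    neg, pos = run.pct("NEG"), run.pct("POS")
    if neg < limits.neg_low:
        reasons.append(f"poorly reactive donor platelets (%NEG {neg:.1f} < {limits.neg_low})")
    if neg > limits.neg_high:
        reasons.append(f"over-reactive donor platelets (%NEG {neg:.1f} > {limits.neg_high})")
    if pos < limits.pos_low:
        reasons.append(f"weak positive response (%POS {pos:.1f} < {limits.pos_low})")
    stab = check_stability(run, limits)
    if stab["status"] == "fail":
        reasons.append(f"stale PRP (age {stab['age_minutes']:.0f} min > {limits.max_prp_age_min:.0f} min)")
    return (not reasons, reasons)


def classify(hepla: float, pct_h100: float, limits: ReferenceLimits | None = None) -> tuple[str, bool]:
    """Three-way decision on (%HEPLA, %H100); returns (interpretation, h100 flag).

    The flag marks an elevated %H100 in any non-positive outcome; it
    changes the verdict only in the low-%HEPLA branch.
    """
    limits = limits or ReferenceLimits()
    if not np.isfinite(hepla):
        raise ParameterError("hepla must be finite")
    h100_high = pct_h100 > limits.h100_high
    if hepla > limits.hepla_positive:
        return POSITIVE, False
    if hepla < limits.hepla_negative:
        return (INDETERMINATE, True) if h100_high else (NEGATIVE, False)
    return INDETERMINATE, h100_high  # gray zone, boundaries inclusive


def interpret(h: HeplaResult, limits: ReferenceLimits | None = None) -> str:
    """Interpret a run; refuses invalid PRPs, naming the validity reasons."""
    if not h.prp_valid:
        raise DataError("interpretation refused, PRP invalid: " + "; ".join(h.validity_reasons))
    interpretation, flag = classify(h.hepla, h.pct_h100, limits)
    h.interpretation = interpretation
    h.h100_high_flag = flag
    return interpretation


def evaluate_run(run: AssayRun, limits: ReferenceLimits | None = None) -> HeplaResult:
    """Index + validity + interpretation for one run, in one structure.

    An invalid PRP yields a result whose interpretation is None and whose
    reasons name the violated rules; it does not raise.
    """
    limits = limits or ReferenceLimits()
    valid, reasons = validate_prp(run, limits)
    res = HeplaResult(
        pct_neg=run.pct("NEG"),
        pct_pos=run.pct("POS"),
        pct_h03=run.pct("H03"),
        pct_h100=run.pct("H100"),
        hepla=float("nan"),
        prp_valid=valid,
        validity_reasons=reasons,
        prp_id=run.prp_id,
        sample_id=run.sample_id,
    )
    if not valid:
        return res
    res.hepla = compute_hepla(run)
    interpret(res, limits)
    return res


def aggregate(results: list[HeplaResult], round: str = ROUND_INITIAL) -> FinalResult:
    """Combine per-PRP interpretations under "believe the positive".

    Any positive PRP makes the final call positive; unanimous negatives
    are negative; otherwise the run set is indeterminate — repeat with new
    PRPs on the initial round, inconclusive after a repeat round.
    """
    if round not in (ROUND_INITIAL, ROUND_REPEAT):
        raise ParameterError(f"unknown round {round!r}")
    usable = [r for r in results if r.prp_valid and r.interpretation is not None]
    if not usable:
        raise DataError("no valid, interpreted PRP results to aggregate")
    calls = {r.interpretation for r in usable}
    if POSITIVE in calls:
        verdict = POSITIVE
    elif calls == {NEGATIVE}:
        verdict = NEGATIVE
    else:
        verdict = VERDICT_REPEAT if round == ROUND_INITIAL else VERDICT_INCONCLUSIVE
    return FinalResult(results=list(results), verdict=verdict, round=round)
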