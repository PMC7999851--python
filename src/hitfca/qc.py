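"""Batch statistics, control qualification and reference-limit derivation.

Assay precision is tracked with three control sera: QCH (high,
%HEPLA >= 50), QCM (medium, 13 < %HEPLA < 50) and QCB (blank,
%HEPLA < 9.6). Repeatability (one operator, one day) and reproducibility
(several operators, independent days) series are summarised as
mean / SD / %CV; a CV of 10% is desired and up to 25% acceptable for QCH
and QCM, while QCB's CV is reported but never gated — near-zero means
inflate the ratio and the spread there expresses donor variability.

PRP validity limits derive from a batch series of healthy-donor controls:
mean +/- 2 SD of the NEG activations and mean - 2 SD of the POS
activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .hepla import ReferenceLimits

QCH = "QCH"
QCM = "QCM"
QCB = "QCB"
CONTROL_LEVELS = (QCH, QCM, QCB)


@dataclass(frozen=True)
class BatchStats:
    """n, mean, sample SD and %CV of a batch of index values (percent)."""

    n: int
    mean: float
    sd: float | None
    cv: float | None

    def rounded(self, ndigits: int = 1) -> "BatchStats":
        """Reporting convention: one decimal; computation stays full precision."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return BatchStats(n=self.n, mean=round(self.mean, ndigits), sd=rnd(self.sd), cv=rnd(self.cv))


def batch_stats(values) -> BatchStats:
    """Arithmetic mean, sample (n-1) SD and %CV = 100 * SD / mean."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise DataError("batch statistics need a non-empty, finite series")
    mean = float(x.mean())
    if x.size < 2:
        return BatchStats(n=1, mean=mean, sd=None, cv=None)
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else None
    return BatchStats(n=int(x.size), mean=mean, sd=sd, cv=cv)


def cv_from_summary(mean: float, sd: float) -> float:
    """%CV from an already-summarised (mean, SD) pair."""
    if mean <= 0:
        raise DataError("CV undefined for non-positive mean")
    return 100.0 * sd / mean


def qualify_control(hepla: float, level: str, limits: ReferenceLimits | None = None) -> bool:
    """Does a control run's %HEPLA fall in its level's qualification range?"""
    limits = limits or ReferenceLimits()
    if level == QCH:
        return hepla >= limits.qch_min
    if level == QCM:
        lo, hi = limits.qcm_range
        return lo < hepla < hi
    if level == QCB:
        return hepla < limits.qcb_max
    raise ParameterError(f"unknown control level {level!r}")


def cv_acceptability(stats: BatchStats, level: str, limits: ReferenceLimits | None = None) -> str:
    """pass (cv <= 10), warn (<= 25), fail (> 25); QCB is always exempt."""
    limits = limits or ReferenceLimits()
    if level == QCB:
        return "exempt"
    if level not in (QCH, QCM):
        raise ParameterError(f"unknown control level {level!r}")
    if stats.cv is None:
        raise DataError("CV is undefined for this batch")
    if stats.cv <= limits.cv_desired:
        return "pass"
    if stats.cv <= limits.cv_max:
        return "warn"
    return "fail"


def derive_reference_limits(
    neg_series, pos_series, recommended_batches: int = 20
) -> tuple[dict, list[str]]:
    """PRP validity limits from NEG/POS batch series of % activation.

    Returns ``{"neg_low", "neg_high", "pos_low"}`` as mean -/+ 2 sample
    SDs of the NEG series and mean - 2 SD of the POS series, plus any
    warnings (short series, degenerate zero-spread series).
    """
    neg = np.asarray(list(neg_series), dtype=float)
    pos = np.asarray(list(pos_series), dtype=float)
    warnings = []
    for name, x in (("NEG", neg), ("POS", pos)):
        if x.size < 2:
            raise DataError(f"{name} series needs >= 2 batches")
        if not np.all(np.isfinite(x)):
            raise DataError(f"{name} series contains non-finite values")
        if x.std(ddof=1) == 0:
            warnings.append(f"{name} series is constant; limits are degenerate (zero width)")
    if min(neg.size, pos.size) < recommended_batches:
        warnings.append(
            f"only {min(neg.size, pos.size)} batches; >= {recommended_batches} recommended"
        )
    neg_mean, neg_sd = float(neg.mean()), float(neg.std(ddof=1))
    pos_mean, pos_sd = float(pos.mean()), float(pos.std(ddof=1))
    limits = {
        "neg_low": neg_mean - 2.0 * neg_sd,
        "neg_high": neg_mean + 2.0 * neg_sd,
        "pos_low": pos_mean - 2.0 * pos_sd,
    }
    return limits, warnings
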