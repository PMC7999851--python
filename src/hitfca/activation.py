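"""Activation cutoff on log-FL1 and per-tube percent activation.

The FL1 (FITC / anti-CD62p) signal separates resting from activated
platelets. The analytical cutoff is placed at the crossing point of the
NEG-tube and POS-tube log-FL1 densities — the point where an event is
equally likely under the resting and the fully activated distribution, so
total misclassification of the two controls is minimised. The historical
alternative, mean + 2 SD of the NEG tube, is kept as ``legacy_cutoff``.
A tube's activation is the percentage of CD41+ platelets whose log-FL1
lies strictly beyond the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import CutoffError, DataError, StateError
from .gating import GateResult
from .io import EventTable

#: minimum gated events behind a density curve or a legacy cutoff
MIN_DENSITY_EVENTS = 100
#: grid resolution for density curves
GRID_SIZE = 512
#: grid padding beyond the data range, in bandwidths, so the curve
#: integrates to ~1
GRID_PAD_BW = 4.0

INTERSECTION = "intersection"
LEGACY = "legacy_mean2sd"


@dataclass
class DensityCurve:
    """A kernel density of gated log-FL1 values on an ordered grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise DataError("grid and density must be 1-D and congruent")
        if np.any(np.diff(self.grid) <= 0):
            raise DataError("density grid must be strictly increasing")
        if np.any(self.density < 0):
            raise DataError("density values must be non-negative")
        area = float(np.trapezoid(self.density, self.grid))
        if not (0.99 <= area <= 1.01):
            raise DataError(f"density integrates to {area:.4f}, outside [0.99, 1.01]")

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class ActivationCutoff:
    """A log-FL1 activation threshold and the method that produced it."""

    value: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise CutoffError(f"cutoff value must be finite, got {self.value}")


@dataclass
class TubeActivation:
    """Percent of gated (CD41+) events beyond the activation cutoff."""

    tube_role: str
    percent_activated: float
    n_events: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_activated <= 100.0:
            raise DataError("percent_activated must lie in [0, 100]")


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^{-1/5}."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise DataError("cannot choose a bandwidth for a zero-spread sample")
    return float(0.9 * scale * x.size ** (-1 / 5))


def _gated_fl1(t: EventTable, gate: GateResult) -> np.ndarray:
    if not t.is_log("FL1"):
        raise StateError("FL1 must be log-scaled before density estimation")
    return t.column("FL1")[gate.mask]


def density_on_log_fl1(
    t: EventTable,
    gate: GateResult,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> DensityCurve:
    """Gaussian-kernel density of gated log-FL1 on a padded grid."""
    x = _gated_fl1(t, gate)
    if x.size < MIN_DENSITY_EVENTS:
        raise DataError(f"density needs >= {MIN_DENSITY_EVENTS} gated events, got {x.size}")
    h = float(bandwidth) if bandwidth is not None else silverman_bandwidth(x)
    if h <= 0:
        raise DataError("bandwidth must be positive")
    kde = gaussian_kde(x, bw_method=h / x.std(ddof=1))
    if grid is None:
        grid = np.linspace(x.min() - GRID_PAD_BW * h, x.max() + GRID_PAD_BW * h, GRID_SIZE)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h, n=int(x.size))


def paired_densities(
    neg_t: EventTable,
    neg_gate: GateResult,
    pos_t: EventTable,
    pos_gate: GateResult,
    bandwidth: float | None = None,
) -> tuple[DensityCurve, DensityCurve]:
    """NEG and POS densities on a shared grid with a shared bandwidth.

    A shared bandwidth (mean of the two Silverman choices unless given)
    keeps the crossing point well defined.
    """
    xn, xp = _gated_fl1(neg_t, neg_gate), _gated_fl1(pos_t, pos_gate)
    for x in (xn, xp):
        if x.size < MIN_DENSITY_EVENTS:
            raise DataError(f"density needs >= {MIN_DENSITY_EVENTS} gated events, got {x.size}")
    h = float(bandwidth) if bandwidth is not None else 0.5 * (silverman_bandwidth(xn) + silverman_bandwidth(xp))
    lo = min(xn.min(), xp.min()) - GRID_PAD_BW * h
    hi = max(xn.max(), xp.max()) + GRID_PAD_BW * h
    grid = np.linspace(lo, hi, GRID_SIZE)
    return (
        density_on_log_fl1(neg_t, neg_gate, bandwidth=h, grid=grid),
        density_on_log_fl1(pos_t, pos_gate, bandwidth=h, grid=grid),
    )


def _misclassification(neg: DensityCurve, pos: DensityCurve, cutoff: float) -> float:
    """NEG mass above the cutoff plus POS mass below it."""
    grid = neg.grid
    above = grid >= cutoff
    ga = np.concatenate(([cutoff], grid[above]))
    na = np.concatenate(([np.interp(cutoff, grid, neg.density)], neg.density[above]))
    below = grid <= cutoff
    gb = np.concatenate((grid[below], [cutoff]))
    pb = np.concatenate((pos.density[below], [np.interp(cutoff, grid, pos.density)]))
    return float(np.trapezoid(na, ga) + np.trapezoid(pb, gb))


def intersection_cutoff(neg: DensityCurve, pos: DensityCurve) -> ActivationCutoff:
    """Place the cutoff where the NEG and POS densities cross.

    Only crossings strictly between the NEG mode and the POS mode count;
    with several, the one minimising total NEG/POS misclassification mass
    wins. Crossings are localised by linear interpolation between grid
    points. No crossing (or a NEG mode at/above the POS mode) means the
    PRP gave unusable control histograms.
    """
    if neg.grid.shape != pos.grid.shape or not np.allclose(neg.grid, pos.grid):
        raise DataError("NEG and POS densities must share a common grid")
    m_neg, m_pos = neg.mode, pos.mode
    if m_neg >= m_pos:
        raise CutoffError(
            f"NEG mode ({m_neg:.3f}) is not below POS mode ({m_pos:.3f}); PRP unusable"
        )
    grid = neg.grid
    diff = neg.density - pos.density
    inside = (grid > m_neg) & (grid < m_pos)
    idx = np.nonzero(inside[:-1] & (np.sign(diff[:-1]) * np.sign(diff[1:]) < 0))[0]
    crossings = []
    for i in idx:
        # linear interpolation of the sign change in diff
        x0, x1, d0, d1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        crossings.append(float(x0 - d0 * (x1 - x0) / (d1 - d0)))
    # exact zeros on grid points
    zero = np.nonzero(inside & (diff == 0))[0]
    crossings.extend(float(grid[i]) for i in zero)
    crossings = sorted(set(c for c in crossings if m_neg < c < m_pos))
    if not crossings:
        raise CutoffError("NEG and POS densities do not cross between their modes; PRP unusable")
    best = min(crossings, key=lambda c: _misclassification(neg, pos, c))
    return ActivationCutoff(
        value=best,
        method=INTERSECTION,
        diagnostics={"n_crossings": len(crossings), "neg_mode": m_neg, "pos_mode": m_pos},
    )


def legacy_cutoff(neg_t: EventTable, gate: GateResult) -> ActivationCutoff:
    """Historical cutoff: mean + 2 sample SDs of the NEG tube's log-FL1."""
    x = _gated_fl1(neg_t, gate)
    if x.size < MIN_DENSITY_EVENTS:
        raise DataError(f"legacy cutoff needs >= {MIN_DENSITY_EVENTS} gated events, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return ActivationCutoff(
        value=mean + 2.0 * sd,
        method=LEGACY,
        diagnostics={"neg_mean": mean, "neg_sd": sd},
    )


def percent_activation(t: EventTable, gate: GateResult, c: ActivationCutoff) -> TubeActivation:
    """Percentage of gated events with log-FL1 strictly beyond the cutoff."""
    if not t.is_log("FL1"):
        raise StateError("FL1 must be log-scaled before counting activation")
    x = t.column("FL1")[gate.mask]
    if x.size == 0:
        raise DataError("no gated events to classify")
    pct = 100.0 * float(np.count_nonzero(x > c.value)) / x.size
    return TubeActivation(tube_role=t.tube_role, percent_activated=pct, n_events=int(x.size))
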