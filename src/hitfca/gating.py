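"""Platelet identification per tube.

Two nested gates reproduce the standard manual strategy on automated,
deterministic rules: a robust scatter gate on the log FSC / log SSC plane
(platelets are a compact log-normal cloud; debris and other cells fall
outside), then a CD41+ gate on the log-FL2 (PE) histogram, placed at the
deepest density valley between the two largest modes, separating
CD41-bright platelets from CD41-dim debris. An acquisition-count check
mirrors the convention of acquiring 10,000 events in the CD41+ gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .errors import DataError, StateError
from .io import EventTable

#: minimum events for a meaningful scatter gate
MIN_SCATTER_EVENTS = 50
#: default robust-spread multiplier for the scatter gate
DEFAULT_SCATTER_K = 3.0
#: a secondary scatter mode holding at least this fraction of events
#: outside the gate marks the population as non-unique
DEFAULT_SECONDARY_FRACTION = 0.10
#: default acquisition target in the CD41+ gate
DEFAULT_MIN_EVENTS = 10_000
#: KDE grid resolution for the FL2 valley search
FL2_GRID_SIZE = 512
#: a local FL2 density maximum counts as a mode only if its peak reaches
#: this fraction of the global maximum; smaller bumps are tail noise
FL2_MODE_MIN_HEIGHT = 0.02

_MAD_TO_SD = 1.4826  # consistent with a normal distribution


@dataclass
class GateResult:
    """Membership mask over the parent table's events plus gate diagnostics."""

    mask: np.ndarray
    n_total: int
    threshold_fl2: float | None = None
    unique_population: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_total,):
            raise DataError("gate mask length does not match event count")

    @property
    def n_in(self) -> int:
        return int(self.mask.sum())


def _require_log(t: EventTable, channels: tuple[str, ...]) -> None:
    not_log = [ch for ch in channels if not t.is_log(ch)]
    if not_log:
        raise StateError(f"channels must be log-scaled first: {not_log}")


def gate_platelet_scatter(t: EventTable, k: float = DEFAULT_SCATTER_K,
                          secondary_fraction: float = DEFAULT_SECONDARY_FRACTION) -> GateResult:
    """Retain events within median +/- k * robust SD on each scatter axis.

    The robust SD is 1.4826 * MAD, so for a single Gaussian population the
    gate at k = 3 keeps essentially everything. When at least
    ``secondary_fraction`` of events fall outside the gate, a secondary
    scatter population is assumed present and the result is flagged
    non-unique.
    """
    _require_log(t, ("FSC", "SSC"))
    if t.n_events < MIN_SCATTER_EVENTS:
        raise DataError(f"scatter gate needs >= {MIN_SCATTER_EVENTS} events, got {t.n_events}")
    mask = np.ones(t.n_events, dtype=bool)
    for ch in ("FSC", "SSC"):
        x = t.column(ch)
        med = np.median(x)
        spread = _MAD_TO_SD * np.median(np.abs(x - med))
        if spread == 0:
            continue  # degenerate axis: all events identical, keep all
        mask &= np.abs(x - med) <= k * spread
    outside = 1.0 - mask.mean()
    unique = outside < secondary_fraction
    flags = [] if unique else [f"secondary scatter population ({outside:.1%} of events outside gate)"]
    return GateResult(mask=mask, n_total=t.n_events, unique_population=unique, flags=flags)


def gate_cd41_positive(t: EventTable, prior: GateResult) -> GateResult:
    """Gate CD41+ platelets on the log-FL2 density within the scatter gate.

    The threshold is the deepest density minimum between the two largest
    modes of a Gaussian-kernel density (Silverman bandwidth, 512-point
    grid over the data range). A unimodal density means no debris
    population is resolvable: all prior-gated events are kept and the
    result flagged.
    """
    _require_log(t, ("FL2",))
    if prior.n_in == 0:
        raise DataError("no events in the prior scatter gate")
    fl2 = t.column("FL2")[prior.mask]
    mask = prior.mask.copy()
    if np.ptp(fl2) == 0:
        return GateResult(mask=mask, n_total=t.n_events, unique_population=prior.unique_population,
                          flags=prior.flags + ["FL2 constant; CD41 gate skipped"])
    kde = gaussian_kde(fl2, bw_method="silverman")
    grid = np.linspace(fl2.min(), fl2.max(), FL2_GRID_SIZE)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if dens[0] > dens[1]:
        maxima = np.append(maxima, 0)
    if dens[-1] > dens[-2]:
        maxima = np.append(maxima, dens.size - 1)
    maxima = maxima[dens[maxima] >= FL2_MODE_MIN_HEIGHT * dens.max()]
    if maxima.size < 2:
        return GateResult(mask=mask, n_total=t.n_events, unique_population=prior.unique_population,
                          flags=prior.flags + ["unimodal FL2; all scatter-gated events retained"])
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    lo, hi = sorted(int(i) for i in top2)
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    threshold = float(grid[valley])
    mask &= t.column("FL2") > threshold
    return GateResult(mask=mask, n_total=t.n_events, threshold_fl2=threshold,
                      unique_population=prior.unique_population, flags=list(prior.flags))


def check_acquisition(g: GateResult, minimum: int = DEFAULT_MIN_EVENTS) -> dict:
    """Acquisition-count QC: pass iff the gate holds >= ``minimum`` events."""
    ok = g.n_in >= minimum
    out = {"status": "pass" if ok else "warn", "n_in": g.n_in, "minimum": minimum}
    if not ok:
        out["deficit"] = minimum - g.n_in
    return out
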