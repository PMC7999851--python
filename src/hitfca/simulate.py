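"""Synthetic four-tube cytometry runs with known ground truth.

Every pipeline stage is testable without instrument data: the generator
draws per-event scatter and fluorescence from log-normal components — the
standard approximation for cytometry intensities — and keeps the true
per-event labels, so recovered gate fractions and activation percentages
can be checked against what was simulated.

Each tube is a two-level mixture. An event is a platelet (default 90%)
or low-scatter CD41-dim debris; platelet FL1 (anti-CD62p, FITC) comes
from a resting or an activated component according to the tube's
activation fraction. The NEG tube sits at the donors' baseline (default
11% activated, matching the reported healthy-donor mean), the POS tube
at the TRAP-stimulated maximum (default 93%), and the two patient tubes
follow the sample phenotype. FITC<->PE spillover is applied last, so the
analysis chain has real compensation work to do.

Donor realism: a configurable fraction of donors (default 25%, the
population frequency of the low-affinity FcgRIIA variant) are low
responders whose platelets ignore the patient's antibodies; donor-to-
donor jitter perturbs baselines in reproducibility mode; and PRP ages —
baseline activation drifts upward the longer the PRP sits before
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from .errors import DataError, ParameterError
from .io import EventTable, SpilloverMatrix

_ROLE_CODE = {"OTHER": 0, "NEG": 1, "POS": 2, "H03": 3, "H100": 4}

HIT_POSITIVE = "hit_positive"
NON_HIT = "non_hit"
HEPARIN_INDEPENDENT = "heparin_independent"
LOW_RESPONDER = "low_responder_donor"

#: population frequency of low-responder platelet donors (low-affinity
#: FcgRIIA variant)
LOW_RESPONDER_FREQUENCY = 0.25


def _default_spillover() -> SpilloverMatrix:
    # FITC spills into the PE detector far more than the reverse
    return SpilloverMatrix(channels=("FL1", "FL2"), matrix=np.array([[1.0, 0.12], [0.02, 1.0]]))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters. Location/scale pairs are log10-intensity units."""

    n_events: int = 10_000
    platelet_fraction: float = 0.9
    platelet_log_fsc: tuple[float, float] = (2.0, 0.15)
    platelet_log_ssc: tuple[float, float] = (1.7, 0.15)
    debris_log_fsc: tuple[float, float] = (1.0, 0.30)
    debris_log_ssc: tuple[float, float] = (0.7, 0.30)
    platelet_log_fl2: tuple[float, float] = (2.5, 0.25)
    debris_log_fl2: tuple[float, float] = (0.8, 0.30)
    resting_log_fl1: tuple[float, float] = (1.0, 0.30)
    activated_log_fl1: tuple[float, float] = (3.0, 0.30)
    debris_log_fl1: tuple[float, float] = (0.5, 0.30)
    neg_activation: float = 0.11
    pos_activation: float = 0.93
    spillover: SpilloverMatrix = field(default_factory=_default_spillover)
    low_responder_frequency: float = LOW_RESPONDER_FREQUENCY
    #: baseline-activation drift per hour of PRP age beyond the first hour
    drift_per_hour: float = 0.03
    prp_age_min: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("platelet_fraction", "neg_activation", "pos_activation",
                     "low_responder_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} = {v} outside [0, 1]")
        if self.resting_log_fl1[0] >= self.activated_log_fl1[0]:
            raise ParameterError("resting FL1 mode must lie below the activated FL1 mode")
        if self.n_events < 0:
            raise ParameterError("n_events must be non-negative")


@dataclass(frozen=True)
class SamplePhenotype:
    """Activation targets for the patient tubes implied by the sample kind.

    hit_positive: pathogenic antibodies — strong activation at 0.3 IU/mL
    heparin, none at 100 IU/mL. non_hit: both patient tubes at baseline.
    heparin_independent: activation that high-dose heparin does not
    inhibit (both tubes high) — the pattern that forces an indeterminate
    call. low_responder_donor: the donor's platelets do not respond, so
    H0.3 stays at baseline regardless of the sample.
    """

    kind: str
    h03_activation: float | None = None
    h100_activation: float | None = None

    _DEFAULTS = {
        HIT_POSITIVE: (0.85, None),
        NON_HIT: (None, None),
        HEPARIN_INDEPENDENT: (0.75, 0.75),
        LOW_RESPONDER: (None, None),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._DEFAULTS:
            raise ParameterError(f"unknown phenotype kind {self.kind!r}")

    def targets(self, baseline: float) -> tuple[float, float]:
        d03, d100 = self._DEFAULTS[self.kind]
        h03 = self.h03_activation if self.h03_activation is not None else d03
        h100 = self.h100_activation if self.h100_activation is not None else d100
        if self.kind == LOW_RESPONDER:
            h03 = baseline  # donor platelets ignore the sample
        return (h03 if h03 is not None else baseline,
                h100 if h100 is not None else baseline)


@dataclass
class SimulatedRun:
    """Four event tables plus the ground truth that generated them."""

    tables: dict[str, EventTable]
    truth: dict
    prp_prepared_at: datetime
    measured_at: datetime
    prp_id: str = "PRP-1"
    sample_id: str = "sample"


def _tube_rng(seed: int, role: str, stream: int = 0) -> np.random.Generator:
    # fixed per-role substreams: tube order never changes results
    return np.random.default_rng(np.random.SeedSequence([int(seed), _ROLE_CODE[role], stream]))


def _lognormal(rng: np.random.Generator, loc_sd: tuple[float, float], n: int) -> np.ndarray:
    return 10.0 ** rng.normal(loc_sd[0], loc_sd[1], size=n)


def simulate_tube(
    cfg: SimConfig,
    role: str,
    activation_fraction: float,
    seed: int | None = None,
) -> EventTable:
    """One tube: platelet/debris mixture with the given activated fraction.

    True per-event labels are kept in ``table.meta`` under
    ``"is_platelet"`` and ``"is_activated"``; spillover is applied last.
    """
    if not 0.0 <= activation_fraction <= 1.0:
        raise ParameterError(f"activation fraction {activation_fraction} outside [0, 1]")
    if role not in _ROLE_CODE:
        raise ParameterError(f"unknown tube role {role!r}")
    rng = _tube_rng(cfg.seed if seed is None else seed, role)
    n = cfg.n_events
    is_platelet = rng.random(n) < cfg.platelet_fraction
    is_activated = is_platelet & (rng.random(n) < activation_fraction)

    fsc = np.where(is_platelet, _lognormal(rng, cfg.platelet_log_fsc, n),
                   _lognormal(rng, cfg.debris_log_fsc, n))
    ssc = np.where(is_platelet, _lognormal(rng, cfg.platelet_log_ssc, n),
                   _lognormal(rng, cfg.debris_log_ssc, n))
    fl2 = np.where(is_platelet, _lognormal(rng, cfg.platelet_log_fl2, n),
                   _lognormal(rng, cfg.debris_log_fl2, n))
    fl1 = np.where(is_platelet,
                   np.where(is_activated, _lognormal(rng, cfg.activated_log_fl1, n),
                            _lognormal(rng, cfg.resting_log_fl1, n)),
                   _lognormal(rng, cfg.debris_log_fl1, n))

    # mix true fluorescence through the spillover matrix: observed = true @ S
    fluo = np.column_stack([fl1, fl2]) @ cfg.spillover.matrix
    events = np.column_stack([fsc, ssc, fluo]).astype(np.float32)
    return EventTable(
        events=events,
        channels=("FSC", "SSC", "FL1", "FL2"),
        tube_role=role,
        meta={
            "is_platelet": is_platelet,
            "is_activated": is_activated,
            "true_activation_fraction": float(activation_fraction),
        },
    )


def _effective_baselines(cfg: SimConfig, rng: np.random.Generator | None) -> tuple[float, float]:
    """Baseline/maximum activation after PRP-age drift and donor jitter."""
    drift = cfg.drift_per_hour * max(0.0, cfg.prp_age_min - 60.0) / 60.0
    neg = cfg.neg_activation + drift
    pos = cfg.pos_activation - drift
    if rng is not None:
        neg += rng.normal(0.0, 0.02)
        pos += rng.normal(0.0, 0.015)
    return float(np.clip(neg, 0.0, 1.0)), float(np.clip(pos, 0.0, 1.0))


def simulate_run(
    cfg: SimConfig,
    phenotype: SamplePhenotype,
    seed: int | None = None,
    donor_jitter: bool = False,
    prp_id: str = "PRP-1",
    sample_id: str = "sample",
) -> SimulatedRun:
    """Four tubes for one patient sample on one PRP, with ground truth."""
    seed = cfg.seed if seed is None else int(seed)
    jitter_rng = _tube_rng(seed, "OTHER", stream=1) if donor_jitter else None
    neg, pos = _effective_baselines(cfg, jitter_rng)
    h03, h100 = phenotype.targets(neg)
    fractions = {"NEG": neg, "POS": pos, "H03": h03, "H100": h100}
    tables = {role: simulate_tube(cfg, role, frac, seed=seed) for role, frac in fractions.items()}
    prepared = datetime(2021, 3, 1, 9, 0, 0)
    measured = prepared + timedelta(minutes=cfg.prp_age_min)
    for t in tables.values():
        t.acquired_at = measured
    return SimulatedRun(
        tables=tables,
        truth={"phenotype": phenotype.kind, "fractions": fractions, "seed": seed},
        prp_prepared_at=prepared,
        measured_at=measured,
        prp_id=prp_id,
        sample_id=sample_id,
    )


def low_responder_prob(k: int, p: float = LOW_RESPONDER_FREQUENCY) -> float:
    """Probability that all k independent unselected donors are low responders."""
    if k < 0:
        raise ParameterError("donor count must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ParameterError("per-donor probability must lie in [0, 1]")
    return float(p) ** int(k)


#: expected %HEPLA targets used to calibrate control-series phenotypes
CONTROL_TARGETS = {"QCH": 92.6, "QCM": 26.5, "QCB": 2.6}


def simulate_control_series(
    level: str,
    n: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
    mode: str = "repeatability",
) -> list[SimulatedRun]:
    """n control runs whose expected %HEPLA sits at the level's target.

    The patient-tube target is back-solved from the level's index target:
    h03 = baseline + target/100 * (max - baseline), h100 at baseline.
    Repeatability mode repeats the same donor (measurement noise only);
    reproducibility mode re-draws donor baselines per run.
    """
    cfg = cfg or SimConfig()
    if level not in CONTROL_TARGETS:
        raise ParameterError(f"unknown control level {level!r}")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mode not in ("repeatability", "reproducibility"):
        raise ParameterError(f"unknown mode {mode!r}")
    target = CONTROL_TARGETS[level]
    runs = []
    for i in range(n):
        run_seed = (int(seed) * 1_000 + i) % (2**31)
        jitter = mode == "reproducibility"
        jrng = _tube_rng(run_seed, "OTHER", stream=1) if jitter else None
        neg, pos = _effective_baselines(cfg, jrng)
        h03 = float(np.clip(neg + target / 100.0 * (pos - neg), 0.0, 1.0))
        pheno = SamplePhenotype(kind=HIT_POSITIVE, h03_activation=h03, h100_activation=neg)
        runs.append(
            simulate_run(cfg, pheno, seed=run_seed, donor_jitter=jitter,
                         prp_id=f"PRP-{i + 1}", sample_id=level)
        )
    return runs
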