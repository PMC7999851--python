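"""End-to-end analysis of one four-tube run.

Stage order: read -> (compensate) -> log transform -> scatter gate ->
CD41+ gate -> acquisition check -> activation cutoff (from NEG/POS) ->
percent activation per tube -> %HEPLA -> PRP validation ->
interpretation. Stage failures carry the stage name; an invalid PRP
produces a report whose interpretation is refused, not a crash.
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime
from pathlib import Path

from . import activation, gating, hepla, io
from .config import RunConfig
from .errors import HitFcaError
from .simulate import SimulatedRun

RUN_ROLES = ("NEG", "POS", "H03", "H100")


class StageError(HitFcaError):
    """Wraps a stage failure with the stage name for the report/CLI."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _prepare_tube(t: io.EventTable, config: RunConfig) -> tuple[io.EventTable, gating.GateResult, dict]:
    """Compensate, log-transform and gate one tube; returns table, gate, QC."""
    if config.spillover is not None:
        t = io.apply_compensation(t, config.spillover)
    t = io.to_log(t, floor=config.log_floor)
    scatter = gating.gate_platelet_scatter(
        t, k=config.scatter_k, secondary_fraction=config.secondary_fraction
    )
    cd41 = gating.gate_cd41_positive(t, scatter)
    acq = gating.check_acquisition(cd41, minimum=config.min_acquired_events)
    summary = {
        "n_total": t.n_events,
        "n_scatter": scatter.n_in,
        "n_cd41": cd41.n_in,
        "threshold_fl2": cd41.threshold_fl2,
        "unique_population": cd41.unique_population,
        "flags": cd41.flags,
        "acquisition": acq,
    }
    return t, cd41, summary


def analyze_tables(
    tables: dict[str, io.EventTable],
    config: RunConfig | None = None,
    prp_prepared_at: datetime | None = None,
    measured_at: datetime | None = None,
    prp_id: str = "PRP-1",
    sample_id: str = "sample",
) -> dict:
    """Run the full analysis on in-memory tables; returns the JSON report."""
    config = config or RunConfig()
    missing = [r for r in RUN_ROLES if r not in tables]
    if missing:
        raise StageError("input", HitFcaError(f"missing tubes: {missing}"))

    prepared: dict[str, tuple[io.EventTable, gating.GateResult]] = {}
    gate_summaries: dict[str, dict] = {}
    for role in RUN_ROLES:
        try:
            t, gate, summary = _prepare_tube(tables[role], config)
        except HitFcaError as exc:
            raise StageError("gating", exc) from exc
        prepared[role] = (t, gate)
        gate_summaries[role] = summary

    try:
        if config.cutoff_method == "intersection":
            neg_curve, pos_curve = activation.paired_densities(
                prepared["NEG"][0], prepared["NEG"][1], prepared["POS"][0], prepared["POS"][1]
            )
            cutoff = activation.intersection_cutoff(neg_curve, pos_curve)
        else:
            cutoff = activation.legacy_cutoff(prepared["NEG"][0], prepared["NEG"][1])
    except HitFcaError as exc:
        raise StageError("activation", exc) from exc

    tubes = {
        role: activation.percent_activation(t, gate, cutoff)
        for role, (t, gate) in prepared.items()
    }
    run = hepla.AssayRun(
        tubes=tubes,
        prp_prepared_at=prp_prepared_at,
        measured_at=measured_at,
        prp_id=prp_id,
        sample_id=sample_id,
    )
    try:
        result = hepla.evaluate_run(run, config.limits)
    except HitFcaError as exc:
        raise StageError("hepla", exc) from exc

    stability = hepla.check_stability(run, config.limits)
    return {
        "sample_id": sample_id,
        "prp_id": prp_id,
        "gates": gate_summaries,
        "cutoff": {"value": cutoff.value, "method": cutoff.method, **cutoff.diagnostics},
        "stability": stability,
        "result": asdict(result),
    }


def analyze_run(
    paths: dict[str, str | Path],
    config: RunConfig | None = None,
    **kwargs,
) -> dict:
    """Read the four tube files and analyze them (see ``analyze_tables``)."""
    config = config or RunConfig()
    tables = {}
    for role in RUN_ROLES:
        if role not in paths:
            raise StageError("input", HitFcaError(f"no file given for tube {role}"))
        try:
            tables[role] = io.read_event_table(
                paths[role], config.channel_map, dialect=config.dialect, tube_role=role
            )
        except HitFcaError as exc:
            raise StageError("read", exc) from exc
    return analyze_tables(tables, config, **kwargs)


def analyze_simulated(sim: SimulatedRun, config: RunConfig | None = None) -> dict:
    """Analyze a simulated run, carrying its PRP timestamps and ids."""
    return analyze_tables(
        sim.tables,
        config,
        prp_prepared_at=sim.prp_prepared_at,
        measured_at=sim.measured_at,
        prp_id=sim.prp_id,
        sample_id=sim.sample_id,
    )
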