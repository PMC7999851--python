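"""Run configuration: channel map, spillover, gate parameters, limits.

One structured block (YAML on disk) holds every tunable the pipeline
uses, with defaults reproducing the assay's published constants, so a
run is fully determined by (input files, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .gating import DEFAULT_MIN_EVENTS, DEFAULT_SCATTER_K, DEFAULT_SECONDARY_FRACTION
from .hepla import ReferenceLimits
from .io import DEFAULT_LOG_FLOOR, ChannelMap, SpilloverMatrix


@dataclass
class RunConfig:
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    spillover: SpilloverMatrix | None = None  # None: no compensation (instrument-side)
    cutoff_method: str = "intersection"  # or "legacy"
    limits: ReferenceLimits = field(default_factory=ReferenceLimits)
    scatter_k: float = DEFAULT_SCATTER_K
    secondary_fraction: float = DEFAULT_SECONDARY_FRACTION
    min_acquired_events: int = DEFAULT_MIN_EVENTS
    log_floor: float = DEFAULT_LOG_FLOOR
    dialect: str = "csv"

    def __post_init__(self) -> None:
        if self.cutoff_method not in ("intersection", "legacy"):
            raise ParameterError(f"cutoff_method must be intersection|legacy, got {self.cutoff_method!r}")
        if self.dialect not in ("csv", "fcs"):
            raise ParameterError(f"dialect must be csv|fcs, got {self.dialect!r}")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "channel_map" in raw:
        kwargs["channel_map"] = ChannelMap(**{k.lower(): v for k, v in raw["channel_map"].items()})
    if raw.get("spillover") is not None:
        sp = raw["spillover"]
        kwargs["spillover"] = SpilloverMatrix(
            channels=tuple(sp.get("channels", ("FL1", "FL2"))),
            matrix=np.asarray(sp["matrix"], dtype=float),
        )
    if "limits" in raw:
        lim = dict(raw["limits"])
        if "qcm_range" in lim:
            lim["qcm_range"] = tuple(lim["qcm_range"])
        kwargs["limits"] = ReferenceLimits(**lim)
    simple = {f.name for f in fields(RunConfig)} - {"channel_map", "spillover", "limits"}
    for key in simple & set(raw):
        kwargs[key] = raw[key]
    unknown = set(raw) - simple - {"channel_map", "spillover", "limits"}
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)
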