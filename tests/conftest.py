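import numpy as np
import pytest

from hitfca import EventTable, GateResult, RunConfig, SimConfig


def make_log_table(n=None, fsc=None, ssc=None, fl1=None, fl2=None, role="OTHER"):
    """EventTable already in log10 scale, channels filled with zeros by default."""
    cols = {"FSC": fsc, "SSC": ssc, "FL1": fl1, "FL2": fl2}
    sizes = {len(v) for v in cols.values() if v is not None}
    if n is None:
        n = sizes.pop() if sizes else 0
    data = np.column_stack([
        np.asarray(v, dtype=float) if v is not None else np.zeros(n) for v in cols.values()
    ])
    t = EventTable(events=data.astype(np.float32), channels=tuple(cols), tube_role=role)
    t.scale = {ch: "log10" for ch in cols}
    return t


def full_gate(t):
    """A gate admitting every event."""
    return GateResult(mask=np.ones(t.n_events, dtype=bool), n_total=t.n_events)


@pytest.fixture
def simcfg():
    return SimConfig()


@pytest.fixture
def runcfg(simcfg):
    """Pipeline config that compensates with the simulator's spillover."""
    return RunConfig(spillover=simcfg.spillover)
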