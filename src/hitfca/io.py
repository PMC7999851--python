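"""Event-level cytometry I/O: FCS 3.0/3.1 and CSV dialects.

The atomic dataset is the :class:`EventTable`: one row per acquired event,
one column per channel (forward scatter FSC, side scatter SSC, and the two
fluorescence channels FL1 = FITC/anti-CD62p and FL2 = PE/anti-CD41).
Instrument channel names are mapped onto those four roles by a
:class:`ChannelMap`; spillover between the fluorophores is corrected by
inverting a :class:`SpilloverMatrix`.

FCS support targets FCS 3.0/3.1 list-mode files with floating-point or
integer data; other versions are rejected. The CSV dialect is a UTF-8
header row of channel names followed by one event per row, period decimal
separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelError, DataError, FormatError, NumericalError, ParameterError, StateError

ROLES = ("FSC", "SSC", "FL1", "FL2")
FLUO_ROLES = ("FL1", "FL2")
TUBE_ROLES = ("NEG", "POS", "H03", "H100", "OTHER")

LINEAR = "linear"
LOG10 = "log10"

#: default clamp applied before log10 so compensated (possibly negative)
#: intensities still have a finite logarithm, in instrument units
DEFAULT_LOG_FLOOR = 0.1


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from the four assay roles to instrument channel names."""

    fsc: str = "FSC"
    ssc: str = "SSC"
    fl1: str = "FL1"
    fl2: str = "FL2"

    def __post_init__(self) -> None:
        names = [self.fsc, self.ssc, self.fl1, self.fl2]
        if len(set(names)) != 4:
            raise ChannelError(f"channel map is not injective: {names}")

    def as_dict(self) -> dict[str, str]:
        return {"FSC": self.fsc, "SSC": self.ssc, "FL1": self.fl1, "FL2": self.fl2}


@dataclass(frozen=True)
class SpilloverMatrix:
    """Spillover fractions between the fluorescence channels.

    Row = source fluorophore, column = detector. Diagonal entries are 1;
    an off-diagonal entry s[i, j] is the fraction of fluorophore i's
    signal read by detector j. Observed = true @ matrix, so compensation
    solves the linear system the other way.
    """

    channels: tuple[str, ...] = FLUO_ROLES
    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ParameterError(f"spillover matrix shape {m.shape} does not match channels {self.channels}")
        if not np.allclose(np.diag(m), 1.0):
            raise ParameterError("spillover diagonal entries must equal 1")
        off = m[~np.eye(k, dtype=bool)]
        if np.any((off < 0) | (off >= 1)):
            raise ParameterError("off-diagonal spillover fractions must lie in [0, 1)")
        if abs(np.linalg.det(m)) < 1e-12:
            raise NumericalError("spillover matrix is singular")


@dataclass
class EventTable:
    """Per-event channel intensities plus tube metadata.

    ``events`` is an (n_events, n_channels) array; ``scale`` records, per
    channel, whether the stored values are linear instrument units or
    log10-transformed.
    """

    events: np.ndarray
    channels: tuple[str, ...] = ROLES
    tube_role: str = "OTHER"
    acquired_at: datetime | None = None
    scale: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.atleast_2d(np.asarray(self.events))
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ChannelError(f"duplicate channel names: {self.channels}")
        if self.events.ndim != 2 or (self.events.size and self.events.shape[1] != len(self.channels)):
            raise DataError("event matrix width does not match the channel list")
        if self.tube_role not in TUBE_ROLES:
            raise ParameterError(f"unknown tube role {self.tube_role!r}")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise DataError("event intensities must all be finite")
        for ch in self.channels:
            self.scale.setdefault(ch, LINEAR)

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    def column(self, channel: str) -> np.ndarray:
        try:
            return self.events[:, self.channels.index(channel)]
        except ValueError:
            raise ChannelError(f"no channel {channel!r} in table (have {self.channels})") from None

    def is_log(self, channel: str) -> bool:
        return self.scale.get(channel) == LOG10

    def with_events(self, events: np.ndarray, **meta) -> "EventTable":
        t = EventTable(
            events=events,
            channels=self.channels,
            tube_role=self.tube_role,
            acquired_at=self.acquired_at,
            scale=dict(self.scale),
            meta={**self.meta, **meta},
        )
        return t


def _select_roles(df: pd.DataFrame, cmap: ChannelMap) -> np.ndarray:
    cols = []
    for role, name in cmap.as_dict().items():
        if name not in df.columns:
            raise ChannelError(f"channel {name!r} required for role {role} is missing")
        cols.append(df[name].to_numpy(dtype=np.float32))
    return np.column_stack(cols) if cols else np.empty((0, 4), dtype=np.float32)


def read_event_table(
    path: str | Path,
    cmap: ChannelMap | None = None,
    dialect: str = "csv",
    tube_role: str = "OTHER",
) -> EventTable:
    """Read an event table, renaming mapped channels to their roles.

    The returned table is in linear scale with channels ordered
    (FSC, SSC, FL1, FL2); event order is preserved.
    """
    cmap = cmap or ChannelMap()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
        events = _select_roles(df, cmap)
        acquired_at = None
    elif dialect == "fcs":
        names, data, acquired_at = _read_fcs(path)
        df = pd.DataFrame(data, columns=names)
        events = _select_roles(df, cmap)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return EventTable(events=events, channels=ROLES, tube_role=tube_role, acquired_at=acquired_at)


def write_event_table(t: EventTable, path: str | Path, dialect: str = "csv") -> Path:
    """Write an event table under the named dialect (inverse of read)."""
    path = Path(path)
    if dialect == "csv":
        pd.DataFrame(t.events, columns=list(t.channels)).to_csv(path, index=False)
    elif dialect == "fcs":
        _write_fcs(path, t)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return path


def apply_compensation(t: EventTable, s: SpilloverMatrix) -> EventTable:
    """Undo fluorescence spillover: solve x @ S = v per event.

    Scatter channels are untouched. Requires linear-scale fluorescence;
    compensating log-transformed data is meaningless and rejected.
    """
    for ch in s.channels:
        if t.is_log(ch):
            raise StateError(f"channel {ch} is log-scaled; compensate before the log transform")
    idx = [t.channels.index(ch) for ch in s.channels]
    v = t.events[:, idx].astype(float)
    try:
        # x S = v  <=>  S^T x^T = v^T
        x = np.linalg.solve(s.matrix.T, v.T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"spillover matrix not invertible: {exc}") from exc
    events = t.events.copy()
    events[:, idx] = x.astype(events.dtype)
    return t.with_events(events, compensated=True)


def to_log(t: EventTable, floor: float = DEFAULT_LOG_FLOOR) -> EventTable:
    """Replace every intensity x by log10(max(x, floor)).

    The floor makes the transform total on compensated data, which can
    contain non-positive values.
    """
    if not (floor > 0):
        raise ParameterError(f"log floor must be positive, got {floor}")
    already = [ch for ch in t.channels if t.is_log(ch)]
    if already:
        raise StateError(f"channels already log-scaled: {already}")
    events = np.log10(np.maximum(t.events.astype(float), floor)).astype(np.float32)
    out = t.with_events(events, log_floor=floor)
    out.scale = {ch: LOG10 for ch in t.channels}
    return out


# ---------------------------------------------------------------------------
# Minimal FCS 3.0/3.1 list-mode reader/writer.
#
# Layout: 58-byte HEADER (version + six 8-char right-justified segment
# offsets), a delimiter-framed TEXT segment of /key/value/ pairs, then the
# DATA segment. Only list mode ($MODE L) with uniform-width float, double
# or integer parameters is supported, which covers files this package
# writes and plain exports from modern instruments.
# ---------------------------------------------------------------------------

_FCS_VERSIONS = ("FCS3.0", "FCS3.1")


def _read_fcs(path: Path) -> tuple[list[str], np.ndarray, datetime | None]:
    raw = path.read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = raw[0:6].decode("ascii", "replace")
    if version not in _FCS_VERSIONS:
        raise FormatError(f"{path}: unsupported FCS version {version!r}; only FCS 3.0/3.1 are handled")

    def _offset(a: int, b: int) -> int:
        s = raw[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_begin <= 0 or text_end <= text_begin:
        raise FormatError(f"{path}: invalid TEXT segment offsets")

    delim = raw[text_begin:text_begin + 1].decode("latin-1")
    body = raw[text_begin + 1:text_end + 1].decode("latin-1")
    parts = body.split(delim)
    kv = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        if key:
            kv[key.strip().upper()] = value

    mode = kv.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FormatError(f"{path}: only list-mode ($MODE L) FCS is supported, got {mode!r}")
    try:
        par = int(kv["$PAR"])
        tot = int(kv["$TOT"])
        datatype = kv["$DATATYPE"].strip().upper()
        byteord = kv["$BYTEORD"].strip()
    except KeyError as exc:
        raise FormatError(f"{path}: missing required FCS keyword {exc}") from exc

    if data_begin == 0:
        data_begin = int(kv.get("$BEGINDATA", 0))
        data_end = int(kv.get("$ENDDATA", 0))
    if data_begin <= 0 or data_end < data_begin:
        raise FormatError(f"{path}: invalid DATA segment offsets")

    endian = {"1,2,3,4": "<", "4,3,2,1": ">"}.get(byteord)
    if endian is None:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")
    widths = {int(kv.get(f"$P{i}B", 32)) for i in range(1, par + 1)}
    if len(widths) != 1:
        raise FormatError(f"{path}: mixed parameter bit widths {sorted(widths)} are not supported")
    bits = widths.pop()
    if datatype == "F":
        if bits != 32:
            raise FormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        if bits != 64:
            raise FormatError(f"{path}: $DATATYPE D requires 64-bit parameters")
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        if bits not in (16, 32, 64):
            raise FormatError(f"{path}: unsupported integer width {bits}")
        dtype = np.dtype(f"{endian}u{bits // 8}")
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_bytes = par * tot * dtype.itemsize
    blob = raw[data_begin:data_begin + n_bytes]
    if len(blob) < n_bytes:
        raise FormatError(f"{path}: DATA segment truncated")
    data = np.frombuffer(blob, dtype=dtype).reshape(tot, par)

    names = []
    for i in range(1, par + 1):
        name = kv.get(f"$P{i}N")
        if name is None:
            raise FormatError(f"{path}: missing $P{i}N")
        names.append(name.strip())

    acquired_at = None
    if "$DATE" in kv and "$BTIM" in kv:
        try:
            acquired_at = datetime.strptime(
                kv["$DATE"].strip() + " " + kv["$BTIM"].strip(), "%d-%b-%Y %H:%M:%S"
            )
        except ValueError:
            acquired_at = None
    return names, np.asarray(data), acquired_at


def _write_fcs(path: Path, t: EventTable) -> None:
    data = np.ascontiguousarray(t.events, dtype="<f4")
    n, par = data.shape
    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(par)),
        ("$TOT", str(n)),
    ]
    if t.acquired_at is not None:
        keywords.append(("$DATE", t.acquired_at.strftime("%d-%b-%Y")))
        keywords.append(("$BTIM", t.acquired_at.strftime("%H:%M:%S")))
    for i, ch in enumerate(t.channels, start=1):
        top = float(data[:, i - 1].max()) if n else 0.0
        keywords += [
            (f"$P{i}N", ch),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(top, 1)) + 1)),
        ]

    # fixed-width offsets keep the TEXT length independent of their values
    keywords = [("$BEGINDATA", "%012d" % 0), ("$ENDDATA", "%012d" % 0)] + keywords
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords) + delim
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    keywords[0] = ("$BEGINDATA", "%012d" % data_begin)
    keywords[1] = ("$ENDDATA", "%012d" % data_end)
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords) + delim

    def _field(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _field(text_begin) + _field(text_end)
    header += _field(data_begin if data_end <= 99999999 else 0)
    header += _field(data_end if data_end <= 99999999 else 0)
    header += _field(0) + _field(0)
    assert len(header) == 58
    path.write_bytes(header + text.encode("latin-1") + data.tobytes())
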