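"""Event-table container, FCS/CSV input-output, spillover compensation and
arcsinh intensity transforms.

The :class:`EventTable` is the atom of the whole pipeline: an events x channels
matrix with ordered channel names and an explicit transform state that only
moves forward (``raw -> compensated -> transformed``), so every downstream
result can be annotated with the scale it was computed on.

FCS support is a minimal, self-contained implementation of the list-mode
subset of the standard: reading FCS 3.0/3.1 files with ``$DATATYPE`` F or D,
and writing FCS 3.1 with single-precision float data. CSV interchange is one
row per event with a mandatory header of channel names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panels import SCATTER_CHANNELS

__all__ = [
    "EventTable",
    "SampleMetadata",
    "SpilloverMatrix",
    "FCSParseError",
    "read_events",
    "write_events",
    "apply_compensation",
    "transform_intensities",
]


class FCSParseError(ValueError):
    """Raised when an FCS file violates the list-mode standard."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class EventTable:
    """Matrix of cytometry events by channels.

    Parameters
    ----------
    values
        ``(n_events, n_channels)`` float array. Raw intensities are
        non-negative by convention; compensated or transformed values may be
        negative and are never clipped.
    channels
        Ordered, unique channel labels, one per column.
    transform_state
        ``"none"`` (raw), ``"compensated"``, or ``"transformed"``.
    transform_params
        For transformed tables, the method and its parameters
        (e.g. ``{"method": "arcsinh", "cofactor": 150.0}``).
    """

    values: np.ndarray
    channels: tuple[str, ...]
    transform_state: str = "none"
    transform_params: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (events x channels) array")
        channels = tuple(self.channels)
        if len(set(channels)) != len(channels):
            dupes = sorted({c for c in channels if list(channels).count(c) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        if values.shape[1] != len(channels):
            raise ValueError(
                f"{values.shape[1]} columns but {len(channels)} channel names"
            )
        if self.transform_state not in ("none", "compensated", "transformed"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channels", channels)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        """Values of one channel, as a view on the underlying matrix."""
        try:
            idx = self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in table (has {self.channels})")
        return self.values[:, idx]

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row subset keeping channel metadata and transform state."""
        return replace(self, values=self.values[np.asarray(mask)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.channels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EventTable":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.columns)), **kwargs)


@dataclass(frozen=True)
class SampleMetadata:
    """Experimental annotations of one acquired tube."""

    animal_id: str
    group: str  # sham | CCI
    hemisphere: str  # ipsilateral | contralateral
    panel: str  # M1 | M2
    tissue_mass_mg: float
    beads_added: int

    def __post_init__(self):
        if self.group not in ("sham", "CCI"):
            raise ValueError(f"group must be 'sham' or 'CCI', got {self.group!r}")
        if self.hemisphere not in ("ipsilateral", "contralateral"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if self.panel not in ("M1", "M2"):
            raise ValueError(f"panel must be 'M1' or 'M2', got {self.panel!r}")
        if not self.tissue_mass_mg > 0:
            raise ValueError("tissue_mass_mg must be positive")
        if self.beads_added < 0:
            raise ValueError("beads_added must be non-negative")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.group, self.hemisphere)


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix over fluorescence channels.

    Convention: ``observed = S @ true`` per event, i.e. entry ``S[i, j]`` is
    the fraction of channel-``j`` signal detected in channel ``i``. The
    diagonal is unity.
    """

    channels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        channels = tuple(self.channels)
        if m.shape != (len(channels), len(channels)):
            raise ValueError("spillover matrix shape does not match channel list")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover matrix must have unit diagonal")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channels", channels)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @classmethod
    def identity(cls, channels) -> "SpilloverMatrix":
        channels = tuple(channels)
        return cls(channels, np.eye(len(channels)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=list(self.channels),
                     columns=list(self.channels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("spillover CSV row and column channel labels differ")
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1


_REQUIRED_KEYWORDS = ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD", "$MODE")


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    # strip leading/trailing delimiter; double delimiters (escapes) are rare
    # and unsupported here.
    parts = body.strip(delim).split(delim)
    if len(parts) % 2 != 0:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs(path) -> tuple[EventTable, dict[str, str]]:
    """Read a list-mode FCS 3.0/3.1 file.

    Returns the event table plus the raw TEXT-segment keyword dictionary.
    ``$PnS`` (stain) labels are preferred over ``$PnN`` (detector) as the
    canonical channel name when present.
    """
    blob = Path(path).read_bytes()
    if len(blob) < 58:
        raise FCSParseError(f"{path}: file too short for an FCS header")
    version = blob[:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise FCSParseError(f"{path}: bad magic {version!r}")

    def _offset(a, b):
        s = blob[a:b].decode("latin-1").strip() or "0"
        return int(s)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    keywords = _parse_text_segment(blob[text_start:text_end + 1])

    for kw in _REQUIRED_KEYWORDS:
        if kw not in keywords:
            raise FCSParseError(f"{path}: required keyword {kw} missing")
    if keywords["$MODE"].upper() != "L":
        raise FCSParseError(f"{path}: only list mode ($MODE=L) is supported")

    n_events = int(keywords["$TOT"])
    n_par = int(keywords["$PAR"])
    if data_start == 0:
        data_start = int(keywords.get("$BEGINDATA", "0"))
        data_end = int(keywords.get("$ENDDATA", "0"))

    datatype = keywords["$DATATYPE"].upper()
    if datatype not in ("F", "D"):
        raise FCSParseError(
            f"{path}: $DATATYPE={datatype} unsupported (only F/D list mode)")
    byteord = keywords["$BYTEORD"].replace(" ", "")
    if byteord in ("1,2,3,4", "1,2"):
        order = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        order = ">"
    else:
        raise FCSParseError(f"{path}: unsupported $BYTEORD={byteord}")
    itemsize = 4 if datatype == "F" else 8
    expected = n_events * n_par * itemsize
    data = blob[data_start:data_end + 1]
    if len(data) < expected:
        raise FCSParseError(
            f"{path}: DATA segment holds {len(data)} bytes, "
            f"$TOT*$PAR needs {expected}")
    dtype = np.dtype(f"{order}f{itemsize}")
    values = np.frombuffer(data[:expected], dtype=dtype).reshape(n_events, n_par)

    channels = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N")
        if not name:
            raise FCSParseError(f"{path}: parameter {i} has neither $PnN nor $PnS")
        channels.append(name)
    if len(set(channels)) != len(channels):
        raise FCSParseError(f"{path}: duplicate channel names {channels}")
    return EventTable(values.astype(float), tuple(channels)), keywords


def write_fcs(table: EventTable, path, extra_keywords: Mapping[str, str] | None = None) -> None:
    """Write an event table as FCS 3.1, single-precision float, little endian."""
    values = np.ascontiguousarray(table.values, dtype="<f4")
    n_events, n_par = values.shape
    delim = "/"
    kw: dict[str, str] = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
    }
    for i, name in enumerate(table.channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        finite = table.values[:, i - 1][np.isfinite(table.values[:, i - 1])]
        top = float(finite.max()) if finite.size else 1.0
        kw[f"$P{i}R"] = str(int(max(top, 1.0)) + 1)
    if extra_keywords:
        kw.update({str(k): str(v) for k, v in extra_keywords.items()})

    # lay out with fixed-width BEGINDATA/ENDDATA so offsets are stable
    kw["$BEGINDATA"] = "0" * 12
    kw["$ENDDATA"] = "0" * 12

    def render(d):
        return (delim + delim.join(f"{k}{delim}{v}" for k, v in d.items()) + delim).encode("latin-1")

    header_len = 58
    text = render(kw)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1
    kw["$BEGINDATA"] = str(data_start).zfill(12)
    kw["$ENDDATA"] = str(data_end).zfill(12)
    text = render(kw)

    header = b"FCS3.1    " + (
        f"{text_start:>8d}{text_end:>8d}"
        f"{data_start if data_start <= 99999999 else 0:>8d}"
        f"{data_end if data_end <= 99999999 else 0:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


# ---------------------------------------------------------------------------
# CSV + dispatch


def read_events(path, format: str | None = None) -> tuple[EventTable, dict]:
    """Read an event table from an FCS or CSV file.

    ``format`` defaults to the file suffix. Returns ``(table, metadata)``
    where metadata is the FCS keyword dictionary (empty for CSV).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        return read_fcs(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        cols = list(map(str, df.columns))
        if len(set(cols)) != len(cols):
            raise ValueError(f"{path}: duplicate channel names in CSV header")
        return EventTable(df.to_numpy(dtype=float), tuple(cols)), {}
    raise ValueError(f"unknown format {fmt!r}; expected 'fcs' or 'csv'")


def write_events(table: EventTable, path, format: str | None = None) -> None:
    """Write an event table as FCS 3.1 or headered CSV."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "fcs":
        write_fcs(table, path)
    elif fmt == "csv":
        table.to_dataframe().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'fcs' or 'csv'")


# ---------------------------------------------------------------------------
# compensation and transforms


def _fluorescence_channels(table: EventTable) -> list[str]:
    return [c for c in table.channels if c not in SCATTER_CHANNELS]


def apply_compensation(table: EventTable, spill: SpilloverMatrix,
                       max_condition: float = 1e8) -> EventTable:
    """Correct fluorescence spillover by inverting the spillover mixing.

    With ``observed = S @ true`` per event, the compensated values solve the
    linear system per event; scatter channels are untouched. Negative
    compensated values are retained.
    """
    if table.transform_state != "none":
        raise ValueError(
            f"compensation requires a raw table (state={table.transform_state!r})")
    missing = [c for c in spill.channels if c not in table.channels]
    if missing:
        raise ValueError(f"spillover references absent channels: {missing}")
    cond = spill.condition_number
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"spillover matrix is singular or ill-conditioned (cond={cond:.3g})")
    idx = [table.channels.index(c) for c in spill.channels]
    values = table.values.copy()
    values[:, idx] = np.linalg.solve(spill.matrix, values[:, idx].T).T
    return replace(table, values=values, transform_state="compensated")


def transform_intensities(table: EventTable, method: str = "arcsinh",
                          cofactor: float = 150.0) -> EventTable:
    """Apply an arcsinh transform ``x -> asinh(x / cofactor)`` to fluorescence.

    Scatter channels stay linear. ``cofactor`` may be a single positive number
    or a mapping channel -> cofactor.
    """
    if method != "arcsinh":
        raise ValueError(f"unsupported transform {method!r} (arcsinh only)")
    if table.transform_state == "transformed":
        raise ValueError("table is already transformed")
    fluor = _fluorescence_channels(table)
    cofactors = (dict(cofactor) if isinstance(cofactor, Mapping)
                 else {c: float(cofactor) for c in fluor})
    values = table.values.copy()
    for c in fluor:
        cf = float(cofactors.get(c, 150.0))
        if cf <= 0:
            raise ValueError(f"cofactor for {c!r} must be positive, got {cf}")
        values[:, table.channels.index(c)] = np.arcsinh(
            values[:, table.channels.index(c)] / cf)
    return replace(
        table, values=values, transform_state="transformed",
        transform_params={"method": "arcsinh", "cofactor": cofactors},
    )


def inverse_transform_intensities(values: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    """Map transformed fluorescence back to raw scale, ``x -> sinh(x)*cofactor``."""
    return np.sinh(values) * float(cofactor)
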