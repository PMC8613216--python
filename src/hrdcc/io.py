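"""Event-data I/O: FCS 3.1 read/write, spillover compensation, arcsinh
transform, and population-table persistence.

The FCS writer emits FCS 3.1 list-mode files with ``$DATATYPE F`` (little
endian float32) and the ``$SPILLOVER`` keyword when a spillover matrix is
attached.  The reader additionally accepts ``$DATATYPE D`` and integer data
and both byte orders, and preserves unknown TEXT keywords verbatim.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventMatrix",
    "FCSFormatError",
    "write_fcs",
    "read_fcs",
    "compensate",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "save_population_table",
    "load_population_table",
    "parse_spillover_keyword",
    "format_spillover_keyword",
]

DEFAULT_COFACTOR = 150.0

SCATTER_NAMES = ("FSC-A", "FSC-H", "SSC-A")


class FCSFormatError(ValueError):
    """Raised when an FCS file is structurally malformed."""


@dataclass
class EventMatrix:
    """Rows = events, columns = channels, plus channel and sample metadata.

    ``transform_state`` is ``"linear"`` for raw intensities or
    ``"arcsinh:<cofactor>"`` after :func:`arcsinh_transform`.
    ``spillover`` (optional) is the square spillover matrix over
    ``spillover_channels``.
    """

    values: np.ndarray
    channel_names: list[str]
    transform_state: str = "linear"
    metadata: dict = field(default_factory=dict)
    spillover: np.ndarray | None = None
    spillover_channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("event values must be a 2-D matrix")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch between values and names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        try:
            j = self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not present") from None
        return self.values[:, j]

    def fluorescence_channels(self) -> list[str]:
        return [c for c in self.channel_names if c not in SCATTER_NAMES]

    def copy_with(self, values: np.ndarray, **kw) -> "EventMatrix":
        out = EventMatrix(
            values,
            list(self.channel_names),
            kw.get("transform_state", self.transform_state),
            dict(self.metadata),
            self.spillover if self.spillover is None else self.spillover.copy(),
            None if self.spillover_channels is None else list(self.spillover_channels),
        )
        return out


# ---------------------------------------------------------------------------
# FCS 3.1
# ---------------------------------------------------------------------------

_DELIM = "/"


def format_spillover_keyword(matrix: np.ndarray, channels: list[str]) -> str:
    """FCS 3.1 $SPILLOVER value: n, channel names, then row-major values."""
    n = len(channels)
    vals = ",".join(repr(float(v)) for v in np.asarray(matrix).ravel())
    return f"{n},{','.join(channels)},{vals}"


def parse_spillover_keyword(text: str) -> tuple[np.ndarray, list[str]]:
    parts = text.split(",")
    n = int(parts[0])
    names = parts[1 : 1 + n]
    vals = np.array([float(v) for v in parts[1 + n :]], dtype=float)
    if vals.size != n * n:
        raise FCSFormatError("$SPILLOVER value count does not match matrix size")
    return vals.reshape(n, n), names


def _escape(v: str) -> str:
    return v.replace(_DELIM, _DELIM * 2)


def write_fcs(sample: EventMatrix, destination) -> None:
    """Write ``sample`` as an FCS 3.1 list-mode float file."""
    destination = Path(destination)
    n_events, n_par = sample.values.shape
    data = sample.values.astype("<f4").tobytes()

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(sample.channel_names, start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}S", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", repr(float(max(1.0, np.max(sample.values[:, i - 1], initial=1.0))))),
        ]
    if sample.spillover is not None:
        chans = sample.spillover_channels or sample.fluorescence_channels()
        keywords.append(("$SPILLOVER", format_spillover_keyword(sample.spillover, chans)))
    keywords.append(("TRANSFORM", sample.transform_state))
    for k, v in sample.metadata.items():
        if k.startswith("$"):
            continue  # structural keywords are regenerated
        keywords.append((str(k), str(v)))

    # offsets appear inside TEXT, so reserve fixed-width fields and fill in
    def render(text_start: int, data_start: int, data_end: int) -> bytes:
        parts = [_DELIM]
        dyn = [
            ("$BEGINDATA", f"{data_start:012d}"),
            ("$ENDDATA", f"{data_end:012d}"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
        ]
        for k, v in dyn + keywords:
            parts.append(f"{_escape(k)}{_DELIM}{_escape(v)}{_DELIM}")
        return "".join(parts).encode("utf-8")

    header_len = 58
    text_start = header_len
    probe = render(text_start, 0, 0)
    text_end = text_start + len(probe) - 1
    data_start = text_end + 1
    data_end = data_start + len(data) - 1 if data else 0
    text = render(text_start, data_start, data_end)
    assert len(text) == len(probe)

    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + (f"{data_start:8d}" if data_start <= 99_999_999 else f"{0:8d}").encode()
        + (f"{data_end:8d}" if data_end <= 99_999_999 else f"{0:8d}").encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(destination, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FCSFormatError("empty TEXT segment")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # delimiter escaping: doubled delimiter inside a value
    tokens = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 1 < len(tokens) and tokens[i + 1] == "" and i + 2 < len(tokens):
            tok = tok + delim + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if len(merged) % 2 == 1:
        merged = merged[:-1]
    return {merged[i]: merged[i + 1] for i in range(0, len(merged), 2)}


def read_fcs(source) -> EventMatrix:
    """Read an FCS 3.x list-mode file into an :class:`EventMatrix`."""
    source = Path(source)
    raw = source.read_bytes()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FCSFormatError("not an FCS file (bad HEADER magic)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FCSFormatError(f"unparseable HEADER offsets: {exc}") from exc
    if text_end <= text_start or text_end >= len(raw):
        raise FCSFormatError("TEXT segment offsets out of bounds")
    kw = _parse_text_segment(raw[text_start : text_end + 1])

    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").strip().upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    little = byteord.startswith("1")
    if datatype == "F":
        dtype = "<f4" if little else ">f4"
        itemsize = 4
    elif datatype == "D":
        dtype = "<f8" if little else ">f8"
        itemsize = 8
    elif datatype == "I":
        bits = int(kw.get("$P1B", "32"))
        if bits not in (16, 32):
            raise FCSFormatError(f"unsupported integer width {bits}")
        dtype = ("<" if little else ">") + ("u2" if bits == 16 else "u4")
        itemsize = bits // 8
    else:
        raise FCSFormatError(f"unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * itemsize
    segment = raw[data_start : data_end + 1]
    if len(segment) < expected:
        raise FCSFormatError(
            f"DATA segment truncated: expected {expected} bytes, found {len(segment)}"
        )
    values = np.frombuffer(segment[:expected], dtype=dtype).astype(float).reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N", f"P{i}"))
    spill = spill_ch = None
    if "$SPILLOVER" in kw:
        spill, spill_ch = parse_spillover_keyword(kw["$SPILLOVER"])
    meta = {k: v for k, v in kw.items() if not k.startswith("$")}
    state = kw.get("TRANSFORM", "linear")
    meta.pop("TRANSFORM", None)
    # keep structural keywords too, verbatim, for provenance
    meta.update({k: v for k, v in kw.items() if k.startswith("$")})
    return EventMatrix(values, names, state, meta, spill, spill_ch)


# ---------------------------------------------------------------------------
# compensation and scale transforms
# ---------------------------------------------------------------------------


def compensate(sample: EventMatrix, spillover: np.ndarray | None = None,
               channels: list[str] | None = None) -> EventMatrix:
    """Remove fluorescence spillover: detected = true @ S  =>  true = detected @ S^-1.

    Only fluorescence channels are touched; scatter columns and the
    transform state are unchanged.
    """
    if spillover is None:
        spillover = sample.spillover
    if spillover is None:
        raise ValueError("no spillover matrix supplied or attached")
    spillover = np.asarray(spillover, dtype=float)
    chans = channels or sample.spillover_channels or sample.fluorescence_channels()
    k = len(chans)
    if spillover.shape != (k, k):
        raise ValueError(
            f"spillover is {spillover.shape}, but {k} fluorescence channels given"
        )
    if not np.allclose(np.diag(spillover), 1.0):
        raise ValueError("spillover diagonal must be 1.0")
    cond = np.linalg.cond(spillover)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("spillover matrix is singular or near-singular")
    idx = [sample.channel_names.index(c) for c in chans]
    out = sample.values.copy()
    detected = out[:, idx]
    # solve true @ S = detected  for true (row-vector convention)
    true = np.linalg.solve(spillover.T, detected.T).T
    out[:, idx] = true
    return sample.copy_with(out)


def arcsinh_transform(sample: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Map fluorescence columns x -> asinh(x / cofactor); scatter untouched."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if sample.transform_state != "linear":
        raise ValueError(f"sample already transformed ({sample.transform_state})")
    out = sample.values.copy()
    for c in sample.fluorescence_channels():
        j = sample.channel_names.index(c)
        out[:, j] = np.arcsinh(out[:, j] / cofactor)
    return sample.copy_with(out, transform_state=f"arcsinh:{cofactor:g}")


def inverse_arcsinh_transform(sample: EventMatrix) -> EventMatrix:
    """Undo :func:`arcsinh_transform`."""
    if not sample.transform_state.startswith("arcsinh:"):
        raise ValueError("sample is not arcsinh-transformed")
    cofactor = float(sample.transform_state.split(":", 1)[1])
    out = sample.values.copy()
    for c in sample.fluorescence_channels():
        j = sample.channel_names.index(c)
        out[:, j] = np.sinh(out[:, j]) * cofactor
    return sample.copy_with(out, transform_state="linear")


# ---------------------------------------------------------------------------
# population tables
# ---------------------------------------------------------------------------

POPULATION_TABLE_COLUMNS = [
    "sample_id",
    "animal",
    "group",
    "day",
    "phase",
    "fluid",
    "population",
    "percent_of_parent",
    "percent_of_live",
    "count",
]


def save_population_table(table: pd.DataFrame, path) -> None:
    """Persist a tidy population table (one row per sample x population) as CSV."""
    missing = [c for c in POPULATION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"population table missing columns {missing}")
    table.to_csv(path, index=False)


def load_population_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in POPULATION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"population table missing columns {missing}")
    for col in ("percent_of_parent", "percent_of_live"):
        vals = table[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100 + 1e-9):
            raise ValueError(f"column {col} contains values outside [0, 100]")
    return table
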