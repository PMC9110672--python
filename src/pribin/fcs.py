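"""FCS file I/O, the arcsinh transform and rectangular sequential gating.

Cytometry events are held in an :class:`EventTable`: an ``n_events x n_channels``
float matrix plus an ordered channel list and a channel→marker map.  Files are
read from FCS 3.0/3.1 (list mode, integer/float data) and written as FCS 3.1
(list mode, little-endian float32), the dominant modern dialect.

Signal intensities are variance-stabilized with the inverse hyperbolic sine,
``asinh(cofactor * x)`` with a default cofactor of 0.1; the alternative
``asinh(x / cofactor)`` convention is selectable via :class:`TransformSpec`.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FcsFormatError, StateError

__all__ = [
    "EventTable",
    "TransformSpec",
    "GateStep",
    "GateSpec",
    "read_fcs",
    "write_fcs",
    "apply_transform",
    "apply_gates",
    "load_gate_spec",
    "cd4_gate_template",
]

_HEADER_SIZE = 58


@dataclass
class EventTable:
    """Matrix of cells x channels with channel names and marker labels.

    Parameters
    ----------
    values
        Float array of shape ``(n_events, n_channels)``.
    channels
        Ordered channel identifiers (FCS ``$PnN``).
    markers
        Map channel → marker label (FCS ``$PnS``); channels without a stain
        label may be absent from the map.
    transformed
        Whether :func:`apply_transform` has been applied.
    """

    values: np.ndarray
    channels: list[str]
    markers: dict[str, str] = field(default_factory=dict)
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.channels)} channels were named"
            )
        labels = [self.markers.get(c, c) for c in self.channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"marker labels are not unique: {dupes}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def marker_labels(self) -> list[str]:
        """Effective per-column labels: marker if mapped, else channel name."""
        return [self.markers.get(c, c) for c in self.channels]

    def column_index(self, marker: str) -> int:
        """Resolve a marker label (or channel name) to its column index."""
        labels = self.marker_labels
        if marker in labels:
            return labels.index(marker)
        if marker in self.channels:
            return self.channels.index(marker)
        raise ConfigError(f"unknown marker {marker!r}; available: {labels}")

    def get(self, marker: str) -> np.ndarray:
        """Return one marker's intensity vector."""
        return self.values[:, self.column_index(marker)]

    def take(self, mask: np.ndarray) -> "EventTable":
        """Row subset preserving metadata."""
        return replace(self, values=self.values[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.marker_labels)


@dataclass(frozen=True)
class TransformSpec:
    """arcsinh transform settings.

    ``convention='multiply'`` computes ``asinh(cofactor * x)`` (default);
    ``'divide'`` computes ``asinh(x / cofactor)``.
    """

    cofactor: float = 0.1
    channels: tuple[str, ...] | None = None  # None = all columns
    convention: str = "multiply"

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ConfigError(f"cofactor must be > 0, got {self.cofactor}")
        if self.convention not in ("multiply", "divide"):
            raise ConfigError(f"unknown convention {self.convention!r}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.convention == "multiply":
            return np.arcsinh(self.cofactor * x)
        return np.arcsinh(x / self.cofactor)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        if self.convention == "multiply":
            return np.sinh(y) / self.cofactor
        return np.sinh(y) * self.cofactor


@dataclass(frozen=True)
class GateStep:
    """One rectangular gate on an (x, y) marker pair.

    Intervals are closed and may be half-unbounded via ``-inf`` / ``inf``.
    """

    name: str
    x_marker: str
    y_marker: str
    x_interval: tuple[float, float] = (-np.inf, np.inf)
    y_interval: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        for axis, (lo, hi) in (("x", self.x_interval), ("y", self.y_interval)):
            if not lo < hi:
                raise ConfigError(
                    f"gate {self.name!r}: empty {axis} interval [{lo}, {hi}]"
                )

    def mask(self, table: EventTable) -> np.ndarray:
        x = table.get(self.x_marker)
        y = table.get(self.y_marker)
        return (
            (x >= self.x_interval[0])
            & (x <= self.x_interval[1])
            & (y >= self.y_interval[0])
            & (y <= self.y_interval[1])
        )


@dataclass(frozen=True)
class GateSpec:
    """Ordered chain of rectangular gates applied as an intersection."""

    steps: tuple[GateStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError("gate spec has no steps")


def apply_gates(table: EventTable, gates: GateSpec) -> tuple[EventTable, pd.DataFrame]:
    """Apply a sequential gate chain; return survivors and a per-step report.

    The report has one row per step with ``n_in``, ``n_out`` and
    ``fraction_kept``.  Because every step is an axis-aligned rectangle the
    surviving set is the intersection of the step masks, hence independent of
    step order.
    """
    rows = []
    current = table
    for step in gates.steps:
        n_in = current.n_events
        mask = step.mask(current)
        current = current.take(mask)
        rows.append(
            {
                "step": step.name,
                "n_in": n_in,
                "n_out": current.n_events,
                "fraction_kept": current.n_events / n_in if n_in else np.nan,
            }
        )
    report = pd.DataFrame(rows, columns=["step", "n_in", "n_out", "fraction_kept"])
    return current, report


def apply_transform(table: EventTable, spec: TransformSpec | None = None) -> EventTable:
    """Return a new EventTable with arcsinh-transformed intensities.

    Only columns named in ``spec.channels`` are transformed (all by default);
    the result carries ``transformed=True`` and a second application raises.
    """
    if spec is None:
        spec = TransformSpec()
    if table.transformed:
        raise StateError("table is already transformed")
    values = table.values.copy()
    if spec.channels is None:
        cols = range(table.n_channels)
    else:
        cols = [table.column_index(m) for m in spec.channels]
    for j in cols:
        values[:, j] = spec.forward(values[:, j])
    return replace(table, values=values, transformed=True)


# ---------------------------------------------------------------------------
# FCS reading / writing
# ---------------------------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value.
    sentinel = b"\x00\x01pribin\x01\x00"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2 != 0:
        raise FcsFormatError("TEXT segment has an odd number of delimited tokens")
    out: dict[str, str] = {}
    for key, value in zip(parts[::2], parts[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = value.decode(
            "utf-8", "replace"
        )
    return out


def _keyword(text: dict[str, str], key: str) -> str:
    if key not in text:
        raise FcsFormatError(f"required keyword {key} missing from TEXT segment")
    return text[key]


_BYTEORD = {"1,2,3,4": "<", "4,3,2,1": ">", "1,2": "<", "2,1": ">"}


def read_fcs(path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Supports list-mode data with ``$DATATYPE`` F (float32), D (float64) or I
    (unsigned integers of 8/16/32/64 bit with ``$PnB`` uniform per channel).
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER_SIZE:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def offset(lo: int, hi: int) -> int:
        token = blob[lo:hi].decode("ascii", "replace").strip() or "0"
        try:
            return int(token)
        except ValueError as exc:
            raise FcsFormatError(f"{path}: bad header offset {token!r}") from exc

    text_begin, text_end = offset(10, 18), offset(18, 26)
    data_begin, data_end = offset(26, 34), offset(34, 42)
    text = _parse_text_segment(blob[text_begin : text_end + 1])
    if data_begin == 0:
        data_begin = int(_keyword(text, "$BEGINDATA"))
    if data_end == 0:
        data_end = int(_keyword(text, "$ENDDATA"))

    n_par = int(_keyword(text, "$PAR"))
    n_tot = int(_keyword(text, "$TOT"))
    datatype = _keyword(text, "$DATATYPE").strip().upper()
    mode = _keyword(text, "$MODE").strip().upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE L) is supported, got {mode}")
    byteord = _keyword(text, "$BYTEORD").strip()
    if byteord not in _BYTEORD:
        raise FcsFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")
    endian = _BYTEORD[byteord]

    bits = [int(_keyword(text, f"$P{i}B")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE F requires $PnB 32")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE D requires $PnB 64")
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32, 64):
            raise FcsFormatError(
                f"{path}: integer data requires one uniform $PnB in 8/16/32/64"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_tot * n_par * dtype.itemsize
    data = blob[data_begin : data_end + 1]
    if len(data) < expected:
        raise FcsFormatError(
            f"{path}: DATA segment holds {len(data)} bytes but $TOT={n_tot} "
            f"x $PAR={n_par} needs {expected}"
        )
    flat = np.frombuffer(data[:expected], dtype=dtype)
    values = flat.reshape(n_tot, n_par).astype(float)

    channels = []
    markers: dict[str, str] = {}
    for i in range(1, n_par + 1):
        name = _keyword(text, f"$P{i}N")
        channels.append(name)
        stain = text.get(f"$P{i}S")
        if stain:
            markers[name] = stain
    return EventTable(values=values, channels=channels, markers=markers)


def write_fcs(table: EventTable, path) -> str:
    """Write an :class:`EventTable` as FCS 3.1 (list mode, LE float32)."""
    if table.n_channels < 1:
        raise ValueError("cannot write a table with zero channels")
    n_tot, n_par = table.values.shape
    data = np.ascontiguousarray(table.values, dtype="<f4").tobytes()

    def esc(s: str) -> str:
        return s.replace("/", "//")

    pairs: list[tuple[str, str]] = [
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, chan in enumerate(table.channels, start=1):
        pairs.append((f"$P{i}N", chan))
        pairs.append((f"$P{i}B", "32"))
        pairs.append((f"$P{i}E", "0,0"))
        pairs.append((f"$P{i}R", str(int(2 ** 24))))
        stain = table.markers.get(chan)
        if stain:
            pairs.append((f"$P{i}S", stain))

    # DATA offsets inside TEXT use fixed-width numbers so the segment length
    # is independent of their value.
    placeholder = "0" * 12
    pairs += [("$BEGINDATA", placeholder), ("$ENDDATA", placeholder)]
    text_body = "/" + "/".join(f"{esc(k)}/{esc(v)}" for k, v in pairs) + "/"
    text_begin = _HEADER_SIZE
    text_end = text_begin + len(text_body.encode("ascii")) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text_body = text_body.replace(
        f"$BEGINDATA/{placeholder}", f"$BEGINDATA/{data_begin:012d}"
    ).replace(f"$ENDDATA/{placeholder}", f"$ENDDATA/{data_end:012d}")

    def hdr(v: int) -> bytes:
        return (f"{v:>8d}" if v <= 99999999 else f"{0:>8d}").encode("ascii")

    header = b"FCS3.1    " + hdr(text_begin) + hdr(text_end)
    header += hdr(data_begin if data_end <= 99999999 else 0)
    header += hdr(data_end if data_end <= 99999999 else 0)
    header += hdr(0) + hdr(0)  # no ANALYSIS segment
    assert len(header) == _HEADER_SIZE, struct.error

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_body.encode("ascii"))
        fh.write(data)
    return str(path)


# ---------------------------------------------------------------------------
# Gate configuration
# ---------------------------------------------------------------------------


def _interval(obj) -> tuple[float, float]:
    if obj is None:
        return (-np.inf, np.inf)
    lo, hi = obj
    lo = -np.inf if lo is None else float(lo)
    hi = np.inf if hi is None else float(hi)
    return (lo, hi)


def load_gate_spec(path) -> GateSpec:
    """Load a gate chain from YAML.

    Schema: ``steps: [{name, x_marker, y_marker, x_interval: [lo, hi],
    y_interval: [lo, hi]}, ...]`` with ``null`` for an unbounded endpoint.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        steps = tuple(
            GateStep(
                name=s["name"],
                x_marker=s["x_marker"],
                y_marker=s["y_marker"],
                x_interval=_interval(s.get("x_interval")),
                y_interval=_interval(s.get("y_interval")),
            )
            for s in doc["steps"]
        )
    except KeyError as exc:
        raise ConfigError(f"gate config is missing key {exc}") from exc
    return GateSpec(steps=steps)


def cd4_gate_template(
    thresholds: dict[str, float] | None = None,
) -> GateSpec:
    """Sequential gate chain isolating live single CD4+ T helper cells.

    The chain mirrors the standard mass-cytometry strategy — DNA+ / cisplatin-
    live singlets, bead exclusion on 140Ce, CD45+ leukocytes, CD3+CD19- T
    cells, CD4+CD8- helpers.  Threshold positions depend on each experiment's
    staining and must be supplied by the user (values here are placeholders in
    asinh units).
    """
    t = {
        "dna_low": 1.0,
        "cisplatin_high": 1.0,
        "bead_high": 1.0,
        "cd45_low": 1.0,
        "cd3_low": 1.0,
        "cd19_high": 1.0,
        "cd4_low": 1.0,
        "cd8_high": 1.0,
    }
    if thresholds:
        t.update(thresholds)
    inf = np.inf
    return GateSpec(
        steps=(
            GateStep("live_singlets", "Ir191", "Pt195", (t["dna_low"], inf), (-inf, t["cisplatin_high"])),
            GateStep("bead_exclusion", "Ce140", "Ir191", (-inf, t["bead_high"]), (-inf, inf)),
            GateStep("leukocytes", "CD45", "Ir191", (t["cd45_low"], inf), (-inf, inf)),
            GateStep("t_cells", "CD3", "CD19", (t["cd3_low"], inf), (-inf, t["cd19_high"])),
            GateStep("cd4_helpers", "CD4", "CD8", (t["cd4_low"], inf), (-inf, t["cd8_high"])),
        )
    )


def warn_if_untransformed(table: EventTable) -> None:
    if not table.transformed:
        warnings.warn("EventTable is not arcsinh-transformed", stacklevel=3)
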