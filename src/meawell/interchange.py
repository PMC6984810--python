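"""Shared domain types and the spike-table interchange format.

The pipeline exchanges spike events through a plain-text tab-separated
table (one row per detected threshold crossing, waveform serialized
inline) whose header records the plate layout, the waveform window, and
per-recording metadata.  An optional Parquet container carries the same
schema for large tables.

Units are fixed throughout the package: seconds, microvolts (uV), Hz.
Timestamps are recording-relative and 0-based; electrode indices are
1-based within a well; wells are labelled row-letter + column-number
("A1" .. "H12" on a 96-well plate).
"""

from __future__ import annotations

import io
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "meawell-spikes-1"

#: mandatory spike-table columns, in output order
SPIKE_COLUMNS = [
    "well",
    "electrode",
    "recording_id",
    "timestamp_s",
    "crossing_threshold_uv",
    "waveform_uv",
]
OPTIONAL_COLUMNS = ["truth_neuron", "cluster_id"]


class SchemaError(ValueError):
    """A spike table violated the interchange schema."""


def waveform_samples(pre_ms: float, post_ms: float, rate: float) -> int:
    """Number of samples retained per spike waveform.

    The window spans ``pre_ms`` before and ``post_ms`` after the
    threshold crossing; the crossing sample itself is always kept, so
    the count is ``floor(pre_ms*rate/1000) + floor(post_ms*rate/1000) + 1``.
    At the instrument settings used throughout (1 ms pre, 2 ms post,
    12.5 kHz) this gives the familiar 38-sample vector, with the
    crossing at 0-based index 12.
    """
    if rate <= 0:
        raise ValueError(f"sampling rate must be positive, got {rate}")
    if pre_ms < 0 or post_ms < 0:
        raise ValueError("window durations must be non-negative")
    return int(math.floor(pre_ms * rate / 1000.0) + math.floor(post_ms * rate / 1000.0)) + 1


def crossing_index(pre_ms: float, rate: float) -> int:
    """0-based index of the threshold-crossing sample within a waveform."""
    return int(math.floor(pre_ms * rate / 1000.0))


def default_well_labels(n_rows: int, n_cols: int) -> list[str]:
    """Row-letter + column-number labels in row-major order (A1..H12)."""
    if n_rows > 26:
        raise ValueError("more than 26 plate rows not supported")
    return [f"{string.ascii_uppercase[r]}{c + 1}" for r in range(n_rows) for c in range(n_cols)]


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well MEA plate.

    The default is the 96-well, 8-electrode-per-well format sampled at
    12.5 kHz (768 simultaneously recorded channels).
    """

    n_rows: int = 8
    n_cols: int = 12
    electrodes_per_well: int = 8
    sampling_rate: float = 12500.0
    well_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0 or self.electrodes_per_well <= 0:
            raise ValueError("plate dimensions must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.well_labels:
            object.__setattr__(
                self, "well_labels", tuple(default_well_labels(self.n_rows, self.n_cols))
            )
        if len(self.well_labels) != self.n_rows * self.n_cols:
            raise ValueError("well_labels length must equal n_rows * n_cols")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_channels(self) -> int:
        """Total electrode count across the plate."""
        return self.n_wells * self.electrodes_per_well


@dataclass(frozen=True)
class RecordingMeta:
    """One recording session: its identifier, duration, and labels."""

    recording_id: str
    duration: float  # seconds
    div: int | None = None
    condition: str | None = None
    phase: str | None = None  # "pre" | "post" | "washout"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")


@dataclass
class SpikeEvent:
    """One detected threshold crossing with its waveform and provenance."""

    well: str
    electrode: int
    recording_id: str
    timestamp: float  # s from recording start
    crossing_threshold: float  # uV
    waveform: np.ndarray  # uV, fixed length per table
    truth_neuron: str | None = None  # simulator ground truth
    cluster_id: str | None = None  # assigned by sorting


@dataclass
class SpikeTable:
    """A validated collection of spike events plus plate/recording metadata."""

    layout: PlateLayout
    recordings: list[RecordingMeta]
    events: list[SpikeEvent]
    pre_ms: float = 1.0
    post_ms: float = 2.0
    extra_header: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()
        self.sort_events()

    # -- basic accessors -------------------------------------------------
    def recording(self, recording_id: str) -> RecordingMeta:
        for r in self.recordings:
            if r.recording_id == recording_id:
                return r
        raise KeyError(recording_id)

    @property
    def recording_ids(self) -> list[str]:
        return [r.recording_id for r in self.recordings]

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def waveform_length(self) -> int:
        return waveform_samples(self.pre_ms, self.post_ms, self.layout.sampling_rate)

    def sort_events(self) -> None:
        order = {rid: i for i, rid in enumerate(self.recording_ids)}
        self.events.sort(key=lambda e: (order[e.recording_id], e.well, e.electrode, e.timestamp))

    def validate(self) -> None:
        ids = self.recording_ids
        if len(set(ids)) != len(ids):
            raise SchemaError("recording_id values must be unique")
        wells = set(self.layout.well_labels)
        durations = {r.recording_id: r.duration for r in self.recordings}
        wlen = self.waveform_length
        for i, ev in enumerate(self.events):
            if ev.recording_id not in durations:
                raise SchemaError(f"event {i}: unknown recording_id {ev.recording_id!r}")
            if ev.well not in wells:
                raise SchemaError(f"event {i}: unknown well {ev.well!r}")
            if not (1 <= ev.electrode <= self.layout.electrodes_per_well):
                raise SchemaError(f"event {i}: electrode {ev.electrode} outside layout")
            if not (0.0 <= ev.timestamp <= durations[ev.recording_id]):
                raise SchemaError(f"event {i}: timestamp {ev.timestamp} outside recording")
            if ev.crossing_threshold <= 0:
                raise SchemaError(f"event {i}: non-positive crossing threshold")
            if len(ev.waveform) != wlen:
                raise SchemaError(
                    f"event {i}: waveform length {len(ev.waveform)} != expected {wlen}"
                )

    def subset(self, events: list[SpikeEvent]) -> "SpikeTable":
        """New table sharing layout/recordings with a different event list."""
        return SpikeTable(
            layout=self.layout,
            recordings=list(self.recordings),
            events=events,
            pre_ms=self.pre_ms,
            post_ms=self.post_ms,
            extra_header=dict(self.extra_header),
        )

    def to_frame(self) -> pd.DataFrame:
        """Events as a DataFrame (waveforms as ndarray objects)."""
        return pd.DataFrame(
            {
                "well": [e.well for e in self.events],
                "electrode": [e.electrode for e in self.events],
                "recording_id": [e.recording_id for e in self.events],
                "timestamp_s": [e.timestamp for e in self.events],
                "crossing_threshold_uv": [e.crossing_threshold for e in self.events],
                "waveform_uv": [e.waveform for e in self.events],
                "truth_neuron": [e.truth_neuron for e in self.events],
                "cluster_id": [e.cluster_id for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# serialization

_TS_DECIMALS = 6  # 1 us
_UV_DECIMALS = 3  # 0.001 uV


def _fmt_wave(w: np.ndarray) -> str:
    return ";".join(f"{v:.{_UV_DECIMALS}f}" for v in w)


def _layout_header(layout: PlateLayout) -> str:
    return (
        f"#layout=rows:{layout.n_rows},cols:{layout.n_cols},"
        f"electrodes_per_well:{layout.electrodes_per_well}"
    )


def _recording_header(r: RecordingMeta) -> str:
    parts = [f"id:{r.recording_id}", f"duration_s:{r.duration!r}"]
    if r.div is not None:
        parts.append(f"div:{r.div}")
    if r.condition is not None:
        parts.append(f"condition:{r.condition}")
    if r.phase is not None:
        parts.append(f"phase:{r.phase}")
    return "#recording=" + ",".join(parts)


def write_spike_table(table: SpikeTable, path, format: str = "tsv") -> None:
    """Write a spike table; deterministic bytes for identical input."""
    if format == "parquet":
        _write_parquet(table, path)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    buf = io.StringIO()
    buf.write(f"#schema={SCHEMA_VERSION}\n")
    buf.write(f"#rate_hz={table.layout.sampling_rate!r}\n")
    buf.write(f"#pre_ms={table.pre_ms!r}\n")
    buf.write(f"#post_ms={table.post_ms!r}\n")
    buf.write(_layout_header(table.layout) + "\n")
    for r in table.recordings:
        buf.write(_recording_header(r) + "\n")
    for k, v in sorted(table.extra_header.items()):
        buf.write(f"#{k}={v}\n")
    cols = SPIKE_COLUMNS + OPTIONAL_COLUMNS
    buf.write("\t".join(cols) + "\n")
    for e in table.events:
        row = [
            e.well,
            str(e.electrode),
            e.recording_id,
            f"{e.timestamp:.{_TS_DECIMALS}f}",
            f"{e.crossing_threshold:.{_UV_DECIMALS}f}",
            _fmt_wave(np.asarray(e.waveform, dtype=float)),
            e.truth_neuron or "",
            e.cluster_id or "",
        ]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _parse_kv(line: str) -> dict:
    out = {}
    for part in line.split(","):
        k, _, v = part.partition(":")
        out[k] = v
    return out


def read_spike_table(path, format: str = "tsv") -> SpikeTable:
    """Read and validate a spike table written by :func:`write_spike_table`."""
    if format == "parquet":
        return _read_parquet(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    header: dict[str, str] = {}
    recordings: list[RecordingMeta] = []
    layout_kv = None
    data_lines: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for ln in lines:
        if ln.startswith("#recording="):
            kv = _parse_kv(ln[len("#recording="):])
            recordings.append(
                RecordingMeta(
                    recording_id=kv["id"],
                    duration=float(kv["duration_s"]),
                    div=int(kv["div"]) if "div" in kv else None,
                    condition=kv.get("condition"),
                    phase=kv.get("phase"),
                )
            )
        elif ln.startswith("#layout="):
            layout_kv = _parse_kv(ln[len("#layout="):])
        elif ln.startswith("#"):
            k, _, v = ln[1:].partition("=")
            header[k] = v
        else:
            data_lines.append(ln)
    if header.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema {header.get('schema')!r}")
    if layout_kv is None:
        raise SchemaError("missing #layout header")
    layout = PlateLayout(
        n_rows=int(layout_kv["rows"]),
        n_cols=int(layout_kv["cols"]),
        electrodes_per_well=int(layout_kv["electrodes_per_well"]),
        sampling_rate=float(header["rate_hz"]),
    )
    pre_ms = float(header["pre_ms"])
    post_ms = float(header["post_ms"])
    extra = {
        k: v
        for k, v in header.items()
        if k not in {"schema", "rate_hz", "pre_ms", "post_ms"}
    }

    if not data_lines:
        raise SchemaError("missing column header line")
    cols = data_lines[0].split("\t")
    missing = [c for c in SPIKE_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    idx = {c: i for i, c in enumerate(cols)}
    events: list[SpikeEvent] = []
    for rowno, ln in enumerate(data_lines[1:], start=1):
        f = ln.split("\t")
        if len(f) != len(cols):
            raise SchemaError(f"row {rowno}: expected {len(cols)} fields, got {len(f)}")
        try:
            wave = np.array(
                [float(x) for x in f[idx["waveform_uv"]].split(";")], dtype=float
            )
            ev = SpikeEvent(
                well=f[idx["well"]],
                electrode=int(f[idx["electrode"]]),
                recording_id=f[idx["recording_id"]],
                timestamp=float(f[idx["timestamp_s"]]),
                crossing_threshold=float(f[idx["crossing_threshold_uv"]]),
                waveform=wave,
                truth_neuron=(f[idx["truth_neuron"]] or None) if "truth_neuron" in idx else None,
                cluster_id=(f[idx["cluster_id"]] or None) if "cluster_id" in idx else None,
            )
        except (ValueError, IndexError) as exc:
            raise SchemaError(f"row {rowno}: {exc}") from exc
        events.append(ev)
    try:
        return SpikeTable(
            layout=layout,
            recordings=recordings,
            events=events,
            pre_ms=pre_ms,
            post_ms=post_ms,
            extra_header=extra,
        )
    except SchemaError:
        raise
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def _write_parquet(table: SpikeTable, path) -> None:
    import pyarrow as pa
    import pyarrow.parquet as pq

    df = table.to_frame()
    df["waveform_uv"] = [np.asarray(w, dtype=float).tolist() for w in df["waveform_uv"]]
    meta = {
        "schema": SCHEMA_VERSION,
        "rate_hz": repr(table.layout.sampling_rate),
        "pre_ms": repr(table.pre_ms),
        "post_ms": repr(table.post_ms),
        "layout": (
            f"rows:{table.layout.n_rows},cols:{table.layout.n_cols},"
            f"electrodes_per_well:{table.layout.electrodes_per_well}"
        ),
        "recordings": "|".join(_recording_header(r)[len("#recording="):] for r in table.recordings),
    }
    t = pa.Table.from_pandas(df, preserve_index=False)
    t = t.replace_schema_metadata({k.encode(): v.encode() for k, v in meta.items()})
    pq.write_table(t, path)


def _read_parquet(path) -> SpikeTable:
    import pyarrow.parquet as pq

    t = pq.read_table(path)
    meta = {k.decode(): v.decode() for k, v in (t.schema.metadata or {}).items() if not k.startswith(b"pandas")}
    if meta.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema {meta.get('schema')!r}")
    layout_kv = _parse_kv(meta["layout"])
    layout = PlateLayout(
        n_rows=int(layout_kv["rows"]),
        n_cols=int(layout_kv["cols"]),
        electrodes_per_well=int(layout_kv["electrodes_per_well"]),
        sampling_rate=float(meta["rate_hz"]),
    )
    recordings = []
    for chunk in meta["recordings"].split("|"):
        kv = _parse_kv(chunk)
        recordings.append(
            RecordingMeta(
                recording_id=kv["id"],
                duration=float(kv["duration_s"]),
                div=int(kv["div"]) if "div" in kv else None,
                condition=kv.get("condition"),
                phase=kv.get("phase"),
            )
        )
    df = t.to_pandas()
    events = [
        SpikeEvent(
            well=r.well,
            electrode=int(r.electrode),
            recording_id=r.recording_id,
            timestamp=float(r.timestamp_s),
            crossing_threshold=float(r.crossing_threshold_uv),
            waveform=np.asarray(r.waveform_uv, dtype=float),
            truth_neuron=r.truth_neuron if isinstance(r.truth_neuron, str) else None,
            cluster_id=r.cluster_id if isinstance(r.cluster_id, str) else None,
        )
        for r in df.itertuples()
    ]
    return SpikeTable(
        layout=layout,
        recordings=recordings,
        events=events,
        pre_ms=float(meta["pre_ms"]),
        post_ms=float(meta["post_ms"]),
    )


# ---------------------------------------------------------------------------
# plate map

def read_plate_map(path) -> pd.DataFrame:
    """Read a `well, group, include` delimited plate map."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = {"well", "group"} - set(df.columns)
    if missing:
        raise SchemaError(f"plate map missing column(s): {sorted(missing)}")
    if "include" not in df.columns:
        df["include"] = True
    return df


def write_plate_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
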