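"""Session and trace containers plus their on-disk formats.

A *session* is one recording trial: a raw multi-channel waveform matrix, a
channel map (which contact of which paddle each column is), and an event
timeline (infusion, retch, distension, feeding, artifact marks).  Sessions are
stored as a human-inspectable pair of files in a directory::

    session_dir/
        waveform.csv   # time_s + one column per channel, mV
        session.json   # fs_native, channel map, events, session_id

Processed (paddle-level, 10 Hz) traces use the same CSV + JSON-sidecar idea.
All times are seconds from recording start; sample indexing is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Event",
    "SessionRecording",
    "ProcessedTrace",
    "Segment",
    "read_session",
    "write_session",
    "read_trace",
    "write_trace",
    "FormatError",
    "ConsistencyError",
]

#: event kinds with defined pipeline semantics; unknown kinds are preserved.
KNOWN_EVENT_KINDS = frozenset(
    {
        "infusion_start",
        "first_retch",
        "distension_start",
        "distension_end",
        "food_presented",
        "food_removed",
        "artifact",
    }
)

# numeric precision of the CSV container (decimal digits after the point)
CSV_DECIMALS = 9


class FormatError(ValueError):
    """A session directory is missing pieces or malformed."""


class ConsistencyError(ValueError):
    """Sidecar metadata disagrees with the waveform table."""


@dataclass(frozen=True)
class Channel:
    """One electrode contact: paddles are lettered A-F, contacts numbered 1-4."""

    channel_id: str
    paddle_id: str
    contact_index: int


@dataclass(frozen=True)
class Event:
    kind: str
    time_s: float


@dataclass
class SessionRecording:
    """Raw multi-channel recording of one trial.

    ``samples`` is ``[n_samples, n_channels]`` in mV, column order matching
    ``channels``.
    """

    session_id: str
    fs_native: float
    channels: list[Channel]
    samples: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_native <= 0:
            raise ValueError(f"fs_native must be > 0, got {self.fs_native}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D [n_samples, n_channels]")
        if self.samples.shape[1] != len(self.channels):
            raise ConsistencyError(
                f"{len(self.channels)} channels declared but waveform has "
                f"{self.samples.shape[1]} columns"
            )
        counts: dict[str, int] = {}
        for ch in self.channels:
            counts[ch.paddle_id] = counts.get(ch.paddle_id, 0) + 1
        for paddle, n in counts.items():
            if not 1 <= n <= 4:
                raise ValueError(f"paddle {paddle!r} has {n} contacts (need 1-4)")
        dur = self.duration_s
        for ev in self.events:
            if not 0 <= ev.time_s <= dur:
                raise ValueError(
                    f"event {ev.kind!r} at {ev.time_s} s outside [0, {dur:.3f}]"
                )
        t_inf = self.event_time("infusion_start")
        t_retch = self.event_time("first_retch")
        if t_inf is not None and t_retch is not None and t_retch <= t_inf:
            raise ValueError("first_retch must occur after infusion_start")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_native

    @property
    def paddle_ids(self) -> list[str]:
        seen: list[str] = []
        for ch in self.channels:
            if ch.paddle_id not in seen:
                seen.append(ch.paddle_id)
        return seen

    def event_time(self, kind: str) -> float | None:
        """Time of the first event of ``kind``, or None."""
        for ev in self.events:
            if ev.kind == kind:
                return ev.time_s
        return None

    def paddle_columns(self, paddle_id: str) -> list[int]:
        cols = [i for i, ch in enumerate(self.channels) if ch.paddle_id == paddle_id]
        if not cols:
            raise KeyError(f"unknown paddle_id {paddle_id!r}")
        return cols


@dataclass
class ProcessedTrace:
    """One paddle-averaged or bipolar-differenced waveform after the filter
    cascade, at the 10 Hz analysis rate.

    ``blanked_windows`` are (start_s, end_s) intervals whose samples were
    replaced by the trace median before filtering; the samples are marked,
    never deleted, so trace length and timing are preserved.
    """

    source_id: str
    fs: float
    samples: np.ndarray
    blanked_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        dur = self.duration_s
        for lo, hi in self.blanked_windows:
            if not (0 <= lo < hi <= dur + 1e-9):
                raise ValueError(f"blanked window ({lo}, {hi}) outside trace extent")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class Segment:
    """One 1-min analysis window of a processed trace.

    ``excluded`` marks overlap with a blanked (artifact) window; excluded
    segments are carried through segmentation but skipped by the feature
    extractor.
    """

    source_id: str
    index: int
    start_s: float
    fs: float
    samples: np.ndarray
    excluded: bool = False


# ---------------------------------------------------------------------------
# session container


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write ``rec`` to ``path`` as waveform.csv + session.json.

    Lossless to :data:`CSV_DECIMALS` decimal digits.  Returns the directory.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs_native
    df = pd.DataFrame({"time_s": t})
    for j, ch in enumerate(rec.channels):
        df[ch.channel_id] = rec.samples[:, j]
    df.to_csv(path / "waveform.csv", index=False, float_format=f"%.{CSV_DECIMALS}g")
    sidecar = {
        "session_id": rec.session_id,
        "fs_native": rec.fs_native,
        "channels": [
            {
                "channel_id": ch.channel_id,
                "paddle_id": ch.paddle_id,
                "contact_index": ch.contact_index,
            }
            for ch in rec.channels
        ],
        "events": [{"kind": ev.kind, "time_s": ev.time_s} for ev in rec.events],
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`FormatError` if the sidecar or waveform is missing, and
    :class:`ConsistencyError` if the sidecar channel count disagrees with the
    waveform table.  Unknown event kinds are preserved verbatim.
    """
    path = Path(path)
    sidecar_path = path / "session.json"
    wave_path = path / "waveform.csv"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not wave_path.exists():
        raise FormatError(f"missing waveform table {wave_path}")
    meta = json.loads(sidecar_path.read_text())
    channels = [
        Channel(c["channel_id"], c["paddle_id"], int(c["contact_index"]))
        for c in meta["channels"]
    ]
    df = pd.read_csv(wave_path)
    data_cols = [c for c in df.columns if c != "time_s"]
    if len(data_cols) != len(channels):
        raise ConsistencyError(
            f"sidecar lists {len(channels)} channels, waveform table has "
            f"{len(data_cols)} data columns"
        )
    samples = df[[ch.channel_id for ch in channels]].to_numpy(dtype=float)
    events = [Event(e["kind"], float(e["time_s"])) for e in meta.get("events", [])]
    return SessionRecording(
        session_id=meta["session_id"],
        fs_native=float(meta["fs_native"]),
        channels=channels,
        samples=samples,
        events=events,
    )


# ---------------------------------------------------------------------------
# processed-trace container


def _trace_stem(source_id: str) -> str:
    return source_id.replace(":", "_").replace("-", "_")


def write_trace(trace: ProcessedTrace, directory: str | Path) -> Path:
    """Serialize one processed trace as <stem>.csv + <stem>.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _trace_stem(trace.source_id)
    t = np.arange(len(trace.samples)) / trace.fs
    pd.DataFrame({"time_s": t, "value_mV": trace.samples}).to_csv(
        directory / f"{stem}.csv", index=False, float_format=f"%.{CSV_DECIMALS}g"
    )
    meta = {
        "source_id": trace.source_id,
        "fs": trace.fs,
        "blanked_windows": [list(w) for w in trace.blanked_windows],
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{stem}.csv"


def read_trace(csv_path: str | Path) -> ProcessedTrace:
    csv_path = Path(csv_path)
    meta_path = csv_path.with_suffix(".json")
    if not meta_path.exists():
        raise FormatError(f"missing trace sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path)
    return ProcessedTrace(
        source_id=meta["source_id"],
        fs=float(meta["fs"]),
        samples=df["value_mV"].to_numpy(dtype=float),
        blanked_windows=[tuple(w) for w in meta.get("blanked_windows", [])],
    )


def list_traces(directory: str | Path) -> list[Path]:
    """All trace CSVs in a directory (those with a JSON sidecar)."""
    directory = Path(directory)
    return sorted(
        p
        for p in directory.glob("*.csv")
        if p.with_suffix(".json").exists() and p.name != "waveform.csv"
    )
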