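"""Containers and I/O for multichannel nerve-cuff recordings.

A :class:`Recording` bundles the raw channels-by-samples matrix with its
sampling rate, channel identifiers and the stimulus annotation track
(:class:`StimulusEvent`).  Two on-disk layouts are supported:

``binary``
    Flat little-endian array, channel-major (row per channel), next to a
    JSON sidecar ``<stem>.json`` holding ``fs``, ``channel_ids``, the
    events and the array dtype/shape.  Round-trips are bit-exact.
``csv``
    Samples as rows, channels as columns, header row of channel ids; the
    same JSON sidecar carries the metadata.  Round-trips are exact to the
    printed decimal precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusEvent",
    "Recording",
    "load_recording",
    "save_recording",
    "extract_epochs",
]

#: steady-state trim applied at both ends of each stimulus (seconds)
DEFAULT_TRIM_S = 0.25


@dataclass(frozen=True)
class StimulusEvent:
    """A single proprioceptive stimulus annotation.

    Parameters
    ----------
    onset_s : float
        Stimulus onset, seconds from recording start.
    duration_s : float
        Stimulus (ON phase) duration in seconds.
    label : int | float | str
        Class identifier; in the emulated experiment, the hindlimb angle
        in degrees.
    """

    onset_s: float
    duration_s: float
    label: object

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")


@dataclass
class Recording:
    """Multichannel extracellular recording with stimulus annotations.

    ``data`` is ``(n_channels, n_samples)``; ``channel_ids`` follow the
    row order of ``data``.
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str] = None
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) matrix")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must have at least one channel and one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        dur = self.duration_s
        for k, ev in enumerate(self.events):
            if ev.onset_s + ev.duration_s > dur + 0.5 / self.fs:
                raise ValueError(
                    f"event {k} (label={ev.label!r}, onset={ev.onset_s}s, "
                    f"duration={ev.duration_s}s) extends past the recording "
                    f"end at {dur}s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        """Return one channel's samples by id."""
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None
        return self.data[idx]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _events_to_json(events: list[StimulusEvent]) -> list[dict]:
    return [
        {"onset_s": ev.onset_s, "duration_s": ev.duration_s, "label": ev.label}
        for ev in events
    ]


def _events_from_json(raw: list[dict]) -> list[StimulusEvent]:
    return [
        StimulusEvent(onset_s=d["onset_s"], duration_s=d["duration_s"], label=d["label"])
        for d in raw
    ]


def save_recording(
    rec: Recording, path: str | Path, format: Literal["binary", "csv"] = "binary"
) -> None:
    """Write a recording and its JSON metadata sidecar to disk."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "channel_ids": rec.channel_ids,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": str(rec.data.dtype),
        "format": format,
        "events": _events_to_json(rec.events),
    }
    if format == "binary":
        # channel-major, little-endian; dtype recorded in the sidecar
        rec.data.astype(rec.data.dtype.newbyteorder("<"), copy=False).tofile(path)
    elif format == "csv":
        header = ",".join(rec.channel_ids)
        np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="", fmt="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path, format: Literal["binary", "csv"] | None = None) -> Recording:
    """Read a recording written by :func:`save_recording`.

    ``format`` defaults to what the sidecar declares.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    if format is None:
        format = meta.get("format", "binary")
    if format == "binary":
        dtype = np.dtype(meta.get("dtype", "float64")).newbyteorder("<")
        data = np.fromfile(path, dtype=dtype).reshape(
            meta["n_channels"], meta["n_samples"]
        )
    elif format == "csv":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    else:
        raise ValueError(f"unknown format {format!r}")
    return Recording(
        data=data,
        fs=meta["fs"],
        channel_ids=meta["channel_ids"],
        events=_events_from_json(meta["events"]),
    )


def extract_epochs(
    rec: Recording,
    phase: Literal["on", "off"] = "on",
    trim_s: float = DEFAULT_TRIM_S,
) -> list[tuple[object, np.ndarray]]:
    """Slice event-aligned steady-state epochs from a recording.

    For ``phase="on"`` each epoch spans ``[onset + trim, onset + duration
    - trim]`` — the steady-state response with the movement transients at
    both ends removed.  For ``phase="off"`` the interval of the same
    nominal duration immediately after stimulus offset is taken (clipped
    at the next onset / recording end) and trimmed the same way.

    Epochs too short to survive the trim are skipped with a warning
    rather than aborting the run.  Spans are half-open ``[start, stop)``
    in samples, 0-based, ``onset_s`` mapped via ``round(onset_s * fs)``.

    Returns
    -------
    list of (label, epoch) with epoch shaped (n_channels, epoch_samples).
    """
    if not rec.events:
        raise ValueError("recording has no stimulus events")
    out: list[tuple[object, np.ndarray]] = []
    onsets = sorted(ev.onset_s for ev in rec.events)
    for k, ev in enumerate(rec.events):
        if phase == "on":
            t0, t1 = ev.onset_s, ev.onset_s + ev.duration_s
        elif phase == "off":
            t0 = ev.onset_s + ev.duration_s
            t1 = t0 + ev.duration_s
            nxt = [o for o in onsets if o > ev.onset_s]
            if nxt:
                t1 = min(t1, nxt[0])
            t1 = min(t1, rec.duration_s)
        else:
            raise ValueError(f"unknown phase {phase!r}")
        start = int(round((t0 + trim_s) * rec.fs))
        stop = int(round((t1 - trim_s) * rec.fs))
        if stop <= start:
            warnings.warn(
                f"event {k} (label={ev.label!r}): {phase.upper()} span of "
                f"{t1 - t0:.3f}s is shorter than 2 x trim ({2 * trim_s:.3f}s); skipped"
            )
            continue
        out.append((ev.label, rec.data[:, start:stop]))
    return out
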