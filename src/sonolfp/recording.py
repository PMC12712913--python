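"""Recording container and file I/O.

A :class:`Recording` holds a multichannel extracellular voltage time series in
microvolts together with its sampling rate, stimulation onset times extracted
from a sync channel, channel labels, and free-form metadata (group label,
intensity level, phase boundaries, ...).

Two on-disk layouts are supported, both accompanied by a JSON metadata sidecar
(``<path>.json``):

* delimited text — one column per channel with a header row of channel ids;
* binary — interleaved little-endian float32 frames.

Times are in seconds, zero-based from the recording start; stimulation onsets
are rising edges of the sync pulse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "extract_sync_onsets",
]


class RecordingStructureError(ValueError):
    """Raised when a file's structure is inconsistent with its metadata."""


@dataclass
class Recording:
    """Multichannel voltage recording (channels x time, µV).

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Recording start time in seconds (default 0).
    stim_onsets : array-like of float
        Ultrasound stimulation onset times in seconds, strictly increasing,
        all inside the recording.
    channel_ids : list of str, optional
        Channel labels; defaults to ``ch0, ch1, ...``.
    meta : dict
        Free-form metadata (group, intensity, phase boundaries, units, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    stim_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise RecordingStructureError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )
        if self.stim_onsets.size:
            if np.any(np.diff(self.stim_onsets) <= 0):
                raise ValueError("stim_onsets must be strictly increasing")
            end = self.t0 + self.n_samples / self.fs
            if self.stim_onsets[0] < self.t0 or self.stim_onsets[-1] > end:
                raise ValueError(
                    f"stim_onsets must lie within [{self.t0}, {end}]"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def extract_sync_onsets(
    sync: np.ndarray,
    fs: float,
    threshold: float,
    refractory: float = 0.3,
) -> np.ndarray:
    """Rising-edge onset times of a sync pulse train.

    Parameters
    ----------
    sync : 1-D array
        Sync-channel voltage trace.
    fs : float
        Sampling rate (Hz).
    threshold : float
        Crossing level, strictly between the baseline and pulse levels.
    refractory : float
        Edges closer than this window (s) to the previous accepted edge are
        merged into it; defaults to the protocol sonication duration so that
        within-burst pulse-repetition edges are not double counted.

    Returns
    -------
    ndarray of onset times in seconds (empty when there is no crossing).
    """
    sync = np.asarray(sync, dtype=float).ravel()
    above = sync >= threshold
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        edges = np.insert(edges, 0, 0)
    times = edges / fs
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_recording(rec: Recording, path: str | Path, format: str = "delimited") -> Path:
    """Write a recording plus its JSON sidecar; returns the data path."""
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "t0": rec.t0,
        "n_channels": rec.n_channels,
        "channel_ids": list(rec.channel_ids),
        "units": "uV",
        "format": format,
        "stim_onsets": [float(t) for t in rec.stim_onsets],
        "meta": rec.meta,
    }
    if format == "delimited":
        df = pd.DataFrame(rec.samples.T, columns=rec.channel_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif format == "binary":
        rec.samples.T.astype("<f4").tofile(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(
    path: str | Path,
    format: str | None = None,
    sync_channel: str | None = None,
    sync_threshold: float | None = None,
    sync_refractory: float = 0.3,
) -> Recording:
    """Read a recording written by :func:`write_recording`.

    When ``sync_channel`` names a channel (or the sidecar carries a
    ``"sync_channel"`` key), that channel is consumed: its rising edges become
    ``stim_onsets`` and it is removed from ``samples``. The threshold defaults
    to half the sync channel's peak value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RecordingStructureError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    fmt = format or meta.get("format", "delimited")
    channel_ids = list(meta["channel_ids"])
    if fmt == "delimited":
        df = pd.read_csv(path, sep="\t")
        if df.shape[0] == 0:
            raise RecordingStructureError(f"{path} contains no samples")
        if list(df.columns) != channel_ids:
            raise RecordingStructureError(
                f"channel header {list(df.columns)} does not match sidecar {channel_ids}"
            )
        samples = df.to_numpy().T
    elif fmt == "binary":
        raw = np.fromfile(path, dtype="<f4")
        n_ch = int(meta["n_channels"])
        if raw.size == 0:
            raise RecordingStructureError(f"{path} is empty")
        if raw.size % n_ch:
            raise RecordingStructureError(
                f"{raw.size} values are not a whole number of {n_ch}-channel frames"
            )
        samples = raw.reshape(-1, n_ch).T.astype(float)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    onsets = np.asarray(meta.get("stim_onsets", []), dtype=float)
    sync_name = sync_channel or meta.get("sync_channel")
    if sync_name is not None:
        if sync_name not in channel_ids:
            raise RecordingStructureError(f"sync channel {sync_name!r} not found")
        idx = channel_ids.index(sync_name)
        sync = samples[idx]
        thr = sync_threshold if sync_threshold is not None else 0.5 * np.max(np.abs(sync))
        onsets = extract_sync_onsets(sync, meta["fs"], thr, sync_refractory)
        samples = np.delete(samples, idx, axis=0)
        channel_ids = [c for c in channel_ids if c != sync_name]
    return Recording(
        samples=samples,
        fs=float(meta["fs"]),
        t0=float(meta.get("t0", 0.0)),
        stim_onsets=onsets,
        channel_ids=channel_ids,
        meta=dict(meta.get("meta", {})),
    )
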