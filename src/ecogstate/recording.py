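"""Multichannel recording container and lightweight on-disk loaders.

The in-memory unit of the package is :class:`Recording`: a channels x samples
float array with a sampling rate, channel labels, a wall-clock start time and
an amplitude unit taken verbatim from the file header.  Loaders are provided
for a plain binary + JSON-sidecar format (used for fixtures and by the
synthetic generator) and, best-effort, for EDF files through :mod:`mne`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = ["Recording", "load_raw", "save_raw", "read_edf"]

_DEFAULT_START = datetime(2000, 1, 1, 0, 0, 0)


@dataclass
class Recording:
    """A channels x samples time series in physical units.

    Parameters
    ----------
    data
        2-D float array, shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz; must be positive.
    channel_labels
        Unique label per channel, same order as the rows of ``data``.
    start_time
        Wall-clock timestamp of the first sample.
    unit
        Amplitude unit string from the acquisition header (e.g. ``"mV"``).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: datetime = _DEFAULT_START
    unit: str = "mV"
    source_file: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Copy of this recording with new sample data (labels etc. kept)."""
        return replace(self, data=data, **changes)

    def pick(self, labels: list[str]) -> "Recording":
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(self, data=self.data[idx], channel_labels=list(labels))


def save_raw(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as float32 little-endian binary with a JSON sidecar.

    ``path`` names the binary file; the sidecar is ``path.with_suffix('.json')``.
    """
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    header = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": rec.channel_labels,
        "start_time": rec.start_time.isoformat(),
        "unit": rec.unit,
        "dtype": "<f4",
        "order": "C",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def load_raw(path: str | Path) -> Recording:
    """Load a recording written by :func:`save_raw`."""
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=header.get("dtype", "<f4"))
    data = data.reshape(header["n_channels"], header["n_samples"]).astype(float)
    return Recording(
        data=data,
        fs=header["fs"],
        channel_labels=list(header["channel_labels"]),
        start_time=datetime.fromisoformat(header["start_time"]),
        unit=header.get("unit", "mV"),
        source_file=str(path),
    )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    start = raw.info["meas_date"]
    start_dt = (
        datetime.fromtimestamp(start.timestamp()) if start is not None else _DEFAULT_START
    )
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=start_dt,
        unit="V",  # mne converts EDF physical dimensions to SI volts
        source_file=str(path),
    )
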