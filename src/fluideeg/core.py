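"""Shared containers and plain-text I/O for multichannel recordings.

The central object is :class:`MultichannelSeries`, a channels x samples
matrix with a sampling rate. All dynamics analyses consume it; the
preprocessing stage (lowpass + 40 ms coarse-graining) turns a raw 1 kHz
recording into the 25 Hz topography trajectory ``u_t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FluideegError(Exception):
    """Base class for package errors."""


class InvalidArgument(FluideegError, ValueError):
    """An argument violates a documented precondition."""


@dataclass
class MultichannelSeries:
    """A channels x samples real matrix with sampling rate.

    Parameters
    ----------
    values
        Array of shape (n_channels, n_samples); amplitude in µV or
        arbitrary units.
    rate
        Sampling rate in samples/s; must be positive.
    channel_names
        One name per channel, order matching the rows of ``values``.
    meta
        Provenance: filters applied, coarse-grain window, phase
        boundaries, reference scheme, generator parameters.
    """

    values: np.ndarray
    rate: float
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgument("values must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise InvalidArgument("rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.values.shape[0])]
        if len(self.channel_names) != self.values.shape[0]:
            raise InvalidArgument("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, values: np.ndarray | None = None, **meta_updates) -> "MultichannelSeries":
        new_meta = dict(self.meta)
        new_meta.update(meta_updates)
        return MultichannelSeries(
            values=self.values.copy() if values is None else values,
            rate=new_meta.pop("rate", self.rate),
            channel_names=list(self.channel_names),
            meta=new_meta,
        )


def save_series(series: MultichannelSeries, matrix_path: str | Path) -> None:
    """Write a series as a plain TSV matrix plus a JSON sidecar.

    The matrix file holds one row per channel; the sidecar
    (``<matrix>.json``) records channel names, rate and meta.
    """
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, series.values, delimiter="\t")
    sidecar = {
        "channel_names": series.channel_names,
        "rate": series.rate,
        "meta": _jsonable(series.meta),
    }
    matrix_path.with_suffix(matrix_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def load_series(matrix_path: str | Path) -> MultichannelSeries:
    """Read a series written by :func:`save_series`."""
    matrix_path = Path(matrix_path)
    values = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    sidecar_path = matrix_path.with_suffix(matrix_path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    else:
        raise FluideegError(f"missing sidecar {sidecar_path}")
    return MultichannelSeries(
        values=values,
        rate=float(sidecar["rate"]),
        channel_names=list(sidecar["channel_names"]),
        meta=dict(sidecar.get("meta", {})),
    )


def load_edf(path: str | Path) -> MultichannelSeries:
    """Read an EDF recording into a MultichannelSeries (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise FluideegError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelSeries(
        values=raw.get_data(),
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        meta={"source": str(path), "format": "edf"},
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
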