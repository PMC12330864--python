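"""Raw recording -> coarse-grained trajectory.

The dynamics analyses consume a low-rate topography trajectory obtained
from the 1 kHz recording by (1) rejecting faulty channels, (2) zero-phase
lowpass filtering at 100 Hz, and (3) non-overlapping 40 ms block
averaging, which brings the series to 25 Hz and matches the behavioral
video frame rate. A subject with more than five faulty channels is
flagged for exclusion from the study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import FluideegError, InvalidArgument, MultichannelSeries

#: More than this many rejected channels flags the subject for exclusion.
MAX_FAULTY_CHANNELS = 5


@dataclass
class ChannelRejectionReport:
    rejected_channels: list[str]
    n_rejected: int
    subject_excluded: bool


def reject_channels(
    series: MultichannelSeries,
    reject_list: list[str] | None = None,
    flat_variance_threshold: float = 1e-12,
    saturation_threshold: float | None = None,
    saturation_fraction: float = 0.1,
) -> tuple[MultichannelSeries, ChannelRejectionReport]:
    """Drop faulty channels; flag the subject if more than 5 are faulty.

    Faulty means: explicitly listed in ``reject_list``, or flatlined
    (variance below ``flat_variance_threshold``), or saturated
    (``|x| >= saturation_threshold`` for more than ``saturation_fraction``
    of samples, when a saturation threshold is given). Channel order of
    the survivors is preserved.
    """
    if reject_list is not None:
        unknown = set(reject_list) - set(series.channel_names)
        if unknown:
            raise InvalidArgument(f"unknown channels in reject list: {sorted(unknown)}")
        bad = set(reject_list)
    else:
        if flat_variance_threshold <= 0:
            raise InvalidArgument("flat_variance_threshold must be positive")
        variances = series.values.var(axis=1)
        bad = {
            name
            for name, v in zip(series.channel_names, variances)
            if v < flat_variance_threshold
        }
        if saturation_threshold is not None:
            if saturation_threshold <= 0:
                raise InvalidArgument("saturation_threshold must be positive")
            sat = (np.abs(series.values) >= saturation_threshold).mean(axis=1)
            bad |= {
                name
                for name, frac in zip(series.channel_names, sat)
                if frac > saturation_fraction
            }
    keep = [i for i, name in enumerate(series.channel_names) if name not in bad]
    if not keep:
        raise FluideegError("all channels rejected")
    report = ChannelRejectionReport(
        rejected_channels=[n for n in series.channel_names if n in bad],
        n_rejected=len(bad),
        subject_excluded=len(bad) > MAX_FAULTY_CHANNELS,
    )
    out = MultichannelSeries(
        values=series.values[keep],
        rate=series.rate,
        channel_names=[series.channel_names[i] for i in keep],
        meta={**series.meta, "rejected_channels": report.rejected_channels},
    )
    return out, report


def lowpass_filter(
    series: MultichannelSeries, cutoff_hz: float = 100.0, order: int = 4
) -> MultichannelSeries:
    """Zero-phase (forward-backward) Butterworth lowpass, per channel.

    Zero-phase filtering avoids latency distortion of the topography
    trajectory; DC is preserved.
    """
    nyquist = series.rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise InvalidArgument(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=series.rate, output="sos")
    filtered = sosfiltfilt(sos, series.values, axis=1)
    return series.copy_with(
        values=filtered, lowpass_hz=cutoff_hz, lowpass_order=order
    )


def coarse_grain(
    series: MultichannelSeries, window_ms: float = 40.0, method: str = "mean"
) -> MultichannelSeries:
    """Non-overlapping block average over a fixed time window.

    At the 40 ms default on a 1 kHz recording this yields the 25 Hz
    trajectory aligned with the behavioral video frame rate. A trailing
    partial block is dropped (a partial mean would be biased).
    ``method='decimate'`` keeps the first sample of each block instead of
    the mean.
    """
    window_samples = series.rate * window_ms / 1000.0
    if window_samples < 1:
        raise InvalidArgument("window shorter than one sample")
    if abs(window_samples - round(window_samples)) > 1e-9:
        warnings.warn(
            f"window of {window_ms} ms is not an integer number of samples at "
            f"{series.rate} Hz; truncating to {int(window_samples)} samples"
        )
    w = int(np.floor(window_samples + 1e-9))
    n_blocks = series.n_samples // w
    if n_blocks == 0:
        raise InvalidArgument("series shorter than one coarse-grain window")
    trimmed = series.values[:, : n_blocks * w]
    blocks = trimmed.reshape(series.n_channels, n_blocks, w)
    if method == "mean":
        values = blocks.mean(axis=2)
    elif method == "decimate":
        values = blocks[:, :, 0]
    else:
        raise InvalidArgument(f"unknown coarse-grain method {method!r}")
    return MultichannelSeries(
        values=values,
        rate=series.rate / w,
        channel_names=list(series.channel_names),
        meta={
            **series.meta,
            "coarse_grain_ms": window_ms,
            "coarse_grain_samples": w,
            "coarse_grain_method": method,
        },
    )


def concat_phases(parts: list[MultichannelSeries]) -> MultichannelSeries:
    """Concatenate task phases along time, recording phase boundaries.

    Boundaries are stored in ``meta['phase_boundaries']`` (sample index of
    each join) so fluidity estimation can optionally censor
    inter-exceedance gaps that span a join.
    """
    if not parts:
        raise InvalidArgument("need at least one part")
    first = parts[0]
    for p in parts[1:]:
        if p.channel_names != first.channel_names:
            raise InvalidArgument("channel names must match positionally")
        if p.rate != first.rate:
            raise InvalidArgument("sampling rates must match")
    if len(parts) == 1:
        return first.copy_with()
    boundaries = list(np.cumsum([p.n_samples for p in parts[:-1]]).tolist())
    return MultichannelSeries(
        values=np.concatenate([p.values for p in parts], axis=1),
        rate=first.rate,
        channel_names=list(first.channel_names),
        meta={**first.meta, "phase_boundaries": boundaries},
    )
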