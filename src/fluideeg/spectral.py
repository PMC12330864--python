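"""Multitaper spectrograms and relative band power per cortical region.

Spectral analysis runs on the raw (non-coarse-grained) recording using
Slepian (DPSS) tapers, Chronux-style: a time-bandwidth product ``NW`` of
3 with 5 tapers, 10 s windows with 5 s overlap for band power and 60 s
windows with 30 s overlap for the 40 Hz stimulation peak (the longer
window narrows the frequency bins around 40 Hz). The time-averaged
spectrum of each channel is normalized to unit total power so band
values are fractions, then averaged within electrode groups over named
cortical territories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .core import InvalidArgument, MultichannelSeries

#: Frequency bands (Hz), half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 12.0),
    "gamma": (30.0, 80.0),
}

#: Cortical territories used for electrode grouping.
REGIONS = ("PFC", "MOC", "SSC", "PAR", "RSC", "VIS")


def default_region_map(channel_names: list[str]) -> dict[str, str]:
    """Assign channels to the six territories in contiguous blocks.

    Stands in for an electrode-position map when none is supplied: the 30
    channels of the surface grid are split front-to-back into six groups
    of five.
    """
    n = len(channel_names)
    per = max(1, int(np.ceil(n / len(REGIONS))))
    return {
        name: REGIONS[min(i // per, len(REGIONS) - 1)]
        for i, name in enumerate(channel_names)
    }


@dataclass
class Spectrogram:
    power: np.ndarray  # (n_windows, n_freqs, n_channels)
    freqs: np.ndarray
    window_starts_s: np.ndarray
    channel_names: list[str]

    def mean_spectrum(self) -> np.ndarray:
        """Time-averaged power, shape (n_freqs, n_channels)."""
        return self.power.mean(axis=0)


@dataclass
class BandPowerTable:
    """Region x band relative power fractions."""

    table: pd.DataFrame  # index=region, columns=band
    region_map: dict[str, str]

    def to_tsv(self, path) -> None:
        long = self.table.reset_index().melt(
            id_vars="region", var_name="band", value_name="fraction"
        )
        long.to_csv(path, sep="\t", index=False)


def multitaper_spectrogram(
    series: MultichannelSeries,
    window_s: float = 10.0,
    overlap_s: float = 5.0,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> Spectrogram:
    """Sliding-window Slepian-taper power spectrogram, per channel.

    ``time_bandwidth`` is the DPSS time-bandwidth product ``NW``; power in
    each window is averaged over the ``n_tapers`` leading tapers.
    """
    if overlap_s >= window_s:
        raise InvalidArgument("overlap must be shorter than the window")
    nper = int(round(window_s * series.rate))
    if nper > series.n_samples:
        raise InvalidArgument("window longer than the recording")
    step = nper - int(round(overlap_s * series.rate))
    tapers = dpss(nper, time_bandwidth, Kmax=n_tapers)  # (n_tapers, nper)
    starts = np.arange(0, series.n_samples - nper + 1, step)
    freqs = np.fft.rfftfreq(nper, d=1.0 / series.rate)
    power = np.empty((starts.size, freqs.size, series.n_channels))
    for wi, s0 in enumerate(starts):
        seg = series.values[:, s0 : s0 + nper]  # (C, nper)
        tapered = seg[:, None, :] * tapers[None, :, :]  # (C, K, nper)
        spec = np.fft.rfft(tapered, axis=2)
        power[wi] = np.abs(spec).__pow__(2).mean(axis=1).T / series.rate
    return Spectrogram(
        power=power,
        freqs=freqs,
        window_starts_s=starts / series.rate,
        channel_names=list(series.channel_names),
    )


def _normalized_mean_spectrum(spec: Spectrogram) -> np.ndarray:
    """Unit-total-power mean spectrum, shape (n_freqs, n_channels)."""
    mean = spec.mean_spectrum()
    total = mean.sum(axis=0, keepdims=True)
    if np.any(total <= 0):
        raise InvalidArgument("zero total power in at least one channel")
    return mean / total


def relative_band_power(
    spec: Spectrogram,
    bands: dict[str, tuple[float, float]] | None = None,
    region_map: dict[str, str] | None = None,
) -> BandPowerTable:
    """Band-integrated fractions of the unit-normalized spectrum, by region."""
    bands = dict(BANDS) if bands is None else bands
    if region_map is None:
        region_map = default_region_map(spec.channel_names)
    unknown = set(region_map) - set(spec.channel_names)
    if unknown:
        raise InvalidArgument(f"region map references unknown channels: {sorted(unknown)}")
    fmax = spec.freqs.max()
    df = spec.freqs[1] - spec.freqs[0] if spec.freqs.size > 1 else fmax
    for name, (lo, hi) in bands.items():
        # bands are half-open [lo, hi); hi may reach one bin past fmax so a
        # partition of the full range can include the last bin
        if lo < 0 or hi <= lo or lo > fmax or hi > fmax + df:
            raise InvalidArgument(f"band {name} [{lo}, {hi}) outside spectral range")
    norm = _normalized_mean_spectrum(spec)  # (F, C)
    rows = {}
    for band, (lo, hi) in bands.items():
        mask = (spec.freqs >= lo) & (spec.freqs < hi)
        rows[band] = norm[mask].sum(axis=0)  # per channel
    per_channel = pd.DataFrame(rows, index=spec.channel_names)
    per_channel["region"] = [region_map.get(c, "UNASSIGNED") for c in spec.channel_names]
    table = per_channel.groupby("region").mean()
    table.index.name = "region"
    return BandPowerTable(table=table, region_map=region_map)


def relative_40hz_power(
    series: MultichannelSeries,
    window_s: float = 60.0,
    overlap_s: float = 30.0,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
    region_map: dict[str, str] | None = None,
    target_hz: float = 40.0,
    integrate_hz: float = 0.0,
) -> pd.Series:
    """Fraction of total power at (or around) 40 Hz, per region.

    By default the single frequency bin nearest ``target_hz`` is used
    (bin width set by the 60 s window); ``integrate_hz`` widens this to
    ``target_hz ± integrate_hz``.
    """
    spec = multitaper_spectrogram(
        series,
        window_s=window_s,
        overlap_s=overlap_s,
        time_bandwidth=time_bandwidth,
        n_tapers=n_tapers,
    )
    if region_map is None:
        region_map = default_region_map(series.channel_names)
    norm = _normalized_mean_spectrum(spec)
    if integrate_hz > 0:
        mask = np.abs(spec.freqs - target_hz) <= integrate_hz
        frac = norm[mask].sum(axis=0)
    else:
        idx = int(np.argmin(np.abs(spec.freqs - target_hz)))
        frac = norm[idx]
    out = pd.Series(frac, index=series.channel_names, name="fraction_40hz")
    regions = pd.Series(
        [region_map.get(c, "UNASSIGNED") for c in series.channel_names],
        index=series.channel_names,
    )
    return out.groupby(regions).mean()
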