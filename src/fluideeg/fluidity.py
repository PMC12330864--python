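"""Dynamics fluidity: time-resolved extremal index of the EEG trajectory.

The coarse-grained multichannel EEG is read as a trajectory ``u_t`` in
channel space. Around a reference configuration ``u_0`` we form the
observable ``g(t) = -log ||u_t - u_0||``, which is large whenever the
trajectory revisits the neighborhood of ``u_0``. Threshold exceedances of
``g`` above a high quantile (default 98%) behave, for a stationary
series, like a clustered point process whose extremal index ``theta`` in
[0, 1] measures the clustering of those returns:

* ``theta = 1`` — exceedances are Poisson; the trajectory leaves every
  neighborhood immediately (maximally fluid dynamics);
* ``theta = 0`` — the reference is a fixed point; once entered, the
  neighborhood is never left.

``theta`` is estimated from inter-exceedance times with the Süveges
maximum-likelihood closed form. Repeating the estimate with each
observation as the reference yields a fluidity time series. The
exponential tail scale ``sigma`` of excesses over the threshold (a local
dimension proxy) is fitted alongside but not analyzed further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import InvalidArgument, MultichannelSeries

DEFAULT_QUANTILE = 0.98
MIN_SERIES_LENGTH = 100


@dataclass
class LogDistanceSeries:
    """The observable g(t) = -log distance to a reference configuration.

    The self point (distance exactly 0 at the reference time) is
    excluded; any other exact duplicates of the reference are excluded
    too and counted in ``n_zero_excluded``.
    """

    g: np.ndarray
    times: np.ndarray
    ref_index: int
    n_zero_excluded: int = 0


@dataclass
class ExceedanceRecord:
    """Sorted exceedance times of g above a threshold."""

    exceedance_times: np.ndarray
    threshold: float
    g_values: np.ndarray


@dataclass
class FluiditySeries:
    """Per-reference-time extremal index estimates.

    ``theta`` is NaN where estimation failed; ``reasons`` records why.
    ``sigma`` is the exponential tail scale of g-excesses (stored, not
    analyzed).
    """

    theta: np.ndarray
    sigma: np.ndarray
    quantile: float
    n_exceedances: np.ndarray
    ref_times: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    @property
    def valid_theta(self) -> np.ndarray:
        return self.theta[np.isfinite(self.theta)]

    @property
    def mean_theta(self) -> float:
        v = self.valid_theta
        return float(v.mean()) if v.size else float("nan")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ref_time": self.ref_times,
                "theta": self.theta,
                "sigma": self.sigma,
                "n_exceedances": self.n_exceedances,
            }
        )


def log_distance_series(
    series: MultichannelSeries, ref_index: int
) -> LogDistanceSeries:
    """g(t) = -log Euclidean distance between u_t and the reference u_0."""
    n = series.n_samples
    if not 0 <= ref_index < n:
        raise InvalidArgument(f"ref_index {ref_index} outside series of length {n}")
    u = series.values
    diff = u - u[:, [ref_index]]
    dist = np.linalg.norm(diff, axis=0)
    times = np.arange(n)
    keep = times != ref_index
    zero = (dist == 0) & keep
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(f"{n_zero} duplicate points identical to the reference excluded")
        keep &= ~zero
    with np.errstate(divide="ignore"):
        g = -np.log(dist[keep])
    return LogDistanceSeries(
        g=g, times=times[keep], ref_index=ref_index, n_zero_excluded=n_zero
    )


def suveges_theta(
    spaced_gaps: np.ndarray, p: float, use_t_gaps: bool = False
) -> float:
    """Closed-form Süveges MLE of the extremal index from exceedance gaps.

    ``spaced_gaps`` are the inter-exceedance times ``T_i`` (differences of
    consecutive exceedance time indices); ``p = 1 - q`` is the exceedance
    probability. The default convention uses ``S_i = T_i - 1`` (adjacent
    exceedances contribute zero spacing); ``use_t_gaps=True`` switches to
    the ``S_i = T_i`` variant found in part of the literature.

    The estimator maximizes
    ``l(theta) = (N - Nc) log(1-theta) + 2 Nc log(theta) - theta p sum(S)``
    with ``N`` the number of gaps and ``Nc`` the number of positive
    ``S_i``.
    """
    T = np.asarray(spaced_gaps, dtype=float)
    if T.size == 0:
        return float("nan")
    S = T if use_t_gaps else T - 1.0
    n_gaps = S.size
    n_cluster = int(np.count_nonzero(S > 0))
    s_sum = float(p * S.sum())
    if s_sum == 0.0:
        # single contiguous run of exceedances: the fixed-point limit
        return 0.0
    a = s_sum + n_gaps + n_cluster
    disc = a * a - 8.0 * n_cluster * s_sum
    theta = (a - np.sqrt(max(disc, 0.0))) / (2.0 * s_sum)
    return float(min(max(theta, 0.0), 1.0))


def estimate_extremal_index(
    g: np.ndarray,
    q: float = DEFAULT_QUANTILE,
    times: np.ndarray | None = None,
    use_t_gaps: bool = False,
    boundaries: list[int] | None = None,
) -> tuple[float, int]:
    """Extremal index of a scalar series via quantile-threshold exceedances.

    The threshold is the empirical ``q``-quantile of ``g``; exceedance
    times are where ``g`` strictly exceeds it. Returns ``(theta,
    n_exceedances)``; ``theta`` is NaN for series shorter than 100
    samples or with fewer than 2 exceedances. When ``boundaries`` is
    given (sample indices of concatenation joins), gaps spanning a join
    are censored out of the likelihood.
    """
    theta, n_exc, _ = _estimate(g, q, times, use_t_gaps, boundaries)
    return theta, n_exc


def _estimate(g, q, times, use_t_gaps, boundaries):
    g = np.asarray(g, dtype=float)
    if not 0 < q < 1:
        raise InvalidArgument("quantile q must lie in (0, 1)")
    if g.size < MIN_SERIES_LENGTH:
        return float("nan"), 0, "too short"
    if times is None:
        times = np.arange(g.size)
    finite = np.isfinite(g)
    g_f, t_f = g[finite], times[finite]
    if g_f.size < MIN_SERIES_LENGTH:
        return float("nan"), 0, "too short"
    threshold = float(np.quantile(g_f, q))
    exceed = g_f > threshold
    exc_times = t_f[exceed]
    n_exc = int(exc_times.size)
    if n_exc < 2:
        return float("nan"), n_exc, "fewer than 2 exceedances"
    gaps = np.diff(exc_times).astype(float)
    if boundaries:
        keep = np.ones(gaps.size, dtype=bool)
        lo, hi = exc_times[:-1], exc_times[1:]
        for b in boundaries:
            keep &= ~((lo < b) & (hi >= b))
        gaps = gaps[keep]
        if gaps.size == 0:
            return float("nan"), n_exc, "all gaps censored at phase boundaries"
    theta = suveges_theta(gaps, p=1.0 - q, use_t_gaps=use_t_gaps)
    return theta, n_exc, ""


def exceedance_record(g: LogDistanceSeries, q: float = DEFAULT_QUANTILE) -> ExceedanceRecord:
    """Threshold ``g`` at its q-quantile and collect exceedance times."""
    finite = np.isfinite(g.g)
    threshold = float(np.quantile(g.g[finite], q))
    mask = finite & (g.g > threshold)
    return ExceedanceRecord(
        exceedance_times=g.times[mask], threshold=threshold, g_values=g.g
    )


def _sigma_mean_excess(g: np.ndarray, threshold: float) -> float:
    """Exponential-GPD scale: mean excess of g over the threshold."""
    excess = g[np.isfinite(g) & (g > threshold)] - threshold
    return float(excess.mean()) if excess.size else float("nan")


def fluidity_timeseries(
    series: MultichannelSeries,
    q: float = DEFAULT_QUANTILE,
    ref_stride: int = 1,
    use_t_gaps: bool = False,
    censor_phase_boundaries: bool = False,
) -> FluiditySeries:
    """Extremal index with every ``ref_stride``-th observation as reference.

    ``ref_stride`` trades resolution for cost: per-reference estimation
    is O(n) so the full series is O(n^2 / ref_stride). Deterministic.
    """
    if ref_stride < 1:
        raise InvalidArgument("ref_stride must be >= 1")
    n = series.n_samples
    u = series.values
    ref_times = np.arange(0, n, ref_stride)
    sq_norms = np.einsum("ct,ct->t", u, u)
    boundaries = (
        list(series.meta.get("phase_boundaries", []))
        if censor_phase_boundaries
        else None
    )
    theta = np.full(ref_times.size, np.nan)
    sigma = np.full(ref_times.size, np.nan)
    n_exc = np.zeros(ref_times.size, dtype=int)
    reasons: dict[int, str] = {}
    times = np.arange(n)
    for i, r in enumerate(ref_times):
        d2 = sq_norms + sq_norms[r] - 2.0 * (u[:, r] @ u)
        np.maximum(d2, 0.0, out=d2)
        keep = (times != r) & (d2 > 0)
        with np.errstate(divide="ignore"):
            g = -0.5 * np.log(d2[keep])
        t_keep = times[keep]
        th, ne, reason = _estimate(g, q, t_keep, use_t_gaps, boundaries)
        theta[i], n_exc[i] = th, ne
        if reason:
            reasons[int(r)] = reason
        elif np.isfinite(th):
            thr = float(np.quantile(g, q))
            sigma[i] = _sigma_mean_excess(g, thr)
    if reasons and len(reasons) > 0.5 * ref_times.size:
        warnings.warn(
            f"{len(reasons)}/{ref_times.size} reference points failed estimation"
        )
    return FluiditySeries(
        theta=theta,
        sigma=sigma,
        quantile=q,
        n_exceedances=n_exc,
        ref_times=ref_times,
        reasons=reasons,
    )
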