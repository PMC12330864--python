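"""Microstate segmentation and symbolic-sequence metrics.

The coarse-grained EEG is segmented into K discrete topographic states by
k-means with correlation distance (signed: ``d = 1 - Pearson r`` across
channels, with an option to fold polarity as in human microstate work).
Two extraction routes are provided: clustering every sample directly, or
the global-field-power (GFP) route — cluster only the topographies at GFP
peaks, then backfit every sample to the best-correlated centroid.

From the resulting label sequence we compute:

* transition matrix — row-normalized counts of t -> t+1 state moves;
* microstates fluidity — ``1 / mean(diagonal)`` of the transition
  matrix over visited states; 1 means the sequence never switches,
  large values mean short dwell times;
* description-length complexity — the ratio of a run-length/shift
  compressed description of the label sequence to its raw positional
  description, mapped through ``100**ratio`` so values are
  approximately normal; sequences with long dwell blocks compress well
  (values far below 100) while rapidly alternating sequences do not;
* entropy of state occupancy within each decile of a fluidity series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .core import FluideegError, InvalidArgument, MultichannelSeries
from .fluidity import FluiditySeries


@dataclass
class MicrostateSegmentation:
    centroids: np.ndarray  # (K, n_channels)
    labels: np.ndarray  # (n_samples,)
    K: int
    method: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class TransitionMatrix:
    probs: np.ndarray  # (K, K); rows of never-departing states are NaN
    counts: np.ndarray  # (K, K) integer


@dataclass
class ComplexityResult:
    L_orig: int
    L_comp: int
    dl_complexity: float


# ---------------------------------------------------------------------------
# Correlation-distance k-means
# ---------------------------------------------------------------------------

def _center_normalize(X: np.ndarray) -> np.ndarray:
    """Center each row across channels and scale to unit norm.

    After this, the dot product of two rows is their Pearson correlation.
    Zero-variance rows map to zero vectors (correlation 0 with anything).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, Xc / norms, 0.0)
    return out


def correlation_distance(X: np.ndarray, C: np.ndarray, ignore_polarity: bool = False):
    """Pairwise ``1 - r`` (or ``1 - |r|``) between sample and centroid rows."""
    r = _center_normalize(X) @ _center_normalize(C).T
    return 1.0 - (np.abs(r) if ignore_polarity else r)


def _kmeans_corr_once(X, K, rng, ignore_polarity, max_iter=300, tol=1e-8):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=K, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    prev_inertia = np.inf
    for _ in range(max_iter):
        d = correlation_distance(X, centroids, ignore_polarity)
        labels = d.argmin(axis=1)
        inertia = float(d[np.arange(n), labels].sum())
        for k in range(K):
            members = X[labels == k]
            if members.size == 0:
                # re-seed an empty cluster at the worst-fit sample
                worst = d[np.arange(n), labels].argmax()
                centroids[k] = X[worst]
            else:
                centroids[k] = members.mean(axis=0)
        if prev_inertia - inertia < tol:
            break
        prev_inertia = inertia
    d = correlation_distance(X, centroids, ignore_polarity)
    labels = d.argmin(axis=1)
    inertia = float(d[np.arange(n), labels].sum())
    return centroids, labels, inertia


def kmeans_correlation(
    X: np.ndarray,
    K: int,
    seed: int | None = None,
    n_restarts: int = 10,
    ignore_polarity: bool = False,
):
    """Best-of-``n_restarts`` Lloyd k-means with correlation distance."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centroids, labels, inertia = _kmeans_corr_once(X, K, rng, ignore_polarity)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    if best is None:  # pragma: no cover
        raise FluideegError("k-means failed on every restart")
    return best


def segment_kmeans(
    series: MultichannelSeries,
    K: int,
    seed: int | None = None,
    n_restarts: int = 10,
    ignore_polarity: bool = False,
) -> MicrostateSegmentation:
    """Cluster every coarse-grained sample topography into K microstates."""
    if K < 2:
        raise InvalidArgument("K must be >= 2")
    if K > series.n_channels:
        raise InvalidArgument("K cannot exceed the channel count")
    if series.n_samples <= 10 * K:
        raise InvalidArgument("series too short for the requested K")
    X = series.values.T
    centroids, labels, inertia = kmeans_correlation(
        X, K, seed=seed, n_restarts=n_restarts, ignore_polarity=ignore_polarity
    )
    return MicrostateSegmentation(
        centroids=centroids,
        labels=labels,
        K=K,
        method="kmeans",
        seed=seed,
        meta={
            "n_restarts": n_restarts,
            "inertia": inertia,
            "ignore_polarity": ignore_polarity,
        },
    )


def gfp(series: MultichannelSeries) -> np.ndarray:
    """Global field power: across-channel variance at each time point."""
    return series.values.var(axis=0)


def segment_gfp(
    series: MultichannelSeries,
    K: int,
    min_prominence: float = 0.5,
    seed: int | None = None,
    n_restarts: int = 10,
    zscore_gfp: bool = False,
    ignore_polarity: bool = False,
) -> MicrostateSegmentation:
    """GFP-peak microstates: cluster peak topographies, backfit all samples.

    Peaks of the GFP curve (local maxima with the given prominence;
    ``zscore_gfp`` applies the prominence on the standardized curve since
    raw variance units depend on amplitude scale) are topography-stable
    moments. Their topographies are k-means clustered and every sample is
    assigned the centroid with the highest Pearson correlation.
    """
    if K < 2:
        raise InvalidArgument("K must be >= 2")
    curve = gfp(series)
    if zscore_gfp:
        sd = curve.std()
        if sd == 0:
            raise FluideegError("constant GFP: no peaks to extract")
        curve = (curve - curve.mean()) / sd
    peaks, _ = find_peaks(curve, prominence=min_prominence if min_prominence > 0 else None)
    if peaks.size < K:
        raise FluideegError(
            f"only {peaks.size} GFP peaks at prominence {min_prominence}; "
            "lower min_prominence"
        )
    X_peaks = series.values[:, peaks].T
    centroids, _, _ = kmeans_correlation(
        X_peaks, K, seed=seed, n_restarts=n_restarts, ignore_polarity=ignore_polarity
    )
    d = correlation_distance(series.values.T, centroids, ignore_polarity)
    labels = d.argmin(axis=1)
    return MicrostateSegmentation(
        centroids=centroids,
        labels=labels,
        K=K,
        method="gfp-peaks",
        seed=seed,
        meta={
            "n_peaks": int(peaks.size),
            "min_prominence": min_prominence,
            "zscore_gfp": zscore_gfp,
            "ignore_polarity": ignore_polarity,
        },
    )


def match_templates(
    centroids: np.ndarray, templates: np.ndarray, ignore_polarity: bool = False
):
    """Optimal centroid-template pairing by absolute-correlation cost.

    Returns (template_index_per_centroid, matched |r| per pair) using the
    Hungarian algorithm.
    """
    r = _center_normalize(centroids) @ _center_normalize(templates).T
    cost = -np.abs(r) if ignore_polarity else -r
    row, col = linear_sum_assignment(cost)
    order = np.empty(len(row), dtype=int)
    order[row] = col
    matched_r = np.abs(r[row, col])
    return order, matched_r


# ---------------------------------------------------------------------------
# Sequence metrics
# ---------------------------------------------------------------------------

def transition_matrix(labels: np.ndarray, K: int) -> TransitionMatrix:
    """Counts and probabilities of state moves between consecutive samples."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InvalidArgument("labels must be nonempty")
    if labels.min() < 0 or labels.max() >= K:
        raise InvalidArgument("labels must lie in [0, K)")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (labels[:-1], labels[1:]), 1)
    row_sums = counts.sum(axis=1)
    probs = np.full((K, K), np.nan)
    visited = row_sums > 0
    probs[visited] = counts[visited] / row_sums[visited, None]
    return TransitionMatrix(probs=probs, counts=counts)


def microstate_fluidity(tm: TransitionMatrix) -> float:
    """Reciprocal of the mean self-transition probability over visited states.

    Equals 1 when the sequence never switches; grows without bound as
    dwell times shrink (infinite for strict alternation).
    """
    diag = np.diag(tm.probs)
    diag = diag[np.isfinite(diag)]
    if diag.size == 0:
        return float("nan")
    mean_diag = float(diag.mean())
    if mean_diag == 0.0:
        return float("inf")
    return 1.0 / mean_diag


def _runs(labels: np.ndarray):
    """(value, start, length) for each maximal run of equal labels."""
    labels = np.asarray(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def mdl_complexity(labels: np.ndarray) -> ComplexityResult:
    """Description-length complexity of a symbolic state sequence.

    The original description lists, for each dictionary symbol, every
    position where it occurs: ``L_orig = |dictionary| + n_symbols``
    tokens. The compressed description lists, per symbol, (block length,
    shift to the next block) pairs for its runs of consecutive
    occurrences, the final block of each symbol carrying no shift token:
    ``L_comp = |dictionary| + sum_over_symbols(2 * n_blocks - 1)``.
    The reported value is ``100 ** (L_comp / L_orig)``; 100 means no
    compression, below 100 means the sequence is dominated by long
    dwell blocks.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise InvalidArgument("labels must be nonempty")
    alphabet = np.unique(labels)
    L_orig = int(alphabet.size + labels.size)
    blocks_per_symbol = {int(a): 0 for a in alphabet}
    for value, _start, _length in _runs(labels):
        blocks_per_symbol[value] += 1
    L_comp = int(alphabet.size + sum(2 * b - 1 for b in blocks_per_symbol.values()))
    return ComplexityResult(
        L_orig=L_orig,
        L_comp=L_comp,
        dl_complexity=float(100.0 ** (L_comp / L_orig)),
    )


def mean_dwell(labels: np.ndarray, K: int, method: str = "markov", max_lag: int = 8) -> float:
    """Mean microstate dwell time (in samples) of a label sequence.

    ``method="runs"`` is the raw mean run length. It is unbiased only for
    noiseless labels: independent per-sample misassignments (inevitable
    at finite SNR, even for an ideal classifier) fragment runs and bias
    it low. ``method="markov"`` is robust to such noise: independent
    misclassification attenuates the amplitude of the lagged
    label-agreement curve ``q_d = P(label_t = label_{t+d})`` but not its
    geometric decay rate, so the Markov eigenvalue ``lambda`` is
    recovered from the median ratio of successive differences of ``q_d``
    over lags up to ``max_lag``, and the dwell follows from the implied
    stay probability of a symmetric K-state chain.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise InvalidArgument("need at least 2 labels")
    if method == "runs":
        n_runs = 1 + int(np.count_nonzero(labels[1:] != labels[:-1]))
        return labels.size / n_runs
    if method != "markov":
        raise InvalidArgument(f"unknown method {method!r}")
    if labels.size <= max_lag + 2:
        raise InvalidArgument("sequence too short for the markov dwell estimate")
    q = np.array(
        [(labels[:-d] == labels[d:]).mean() for d in range(1, max_lag + 2)]
    )
    dq = np.diff(q)
    denom = dq[:-1]
    valid = denom != 0
    if not valid.any():
        return float("inf")  # no decay: the sequence never switches
    lam = float(np.median(dq[1:][valid] / denom[valid]))
    lam = min(max(lam, 0.0), 1.0 - 1e-12)
    stay = lam * (1.0 - 1.0 / K) + 1.0 / K
    return float(1.0 / (1.0 - stay))


def occupancy_entropy(labels: np.ndarray, K: int) -> float:
    """Shannon entropy (bits) of the empirical state occupancy."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=K)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_by_fluidity_decile(
    labels: np.ndarray, fluidity: FluiditySeries, K: int = 4
) -> np.ndarray:
    """State-occupancy entropy within each decile of the fluidity series.

    Labels are taken at the fluidity reference times (both series must
    share the coarse-grained time base). Deciles are formed by rank so
    they are equally populated; deciles emptied by NaN fluidity give NaN
    entropy.
    """
    labels = np.asarray(labels, dtype=int)
    theta = fluidity.theta
    ref = fluidity.ref_times
    if ref.max(initial=0) >= labels.size:
        raise InvalidArgument("fluidity reference times exceed label sequence")
    lab = labels[ref]
    valid = np.isfinite(theta)
    out = np.full(10, np.nan)
    if valid.sum() == 0:
        return out
    th, lb = theta[valid], lab[valid]
    order = np.argsort(th, kind="stable")
    decile_of_rank = np.minimum((np.arange(th.size) * 10) // th.size, 9)
    decile = np.empty(th.size, dtype=int)
    decile[order] = decile_of_rank
    for d in range(10):
        members = lb[decile == d]
        if members.size:
            out[d] = occupancy_entropy(members, K)
    return out


def sweep_k(
    series: MultichannelSeries,
    k_min: int = 3,
    k_max: int = 8,
    seed: int | None = None,
    method: str = "kmeans",
    **kwargs,
):
    """Segment for each K in [k_min, k_max]; average fluidity and complexity.

    Returns a dict with the per-K table and the across-K arithmetic
    means, the per-subject summary used for group comparison.
    """
    if not 2 <= k_min <= k_max:
        raise InvalidArgument("need k_max >= k_min >= 2")
    rows = []
    errors = {}
    for K in range(k_min, k_max + 1):
        try:
            if method == "kmeans":
                seg = segment_kmeans(series, K, seed=seed, **kwargs)
            elif method == "gfp":
                seg = segment_gfp(series, K, seed=seed, **kwargs)
            else:
                raise InvalidArgument(f"unknown method {method!r}")
        except (FluideegError, InvalidArgument) as exc:
            errors[K] = str(exc)
            continue
        tm = transition_matrix(seg.labels, K)
        rows.append(
            {
                "K": K,
                "fluidity": microstate_fluidity(tm),
                "dl_complexity": mdl_complexity(seg.labels).dl_complexity,
            }
        )
    if not rows:
        raise FluideegError(f"segmentation failed for every K: {errors}")
    fl = [r["fluidity"] for r in rows]
    cx = [r["dl_complexity"] for r in rows]
    return {
        "per_k": rows,
        "mean_fluidity": float(np.mean(fl)),
        "mean_dl_complexity": float(np.mean(cx)),
        "errors": errors,
    }
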