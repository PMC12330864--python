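"""Resampling statistics for fluidity distributions and behavior coupling.

Three bespoke procedures:

* ``bootstrap_ks_compare`` — a conservative Monte-Carlo Kolmogorov-
  Smirnov comparison of two fluidity distributions. Each input is
  modeled as a 200-bin histogram, 5000 Monte-Carlo samples are drawn
  per distribution, and 500-observation bootstrap replicas are drawn
  under the association hypothesis H1 (group-specific samples) and the
  no-association hypothesis H0 (samples from the merged pool). The
  reported statistic is the H1 mean ± sd of the replica KS values; the
  p-value is the overlap of the H1 and H0 replica distributions,
  Bonferroni-corrected.
* ``mutual_information_deciles`` — decile-binned normalized mutual
  information MI/H between a fluidity series and a locomotor series,
  with a paired-resampling observed estimate and an independently
  shuffled null.
* ``codistribution_deciles`` — median locomotor value per fluidity
  decile, with paired (H1) and independent (H0) bootstrap bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InvalidArgument


@dataclass
class BootstrapKSResult:
    ks_mean_h1: float
    ks_sd_h1: float
    p_overlap: float
    p_bonferroni: float
    p_exceedance: float
    n_mc: int
    n_replicas: int
    replica_size: int
    n_bins: int
    seed: int
    n_dropped_nan: int = 0

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05


@dataclass
class MIResult:
    mi_over_h_observed: float
    mi_over_h_null: float
    n_boot: int
    n_bins: int
    seed: int


@dataclass
class CodistributionResult:
    decile_edges: np.ndarray
    observed_medians: np.ndarray
    h1_medians: np.ndarray  # (n_boot, 10)
    h0_medians: np.ndarray  # (n_boot, 10)
    h1_band: np.ndarray  # (2, 10): 2.5 / 97.5 percentiles
    h0_band: np.ndarray
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------
# Bootstrap KS
# ---------------------------------------------------------------------------

def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup ECDF difference)."""
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _histogram_mc_sample(
    x: np.ndarray, edges: np.ndarray, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the histogram model of x: pick a bin, uniform within it."""
    counts, _ = np.histogram(x, bins=edges)
    p = counts / counts.sum()
    bins = rng.choice(counts.size, size=n_mc, p=p)
    width = np.diff(edges)
    return edges[bins] + rng.random(n_mc) * width[bins]


def bootstrap_ks_compare(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_mc: int = 5000,
    n_bins: int = 200,
    replica_size: int = 500,
    n_replicas: int = 500,
    m_comparisons: int = 1,
    seed: int = 0,
) -> BootstrapKSResult:
    """Monte-Carlo bootstrap KS comparison of two empirical distributions.

    The overlap p-value is the overlap coefficient of the H1 and H0
    replica-KS distributions (shared area of their normalized
    histograms): identical fluidity distributions give p near 1, fully
    separated replica distributions give p = 0. A one-sided variant —
    the fraction of H0 replicas whose KS statistic reaches the H1
    replica mean — is reported alongside as ``p_exceedance``.
    """
    if replica_size < 10:
        raise InvalidArgument("replica_size must be >= 10")
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    n_nan = int(np.isnan(a).sum() + np.isnan(b).sum())
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidArgument("both samples must contain finite values")
    rng = np.random.default_rng(seed)

    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)

    mc_a = _histogram_mc_sample(a, edges, n_mc, rng)
    mc_b = _histogram_mc_sample(b, edges, n_mc, rng)
    merged = np.concatenate([mc_a, mc_b])

    ks_h1 = np.empty(n_replicas)
    ks_h0 = np.empty(n_replicas)
    for i in range(n_replicas):
        ra = mc_a[rng.integers(n_mc, size=replica_size)]
        rb = mc_b[rng.integers(n_mc, size=replica_size)]
        ks_h1[i] = _ks_statistic(ra, rb)
        ma = merged[rng.integers(2 * n_mc, size=replica_size)]
        mb = merged[rng.integers(2 * n_mc, size=replica_size)]
        ks_h0[i] = _ks_statistic(ma, mb)

    mean_h1 = float(ks_h1.mean())
    p_overlap = _overlap_coefficient(ks_h1, ks_h0)
    p_exceedance = float(np.mean(ks_h0 >= mean_h1))
    return BootstrapKSResult(
        ks_mean_h1=mean_h1,
        ks_sd_h1=float(ks_h1.std(ddof=1)),
        p_overlap=p_overlap,
        p_bonferroni=min(1.0, p_overlap * m_comparisons),
        p_exceedance=p_exceedance,
        n_mc=n_mc,
        n_replicas=n_replicas,
        replica_size=replica_size,
        n_bins=n_bins,
        seed=seed,
        n_dropped_nan=n_nan,
    )


def _overlap_coefficient(x: np.ndarray, y: np.ndarray, n_bins: int = 50) -> float:
    """Shared area of two normalized histograms on a common grid."""
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    return float(np.minimum(px / px.sum(), py / py.sum()).sum())


# ---------------------------------------------------------------------------
# Decile binning and mutual information
# ---------------------------------------------------------------------------

def decile_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile binning into equal-population bins, ties broken by rank.

    Uses the stable rank order so heavily tied data still yields a
    well-defined, deterministic binning.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise InvalidArgument("constant series: deciles undefined")
    order = np.argsort(x, kind="stable")
    bins = np.empty(x.size, dtype=int)
    bins[order] = np.minimum((np.arange(x.size) * n_bins) // x.size, n_bins - 1)
    return bins


def _mi_over_h(bx: np.ndarray, by: np.ndarray, n_bins: int = 10) -> float:
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    mi = float((joint[nz] * np.log2(joint[nz] / outer[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    h = max(hx, hy)
    return mi / h if h > 0 else 0.0


def mutual_information_deciles(
    x: np.ndarray, y: np.ndarray, n_boot: int = 100, seed: int = 0
) -> MIResult:
    """Decile-binned MI/H with paired-bootstrap observed and shuffled null.

    Per iteration: the observed estimate resamples index pairs jointly
    (preserving the x-y pairing); the null resamples the two series
    independently, destroying any dependence. Means over iterations are
    reported. MI is normalized by the larger of the two marginal
    entropies, so MI/H is 1 for a deterministic decile relationship and
    near 0 for independent series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgument("series must have equal length")
    if x.size < 100:
        raise InvalidArgument("need at least 100 paired samples")
    decile_bins(x)  # raises on constant input
    decile_bins(y)
    rng = np.random.default_rng(seed)
    obs = np.empty(n_boot)
    null = np.empty(n_boot)
    n = x.size
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        obs[i] = _mi_over_h(decile_bins(x[idx]), decile_bins(y[idx]))
        ix = rng.integers(n, size=n)
        iy = rng.integers(n, size=n)
        null[i] = _mi_over_h(decile_bins(x[ix]), decile_bins(y[iy]))
    return MIResult(
        mi_over_h_observed=float(obs.mean()),
        mi_over_h_null=float(null.mean()),
        n_boot=n_boot,
        n_bins=10,
        seed=seed,
    )


def codistribution_deciles(
    fluidity: np.ndarray,
    locomotor: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> CodistributionResult:
    """Median locomotor value per fluidity decile, with bootstrap bands.

    Fluidity deciles use the 0:10:...:100 percentile edges. Each of the
    ``n_boot`` iterations forms an H1 replica (both series resampled
    with the same index vector, preserving pairing) and an H0 replica
    (independent resampling); decile-wise medians of the locomotor
    series give bootstrap co-distributions under each hypothesis.
    """
    f = np.asarray(fluidity, dtype=float)
    m = np.asarray(locomotor, dtype=float)
    if f.size != m.size:
        raise InvalidArgument("series must have equal length")
    if np.unique(f).size < 10:
        raise InvalidArgument("need at least 10 distinct fluidity values")
    rng = np.random.default_rng(seed)
    edges = np.percentile(f, np.arange(0, 101, 10))
    observed = _decile_medians(f, m, edges)
    h1 = np.empty((n_boot, 10))
    h0 = np.empty((n_boot, 10))
    n = f.size
    for i in range(n_boot):
        idx = rng.integers(n, size=n)
        fe = np.percentile(f[idx], np.arange(0, 101, 10))
        h1[i] = _decile_medians(f[idx], m[idx], fe)
        i_f = rng.integers(n, size=n)
        i_m = rng.integers(n, size=n)
        fe0 = np.percentile(f[i_f], np.arange(0, 101, 10))
        h0[i] = _decile_medians(f[i_f], m[i_m], fe0)
    return CodistributionResult(
        decile_edges=edges,
        observed_medians=observed,
        h1_medians=h1,
        h0_medians=h0,
        h1_band=np.nanpercentile(h1, [2.5, 97.5], axis=0),
        h0_band=np.nanpercentile(h0, [2.5, 97.5], axis=0),
        n_boot=n_boot,
        seed=seed,
    )


def _decile_medians(f: np.ndarray, m: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.full(10, np.nan)
    which = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, 9)
    for d in range(10):
        sel = m[which == d]
        if sel.size:
            out[d] = float(np.median(sel))
    return out
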