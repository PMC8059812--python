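"""Nonparametric inference for correlation time series and layer profiles.

* sign-flip cluster-size permutation tests against zero,
* bootstrap (resampling subjects) peak-latency estimation with pairwise
  latency-difference tests (Bonferroni corrected),
* Spearman hierarchy correlations with permutation p-values,
* paired t-tests across layers with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .rsa import CorrelationSeries

__all__ = [
    "Cluster",
    "ClusterResult",
    "Peak",
    "PeakLatencyResult",
    "LayerComparisonResult",
    "cluster_permutation_test",
    "find_peaks",
    "bootstrap_peak_latency",
    "hierarchy_correlation",
    "paired_layer_tests",
]


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    size: int
    p_value: float


@dataclass
class ClusterResult:
    clusters: dict[str, list[Cluster]]
    cluster_def_p: float
    cluster_sig_p: float
    n_permutations: int

    def significant(self, layer_id: str) -> list[Cluster]:
        return [c for c in self.clusters[layer_id]
                if c.p_value <= self.cluster_sig_p]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs; stop inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts, stops))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Longest True run per row of a boolean matrix."""
    n_perm, n_t = masks.shape
    padded = np.concatenate(
        [np.zeros((n_perm, 1), bool), masks, np.zeros((n_perm, 1), bool)], axis=1)
    out = np.zeros(n_perm, dtype=int)
    d = np.diff(padded.astype(np.int8), axis=1)
    for i in range(n_perm):
        starts = np.flatnonzero(d[i] == 1)
        if starts.size:
            stops = np.flatnonzero(d[i] == -1)
            out[i] = (stops - starts).max()
    return out


def cluster_permutation_test(series: CorrelationSeries,
                             cluster_def_p: float = 0.01,
                             cluster_sig_p: float = 0.05,
                             n_perm: int = 1000,
                             seed: int = 0,
                             tail: str = "greater") -> ClusterResult:
    """Sign-flip cluster-size permutation test against zero, per layer.

    A one-sample t statistic across subjects is computed at each time
    point; contiguous runs exceeding the cluster-definition threshold
    form clusters scored by their size (number of time points).  The null
    distribution of the maximum cluster size is built from ``n_perm``
    random subject sign flips; a cluster is significant when its
    permutation p-value is at most ``cluster_sig_p``.
    """
    if not (0 < cluster_def_p < 1 and 0 < cluster_sig_p < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    n_sub = series.n_subjects
    if n_sub < 2:
        raise ValueError("cluster test needs >= 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    df = n_sub - 1
    if tail == "greater":
        t_crit = sps.t.ppf(1.0 - cluster_def_p, df)
    elif tail == "two-sided":
        t_crit = sps.t.ppf(1.0 - cluster_def_p / 2.0, df)
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    rng = np.random.default_rng(seed)
    clusters: dict[str, list[Cluster]] = {}
    for li, lid in enumerate(series.layer_ids):
        data = series.values[:, li, :]  # subject x time
        sum_x2 = (data**2).sum(axis=0)

        def t_stats(means: np.ndarray) -> np.ndarray:
            # sample variance of sign-flipped data: sum of squares invariant
            var = np.maximum(sum_x2 - n_sub * means**2, 0.0) / df
            with np.errstate(divide="ignore", invalid="ignore"):
                return means / np.sqrt(var / n_sub)

        t_obs = t_stats(data.mean(axis=0))
        exceed = (t_obs > t_crit) if tail == "greater" else (np.abs(t_obs) > t_crit)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
        t_perm = t_stats((signs @ data) / n_sub)
        masks = (t_perm > t_crit) if tail == "greater" else (np.abs(t_perm) > t_crit)
        null_max = _max_run_lengths(masks)
        found = []
        for start, stop in _runs(exceed):
            size = stop - start + 1
            p = (1 + int((null_max >= size).sum())) / (1 + n_perm)
            found.append(Cluster(start_ms=float(series.time_ms[start]),
                                 end_ms=float(series.time_ms[stop]),
                                 size=size, p_value=p))
        clusters[lid] = found
    return ClusterResult(clusters=clusters, cluster_def_p=cluster_def_p,
                         cluster_sig_p=cluster_sig_p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# peaks

@dataclass
class Peak:
    time_ms: float
    height: float
    prominence: float


def find_peaks(trace: np.ndarray, time_ms: np.ndarray,
               window_ms: tuple[float, float] = (0.0, 1000.0),
               min_prominence: float | None = None) -> list[Peak]:
    """Local maxima within a window, ordered by time.

    ``min_prominence`` defaults to 10% of the trace range inside the
    window.  The first returned element is the "first peak".
    """
    trace = np.asarray(trace, dtype=np.float64)
    time_ms = np.asarray(time_ms, dtype=np.float64)
    sel = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("empty search window")
    seg = trace[sel]
    seg_t = time_ms[sel]
    if min_prominence is None:
        rng_ = float(seg.max() - seg.min())
        min_prominence = 0.1 * rng_ if rng_ > 0 else 0.0
    if min_prominence > 0:
        idx, props = spsig.find_peaks(seg, prominence=min_prominence)
        prom = props["prominences"]
    else:
        idx, _ = spsig.find_peaks(seg)
        prom = spsig.peak_prominences(seg, idx)[0] if idx.size else np.array([])
    return [Peak(time_ms=float(seg_t[i]), height=float(seg[i]),
                 prominence=float(p)) for i, p in zip(idx, prom)]


@dataclass
class PeakLatencyResult:
    layer_ids: list[str]
    estimate_ms: np.ndarray          # point estimate per layer (nan if absent)
    ci_low_ms: np.ndarray
    ci_high_ms: np.ndarray
    n_boot: int
    n_dropped: np.ndarray            # replicates without a qualifying peak
    boot_latencies_ms: np.ndarray    # n_boot x layer, nan where dropped
    pairwise: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict)        # (mean diff, raw p, Bonferroni p)

    def latency(self, layer_id: str) -> float:
        return float(self.estimate_ms[self.layer_ids.index(layer_id)])


def _nth_peak_latency(trace, time_ms, window_ms, min_prominence, n) -> float:
    peaks = find_peaks(trace, time_ms, window_ms, min_prominence)
    return peaks[n].time_ms if len(peaks) > n else np.nan


def bootstrap_peak_latency(series: CorrelationSeries,
                           n_boot: int = 1000,
                           peak_index: int = 0,
                           seed: int = 0,
                           window_ms: tuple[float, float] = (0.0, 1000.0),
                           min_prominence: float | None = None,
                           ci: float = 0.95) -> PeakLatencyResult:
    """Bootstrap distribution of per-layer peak latencies.

    Subjects are resampled with replacement ``n_boot`` times; each
    replicate's subject-average trace is searched for peaks and the
    ``peak_index``-th latency recorded (replicates with too few peaks are
    dropped and counted).  Pairwise layer-latency differences are tested
    two-sided from the paired bootstrap distribution of differences and
    Bonferroni-corrected across pairs.
    """
    if series.n_subjects < 2:
        raise ValueError("bootstrap needs >= 2 subjects")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n_sub = series.n_subjects
    layer_ids = series.layer_ids
    n_layers = len(layer_ids)
    est = np.array([
        _nth_peak_latency(series.subject_mean[li], series.time_ms, window_ms,
                          min_prominence, peak_index)
        for li in range(n_layers)])
    boot = np.full((n_boot, n_layers), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n_sub, size=n_sub)
        mean_traces = series.values[idx].mean(axis=0)
        for li in range(n_layers):
            boot[b, li] = _nth_peak_latency(mean_traces[li], series.time_ms,
                                            window_ms, min_prominence,
                                            peak_index)
    n_dropped = np.isnan(boot).sum(axis=0)
    alpha = (1.0 - ci) / 2.0
    ci_low = np.full(n_layers, np.nan)
    ci_high = np.full(n_layers, np.nan)
    for li in range(n_layers):
        good = boot[~np.isnan(boot[:, li]), li]
        if good.size:
            ci_low[li] = np.quantile(good, alpha)
            ci_high[li] = np.quantile(good, 1.0 - alpha)
    pairwise: dict[tuple[str, str], tuple[float, float, float]] = {}
    pairs = [(i, j) for i in range(n_layers) for j in range(i + 1, n_layers)]
    n_pairs = len(pairs)
    for i, j in pairs:
        both = ~(np.isnan(boot[:, i]) | np.isnan(boot[:, j]))
        d = boot[both, i] - boot[both, j]
        if d.size == 0:
            continue
        n = d.size
        p_le = (1 + int((d <= 0).sum())) / (1 + n)
        p_ge = (1 + int((d >= 0).sum())) / (1 + n)
        p_raw = min(1.0, 2.0 * min(p_le, p_ge))
        pairwise[(layer_ids[i], layer_ids[j])] = (
            float(d.mean()), p_raw, min(1.0, p_raw * n_pairs))
    return PeakLatencyResult(layer_ids=list(layer_ids), estimate_ms=est,
                             ci_low_ms=ci_low, ci_high_ms=ci_high,
                             n_boot=n_boot, n_dropped=n_dropped,
                             boot_latencies_ms=boot, pairwise=pairwise)


# ---------------------------------------------------------------------------
# hierarchy and layer comparisons

def hierarchy_correlation(latencies, order=None, seed: int = 0,
                          n_perm: int = 10000) -> tuple[float, float]:
    """Spearman correlation of layer rank vs latency, permutation p-value.

    Returns (rho, p).  Two-sided p from exhaustive enumeration when the
    number of layers is at most 7, Monte Carlo otherwise.  If all
    latencies are tied the correlation is undefined and (nan, nan) is
    returned.
    """
    lat = np.asarray(latencies, dtype=np.float64)
    if lat.size < 3:
        raise ValueError("need >= 3 layers")
    if order is None:
        order = np.arange(lat.size)
    order = np.asarray(order, dtype=np.float64)
    if np.all(lat == lat[0]):
        return np.nan, np.nan
    rho = float(sps.spearmanr(order, lat).statistic)
    lat_r = sps.rankdata(lat)
    ord_r = sps.rankdata(order)

    def _rho(perm):
        return np.corrcoef(ord_r, lat_r[list(perm)])[0, 1]

    if lat.size <= 7:
        null = np.array([_rho(p) for p in _iter_permutations(range(lat.size))])
    else:
        rng = np.random.default_rng(seed)
        null = np.array([_rho(rng.permutation(lat.size))
                         for _ in range(n_perm)])
    p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
    return rho, p


@dataclass
class LayerComparisonResult:
    labels: list[str]
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    q: float
    method: str = "ttest"


def _one_sample_p(diffs: np.ndarray, method: str, rng) -> tuple[float, float]:
    """Two-sided test of mean(diffs) == 0; returns (statistic, p)."""
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return np.inf * np.sign(mean), 0.0
    t_stat = mean / (sd / np.sqrt(diffs.size))
    if method == "ttest":
        p = 2.0 * sps.t.sf(abs(t_stat), diffs.size - 1)
        return float(t_stat), float(p)
    if method == "sign_permutation":
        n_perm = 10000
        signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
        null = (signs * diffs).mean(axis=1)
        p = (1 + int((np.abs(null) >= abs(mean) - 1e-15).sum())) / (1 + n_perm)
        return float(t_stat), float(p)
    raise ValueError(f"unknown method {method!r}")


def paired_layer_tests(profile_a: np.ndarray,
                       profile_b: np.ndarray | None = None,
                       q: float = 0.05,
                       labels: list[str] | None = None,
                       method: str = "ttest",
                       seed: int = 0) -> LayerComparisonResult:
    """Per-layer paired two-sided tests with BH FDR correction at level q.

    ``profile_a``/``profile_b`` are subject x layer matrices with matched
    subjects; with ``profile_b=None`` each layer is tested above/below
    zero with the same machinery.  Zero-variance, zero-mean differences
    give p = 1 by convention.
    """
    a = np.asarray(profile_a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("profiles must be subject x layer with >= 2 subjects")
    if profile_b is not None:
        b = np.asarray(profile_b, dtype=np.float64)
        if b.shape != a.shape:
            raise ValueError("profiles must have matching shapes")
        diffs = a - b
    else:
        diffs = a
    n_layers = diffs.shape[1]
    if labels is None:
        labels = [f"layer{k}" for k in range(n_layers)]
    rng = np.random.default_rng(seed)
    stats_, pvals = zip(*[_one_sample_p(diffs[:, k], method, rng)
                          for k in range(n_layers)])
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return LayerComparisonResult(labels=list(labels),
                                 statistic=np.asarray(stats_),
                                 p_raw=np.asarray(pvals),
                                 p_adjusted=p_adj,
                                 significant=reject, q=q, method=method)
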