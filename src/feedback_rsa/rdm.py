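"""Representational dissimilarity matrices from model, fMRI and MEG data.

Three dissimilarity sources share one container:

* model layer activations -> 1 - Pearson correlation distance;
* fMRI ROI voxel patterns -> 1 - Pearson correlation distance;
* MEG sensor epochs -> pairwise linear-SVM decoding accuracy at each time
  point, on subaveraged pseudo-trials with leave-one-out cross-validation.

MEG preprocessing (baseline mean removal and zero-phase 30 Hz low-pass)
lives here too, mirroring the conventional epoch pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.svm import SVC

from .synthetic import MEGRecording
from .aae import LayerActivations, LAYER_IDS

__all__ = [
    "RDM",
    "TimeResolvedRDMs",
    "DecodingConfig",
    "preprocess_meg",
    "correlation_rdm",
    "subaverage_bins",
    "decoding_rdm",
    "time_resolved_rdms",
    "model_layer_rdms",
    "write_rdms_hdf5",
    "read_rdms_hdf5",
    "rdm_to_csv",
]


@dataclass
class RDM:
    """Square symmetric condition-dissimilarity matrix with provenance."""

    values: np.ndarray
    condition_ids: list | None = None
    source: str = ""
    dissimilarity_kind: str = "correlation_distance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("RDM must be symmetric")
        if self.dissimilarity_kind == "correlation_distance":
            if not np.allclose(np.diag(v), 0.0, atol=1e-8):
                raise ValueError("correlation-distance RDM must have zero diagonal")
            if v.min() < -1e-8 or v.max() > 2.0 + 1e-8:
                raise ValueError("correlation distances must lie in [0, 2]")
        elif self.dissimilarity_kind == "decoding_accuracy":
            off = v[~np.eye(v.shape[0], dtype=bool)]
            if off.size and (off.min() < -1e-8 or off.max() > 1.0 + 1e-8):
                raise ValueError("decoding accuracies must lie in [0, 1]")
        else:
            raise ValueError(f"unknown dissimilarity kind {self.dissimilarity_kind!r}")
        self.values = v
        if self.condition_ids is None:
            self.condition_ids = list(range(v.shape[0]))
        elif len(self.condition_ids) != v.shape[0]:
            raise ValueError("condition_ids length mismatch")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strict lower-triangle entries; the diagonal never enters statistics."""
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.values[i, j]


@dataclass
class TimeResolvedRDMs:
    """Per-subject sequence of decoding RDMs on a common time grid."""

    values: np.ndarray  # subject x time x condition x condition
    time_ms: np.ndarray
    condition_ids: list | None = None
    dissimilarity_kind: str = "decoding_accuracy"

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError("values must be subject x time x cond x cond")
        if self.values.shape[1] != len(self.time_ms):
            raise ValueError("time axis mismatch")
        if self.condition_ids is None:
            self.condition_ids = list(range(self.values.shape[-1]))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def rdm(self, subject: int, t_index: int) -> RDM:
        return RDM(self.values[subject, t_index],
                   condition_ids=list(self.condition_ids),
                   source=f"meg subject={subject} t={self.time_ms[t_index]:g}ms",
                   dissimilarity_kind=self.dissimilarity_kind)


@dataclass
class DecodingConfig:
    """Pairwise decoding parameters.

    ``backend='batched'`` uses the package's vectorized dual
    coordinate-descent linear SVM (solves every pair x fold x repeat
    problem of a time point in one numpy batch); ``backend='sklearn'``
    fits ``sklearn.svm.SVC(kernel='linear')`` per fold.  Both solve the
    same soft-margin problem and agree on decoding accuracy to within
    solver tolerance.
    """

    n_bins: int = 8
    svm_c: float = 1.0
    n_assignment_repeats: int = 3
    seed: int = 0
    backend: str = "batched"

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if self.n_assignment_repeats < 1:
            raise ValueError("need at least 1 assignment repeat")
        if self.backend not in ("batched", "sklearn"):
            raise ValueError(f"unknown backend {self.backend!r}")


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_meg(raw: MEGRecording,
                   baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
                   lowpass_hz: float = 30.0) -> MEGRecording:
    """Baseline mean removal per trial/sensor, then zero-phase low-pass.

    The filter is a 4th-order Butterworth applied forward and backward
    (``filtfilt``), so no phase delay shifts latencies.
    """
    t = raw.time_ms
    lo, hi = baseline_window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("baseline window outside epoch")
    nyq = raw.sampling_rate_hz / 2.0
    if lowpass_hz >= nyq:
        raise ValueError("low-pass cutoff must be below Nyquist")
    mask = (t >= lo) & (t <= hi)
    b, a = butter(4, lowpass_hz / nyq, btype="low")
    # process per subject to bound peak memory on large sensor arrays
    data = np.empty_like(raw.data)
    for s in range(raw.data.shape[0]):
        block = np.asarray(raw.data[s], dtype=np.float64)
        block = block - block[..., mask].mean(axis=-1, keepdims=True)
        data[s] = filtfilt(b, a, block, axis=-1)
    return MEGRecording(data=data, time_ms=t.copy(),
                        sampling_rate_hz=raw.sampling_rate_hz,
                        baseline_window_ms=baseline_window_ms)


# ---------------------------------------------------------------------------
# correlation-distance RDMs

def correlation_rdm(patterns: np.ndarray, condition_ids: list | None = None,
                    source: str = "") -> RDM:
    """1 - Pearson correlation between condition rows."""
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2:
        raise ValueError("patterns must be condition x feature")
    if patterns.shape[0] < 2 or patterns.shape[1] < 2:
        raise ValueError("need >= 2 conditions and >= 2 features")
    sd = patterns.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ([condition_ids[b] for b in bad] if condition_ids is not None
                 else bad.tolist())
        raise ValueError(f"zero-variance pattern for condition(s) {names}")
    vals = 1.0 - np.corrcoef(patterns)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(vals, 0.0)
    return RDM(values=vals, condition_ids=condition_ids, source=source)


def model_layer_rdms(acts: LayerActivations,
                     condition_ids: list | None = None) -> list[RDM]:
    """One correlation-distance RDM per layer, tagged with the layer id."""
    if not acts.data:
        raise ValueError("no activations given")
    out = []
    for lid in acts.layer_ids:
        out.append(correlation_rdm(acts[lid], condition_ids=condition_ids,
                                   source=f"layer:{lid}"))
    return out


# ---------------------------------------------------------------------------
# MEG decoding RDMs

def subaverage_bins(trials: np.ndarray, n_bins: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Randomly partition trials into near-equal bins; return bin means.

    The weighted grand mean of the pseudo-trials equals the grand mean of
    the input trials exactly.
    """
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < n_bins:
        raise ValueError(f"{n} trials cannot fill {n_bins} bins")
    order = rng.permutation(n)
    return np.stack([trials[chunk].mean(axis=0)
                     for chunk in np.array_split(order, n_bins)])


def _solve_linear_svm_batch(x: np.ndarray, y: np.ndarray, c: float,
                            max_passes: int = 60, tol: float = 1e-4
                            ) -> np.ndarray:
    """Dual coordinate descent for K independent hinge-loss linear SVMs.

    ``x``: (K, m, d) training samples (bias handled by an augmented
    constant feature), ``y``: (K, m) labels in {-1, +1}.  Returns the
    weight vectors (K, d).  This is the standard liblinear L1-SVM dual
    update, vectorized across the K problems.
    """
    k, m, d = x.shape
    q = np.maximum(np.einsum("kmd,kmd->km", x, x), 1e-12)
    alpha = np.zeros((k, m))
    w = np.zeros((k, d))
    for _ in range(max_passes):
        max_delta = 0.0
        for i in range(m):
            xi = x[:, i, :]
            grad = y[:, i] * np.einsum("kd,kd->k", w, xi) - 1.0
            a_new = np.clip(alpha[:, i] - grad / q[:, i], 0.0, c)
            delta = a_new - alpha[:, i]
            step = np.abs(delta).max()
            if step > max_delta:
                max_delta = step
            w += (delta * y[:, i])[:, None] * xi
            alpha[:, i] = a_new
        if max_delta < tol:
            break
    return w


def _pairwise_loo_accuracies(pseudo: np.ndarray, c: float) -> np.ndarray:
    """Decoding accuracy for every condition pair from pseudo-trials.

    ``pseudo``: (n_cond, n_bins, n_sensors).  Returns a symmetric
    (n_cond, n_cond) accuracy matrix (diagonal 0).  All pair x fold
    problems are solved in one batch.
    """
    n_cond, n_bins, _ = pseudo.shape
    aug = np.concatenate([pseudo, np.ones((n_cond, n_bins, 1))], axis=2)
    d = aug.shape[2]
    pairs = [(i, j) for i in range(n_cond) for j in range(i)]
    if not pairs:
        return np.zeros((n_cond, n_cond))
    # stacked samples per pair: first class i bins, then class j bins
    stacked = np.stack([np.concatenate([aug[i], aug[j]]) for i, j in pairs])
    y_full = np.concatenate([np.ones(n_bins), -np.ones(n_bins)])
    folds = np.arange(n_bins)
    train_idx = np.stack([np.delete(np.arange(2 * n_bins), [f, n_bins + f])
                          for f in folds])          # (folds, 2B-2)
    test_idx = np.stack([np.array([f, n_bins + f]) for f in folds])
    # batch over (pair, fold)
    xtr = stacked[:, train_idx, :]                   # (P, F, 2B-2, d)
    xte = stacked[:, test_idx, :]                    # (P, F, 2, d)
    n_pairs = len(pairs)
    xtr = xtr.reshape(n_pairs * n_bins, 2 * n_bins - 2, d)
    ytr = np.broadcast_to(y_full[train_idx], (n_pairs, n_bins, 2 * n_bins - 2)
                          ).reshape(n_pairs * n_bins, -1)
    w = _solve_linear_svm_batch(xtr, np.ascontiguousarray(ytr), c)
    scores = np.einsum("kd,ktd->kt", w, xte.reshape(n_pairs * n_bins, 2, d))
    preds = np.where(scores >= 0, 1.0, -1.0)
    correct = (preds == y_full[test_idx].reshape(1, n_bins, 2).repeat(
        n_pairs, axis=0).reshape(n_pairs * n_bins, 2)).sum(axis=1)
    acc = correct.reshape(n_pairs, n_bins).sum(axis=1) / (2 * n_bins)
    out = np.zeros((n_cond, n_cond))
    for (i, j), a in zip(pairs, acc):
        out[i, j] = out[j, i] = a
    return out


def _pair_loo_accuracy(a: np.ndarray, b: np.ndarray, c: float) -> float:
    """Leave-one-pseudo-trial-pair-out CV accuracy for one condition pair."""
    n_bins = a.shape[0]
    x = np.concatenate([a, b])
    y = np.concatenate([np.zeros(n_bins), np.ones(n_bins)])
    correct = 0
    for fold in range(n_bins):
        test = np.array([fold, n_bins + fold])
        train_mask = np.ones(2 * n_bins, dtype=bool)
        train_mask[test] = False
        clf = SVC(kernel="linear", C=c)
        clf.fit(x[train_mask], y[train_mask])
        correct += int((clf.predict(x[test]) == y[test]).sum())
    return correct / (2 * n_bins)


def decoding_rdm(recording: MEGRecording, t_ms: float,
                 config: DecodingConfig, subject: int = 0,
                 rng: np.random.Generator | None = None) -> RDM:
    """Pairwise SVM decoding-accuracy RDM for one subject at one time point.

    Per condition pair: trials are subaveraged into ``n_bins``
    pseudo-trials, a linear SVM is trained on all but one pseudo-trial per
    condition and tested on the held-out pair, rotating through every
    fold; accuracies are averaged over ``n_assignment_repeats`` random
    partitions.  The diagonal is stored as 0 by convention and flagged by
    ``dissimilarity_kind``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_idx = recording.time_index(t_ms)
    patterns = np.asarray(recording.data[subject, :, :, :, t_idx],
                          dtype=np.float64)  # cond x trial x sensor
    n_cond = patterns.shape[0]
    vals = np.zeros((n_cond, n_cond))
    for _ in range(config.n_assignment_repeats):
        pseudo = np.stack([subaverage_bins(patterns[ci], config.n_bins, rng)
                           for ci in range(n_cond)])
        if config.backend == "batched":
            vals += _pairwise_loo_accuracies(pseudo, config.svm_c)
        else:
            for i in range(n_cond):
                for j in range(i):
                    acc = _pair_loo_accuracy(pseudo[i], pseudo[j],
                                             config.svm_c)
                    vals[i, j] += acc
                    vals[j, i] += acc
    vals /= config.n_assignment_repeats
    return RDM(values=vals, source=f"meg subject={subject} t={t_ms:g}ms",
               dissimilarity_kind="decoding_accuracy")


def time_resolved_rdms(recording: MEGRecording, config: DecodingConfig,
                       stride_ms: float = 1.0,
                       tmin_ms: float | None = None,
                       tmax_ms: float | None = None) -> TimeResolvedRDMs:
    """Decoding RDMs at every strided time point, for every subject."""
    t = recording.time_ms
    lo = t[0] if tmin_ms is None else tmin_ms
    hi = t[-1] if tmax_ms is None else tmax_ms
    step = np.median(np.diff(t))
    stride = max(1, int(round(stride_ms / step)))
    sel = np.arange(len(t))[(t >= lo - 1e-9) & (t <= hi + 1e-9)][::stride]
    n_sub, n_cond = recording.data.shape[0], recording.data.shape[1]
    out = np.zeros((n_sub, len(sel), n_cond, n_cond))
    for s in range(n_sub):
        rng = np.random.default_rng([config.seed, s])
        for k, ti in enumerate(sel):
            out[s, k] = decoding_rdm(recording, t[ti], config, subject=s,
                                     rng=rng).values
    return TimeResolvedRDMs(values=out, time_ms=t[sel])


# ---------------------------------------------------------------------------
# interchange

def write_rdms_hdf5(trrdms: TimeResolvedRDMs, path, source: str = "meg") -> None:
    """RDM stack as ``rdms/<source>/<subject>`` datasets with a time axis."""
    import h5py

    with h5py.File(path, "w") as fh:
        grp = fh.create_group(f"rdms/{source}")
        for s in range(trrdms.n_subjects):
            d = grp.create_dataset(str(s), data=trrdms.values[s])
            d.attrs["time_ms"] = trrdms.time_ms
            d.attrs["dissimilarity_kind"] = trrdms.dissimilarity_kind


def read_rdms_hdf5(path, source: str = "meg") -> TimeResolvedRDMs:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh[f"rdms/{source}"]
        subjects = sorted(grp, key=int)
        values = np.stack([grp[s][...] for s in subjects])
        time_ms = grp[subjects[0]].attrs["time_ms"]
        kind = grp[subjects[0]].attrs["dissimilarity_kind"]
    return TimeResolvedRDMs(values=values, time_ms=np.asarray(time_ms),
                            dissimilarity_kind=str(kind))


def rdm_to_csv(rdm: RDM, path) -> None:
    """Single RDM as a labelled CSV matrix."""
    import pandas as pd

    pd.DataFrame(rdm.values, index=rdm.condition_ids,
                 columns=rdm.condition_ids).to_csv(path)
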