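"""Model-brain RDM comparison: Spearman RSA, noise ceilings, layer similarity.

All comparisons operate on the strict lower triangle of each RDM
(Spearman rank correlation), so the decoding-RDM diagonal convention
never enters any statistic.  fMRI ROI profiles can be normalized by a
leave-one-out noise ceiling; MEG time series are left raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .rdm import RDM, TimeResolvedRDMs

__all__ = [
    "CorrelationSeries",
    "ROICorrelationProfile",
    "LayerSimilarityMatrix",
    "rdm_spearman",
    "layer_time_correlation",
    "roi_correlation_profile",
    "noise_ceiling",
    "normalize_by_ceiling",
    "layer_similarity_matrix",
    "mean_rdm",
]


@dataclass
class CorrelationSeries:
    """Subject x layer x time Spearman correlations of brain vs model RDMs."""

    values: np.ndarray
    time_ms: np.ndarray
    layer_ids: list[str]

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be subject x layer x time")
        if self.values.shape[1] != len(self.layer_ids):
            raise ValueError("layer axis mismatch")
        if self.values.shape[2] != len(self.time_ms):
            raise ValueError("time axis mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def subject_mean(self) -> np.ndarray:
        """Layer x time group-average trace."""
        return self.values.mean(axis=0)

    def layer(self, layer_id: str) -> np.ndarray:
        return self.values[:, self.layer_ids.index(layer_id), :]


@dataclass
class ROICorrelationProfile:
    """Per-subject layer profile of Spearman correlations with one ROI."""

    values: np.ndarray  # subject x layer
    layer_ids: list[str]
    roi_name: str = "ROI"
    ceiling: tuple[float, float] | None = None  # (lower, upper)
    normalized: bool = False

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("values must be subject x layer")
        if self.values.shape[1] != len(self.layer_ids):
            raise ValueError("layer axis mismatch")
        if self.ceiling is not None and self.ceiling[0] > self.ceiling[1] + 1e-12:
            raise ValueError("ceiling lower bound exceeds upper bound")

    @property
    def subject_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def subject_sem(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) / np.sqrt(self.values.shape[0])


@dataclass
class LayerSimilarityMatrix:
    """Layer x layer Pearson correlations of RDM lower triangles."""

    values: np.ndarray
    layer_ids: list[str]

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("diagonal must be 1")


def _check_match(a: RDM, b: RDM) -> None:
    if a.n_conditions != b.n_conditions:
        raise ValueError("RDMs have different condition counts")
    if a.condition_ids != b.condition_ids:
        raise ValueError("RDM condition orderings differ")


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho; 0.0 when either vector is constant (no rank information)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1])


def rdm_spearman(a: RDM, b: RDM) -> float:
    """Spearman rank correlation over strict lower-triangle entries."""
    _check_match(a, b)
    return _spearman(a.lower_triangle(), b.lower_triangle())


def layer_time_correlation(model_rdms: list[RDM],
                           brain: TimeResolvedRDMs) -> CorrelationSeries:
    """Spearman(model layer RDM, brain RDM at t) per subject, layer, time."""
    layer_ids = [r.source.removeprefix("layer:") or f"layer{k}"
                 for k, r in enumerate(model_rdms)]
    n_sub, n_t = brain.values.shape[:2]
    out = np.zeros((n_sub, len(model_rdms), n_t))
    tri = np.tril_indices(brain.values.shape[-1], k=-1)
    model_tris = [r.lower_triangle() for r in model_rdms]
    for r in model_rdms:
        if r.n_conditions != brain.values.shape[-1]:
            raise ValueError("model and brain RDM condition counts differ")
    for s in range(n_sub):
        for t in range(n_t):
            brain_tri = brain.values[s, t][tri]
            for li, mt in enumerate(model_tris):
                out[s, li, t] = _spearman(mt, brain_tri)
    return CorrelationSeries(values=out, time_ms=brain.time_ms,
                             layer_ids=layer_ids)


def roi_correlation_profile(model_rdms: list[RDM],
                            roi_rdms: list[RDM],
                            roi_name: str | None = None,
                            with_ceiling: bool = True) -> ROICorrelationProfile:
    """Per-subject, per-layer Spearman correlation with ROI RDMs."""
    layer_ids = [r.source.removeprefix("layer:") or f"layer{k}"
                 for k, r in enumerate(model_rdms)]
    vals = np.array([[rdm_spearman(mr, rr) for mr in model_rdms]
                     for rr in roi_rdms])
    ceiling = noise_ceiling(roi_rdms) if (with_ceiling and len(roi_rdms) >= 2) else None
    if roi_name is None:
        roi_name = roi_rdms[0].source or "ROI"
    return ROICorrelationProfile(values=vals, layer_ids=layer_ids,
                                 roi_name=roi_name, ceiling=ceiling)


def mean_rdm(rdms: list[RDM]) -> RDM:
    """Element-wise mean RDM across subjects."""
    vals = np.mean([r.values for r in rdms], axis=0)
    return RDM(values=vals, condition_ids=list(rdms[0].condition_ids),
               source="mean", dissimilarity_kind=rdms[0].dissimilarity_kind)


def noise_ceiling(subject_rdms: list[RDM]) -> tuple[float, float]:
    """Leave-one-out noise ceiling (lower, upper) under Spearman.

    upper: mean over subjects of Spearman(subject RDM, all-subject mean
    RDM); lower: same against the mean of the *other* subjects.  The
    upper bound includes each subject in its own reference and so
    overestimates the attainable group correlation; the lower bound
    underestimates it.
    """
    n = len(subject_rdms)
    if n < 2:
        raise ValueError("noise ceiling needs >= 2 subjects")
    grand = mean_rdm(subject_rdms)
    upper = float(np.mean([rdm_spearman(r, grand) for r in subject_rdms]))
    lowers = []
    for i, r in enumerate(subject_rdms):
        others = mean_rdm([x for j, x in enumerate(subject_rdms) if j != i])
        lowers.append(rdm_spearman(r, others))
    lower = float(np.mean(lowers))
    return lower, upper


def normalize_by_ceiling(profile: ROICorrelationProfile,
                         bound: str = "lower") -> ROICorrelationProfile:
    """Divide every correlation by the chosen noise-ceiling bound."""
    if profile.ceiling is None:
        raise ValueError("profile has no noise ceiling")
    ref = profile.ceiling[0] if bound == "lower" else profile.ceiling[1]
    if ref <= 0:
        raise ValueError(
            f"noise-ceiling {bound} bound is {ref:.3f} <= 0; "
            "normalization is undefined")
    return replace(profile, values=profile.values / ref, normalized=True)


def layer_similarity_matrix(model_rdms: list[RDM]) -> LayerSimilarityMatrix:
    """Pearson correlation of RDM lower triangles for every layer pair."""
    if len(model_rdms) < 2:
        raise ValueError("need >= 2 layers")
    layer_ids = [r.source.removeprefix("layer:") or f"layer{k}"
                 for k, r in enumerate(model_rdms)]
    tris = np.stack([r.lower_triangle() for r in model_rdms])
    vals = np.corrcoef(tris)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return LayerSimilarityMatrix(values=vals, layer_ids=layer_ids)
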