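"""Synthetic stimuli and neural recordings with planted representational geometry.

Every downstream stage of the pipeline (network training, decoding RDMs,
RSA, cluster/bootstrap statistics) is exercised against data whose ground
truth is known by construction:

* :func:`generate_image_dataset` draws four procedurally distinct stimulus
  categories (faces, animates, objects, scenes) so that category structure
  exists both at the pixel level and, more strongly, at coarser spatial
  scales.
* :func:`generate_meg_recording` plants representational geometries
  (target RDMs) into sensor-space epochs at chosen latencies, wrapped in a
  Gaussian temporal kernel plus white trial noise.
* :func:`generate_fmri_patterns` embeds one geometry into voxel patterns
  shared across subjects, plus independent subject noise.

Pattern embedding guarantees that, at zero noise, the correlation-distance
matrix of the embedded condition patterns equals the target RDM (up to
positive-semidefinite truncation of the implied correlation matrix).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "ImageSet",
    "PlantedGeometry",
    "MEGRecording",
    "FMRIPatterns",
    "CATEGORY_NAMES",
    "generate_image_dataset",
    "generate_meg_recording",
    "generate_fmri_patterns",
    "generate_probe_images",
    "categorical_block_rdm",
    "random_rdm",
    "rescale_rdm",
    "embed_rdm_patterns",
    "gaussian_kernel",
    "write_imageset",
    "read_imageset",
    "write_recording_hdf5",
    "read_recording_hdf5",
]

CATEGORY_NAMES = ("faces", "animates", "objects", "scenes")


@dataclass
class ImageSet:
    """Labelled category images; intensities in [-1, 1], layout N x H x W x C."""

    images: np.ndarray
    labels: np.ndarray
    category_names: tuple[str, ...] = CATEGORY_NAMES

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4:
            raise ValueError("images must be N x H x W x C")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images length mismatch")
        if self.images.size and (self.images.min() < -1.0 - 1e-9
                                 or self.images.max() > 1.0 + 1e-9):
            raise ValueError("image intensities must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class PlantedGeometry:
    """A target RDM expressed in a temporal window of the epoch."""

    rdm_target: np.ndarray
    latency_ms: float
    width_ms: float = 50.0
    amplitude: float = 1.0
    name: str = ""

    def __post_init__(self):
        rdm = np.asarray(self.rdm_target, dtype=np.float64)
        if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
            raise ValueError("rdm_target must be square")
        if not np.allclose(rdm, rdm.T, atol=1e-10):
            raise ValueError("rdm_target must be symmetric")
        if not np.allclose(np.diag(rdm), 0.0, atol=1e-10):
            raise ValueError("rdm_target must have zero diagonal")
        if rdm.min() < -1e-12:
            raise ValueError("rdm_target must be nonnegative")
        self.rdm_target = rdm

    @property
    def n_conditions(self) -> int:
        return self.rdm_target.shape[0]


@dataclass
class MEGRecording:
    """Sensor-space epochs: subject x condition x trial x sensor x time."""

    data: np.ndarray
    time_ms: np.ndarray
    sampling_rate_hz: float = 1000.0
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 5:
            raise ValueError("data must be subject x condition x trial x sensor x time")
        if self.data.shape[-1] != len(self.time_ms):
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.time_ms - t_ms)))


@dataclass
class FMRIPatterns:
    """Response patterns (t-value-like): subject x condition x voxel."""

    data: np.ndarray
    roi_name: str = "ROI"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be subject x condition x voxel")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("patterns must be finite")


# ---------------------------------------------------------------------------
# image families

def _grid(size: int):
    ax = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(ax, ax, indexing="xy")


def _soft_disc(xx, yy, cx, cy, rx, ry, sharp=25.0):
    d = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    return expit(-sharp * (d - 1.0))


def _face(xx, yy, rng):
    """Mirror-symmetric blob arrangement: head, two eyes, mouth."""
    img = np.zeros_like(xx)
    hr = 0.75 + 0.2 * rng.uniform(-1, 1)
    img += rng.uniform(0.6, 1.0) * _soft_disc(xx, yy, 0.0, 0.08 * rng.uniform(-1, 1),
                                              hr, hr * rng.uniform(1.0, 1.3))
    ex = 0.30 + 0.13 * rng.uniform(-1, 1)
    ey = -0.22 + 0.12 * rng.uniform(-1, 1)
    er = 0.08 + 0.08 * rng.uniform()
    for sx in (-1, 1):
        img -= rng.uniform(0.6, 1.0) * _soft_disc(xx, yy, sx * ex, ey, er, er)
    my = 0.35 + 0.15 * rng.uniform(-1, 1)
    img -= rng.uniform(0.4, 0.8) * _soft_disc(xx, yy, 0.0, my,
                                              0.3 + 0.12 * rng.uniform(-1, 1), 0.1)
    return img


def _animate(xx, yy, rng):
    """Curved closed contour: radial sum-of-sines blob with limb lobes."""
    theta = np.arctan2(yy, xx)
    r = np.sqrt(xx**2 + yy**2)
    k = rng.integers(2, 7)
    phase = rng.uniform(0, 2 * np.pi)
    radius = (0.55 + 0.12 * rng.uniform(-1, 1)
              + rng.uniform(0.1, 0.28) * np.sin(k * theta + phase)
              + 0.08 * np.sin(2 * theta))
    body = expit(-30.0 * (r - radius))
    return 0.9 * body - 0.25 * _soft_disc(xx, yy, 0.35 * rng.uniform(-1, 1),
                                          -0.3, 0.12, 0.12)


def _object(xx, yy, rng):
    """Rectilinear composition: a few axis-aligned rectangles."""
    img = np.zeros_like(xx)
    for _ in range(rng.integers(1, 6)):
        cx, cy = rng.uniform(-0.6, 0.6, size=2)
        w, h = rng.uniform(0.15, 0.9, size=2)
        rect = (np.abs(xx - cx) < w / 2) & (np.abs(yy - cy) < h / 2)
        img += rng.uniform(0.4, 1.0) * rect
    return np.clip(img, 0, 1.2) - 0.3


def _scene(xx, yy, rng):
    """Full-field layout: horizon gradient plus band-limited texture."""
    horizon = rng.uniform(-0.5, 0.5)
    sky = expit(rng.uniform(5.0, 12.0) * (horizon - yy))
    freq = rng.uniform(3.0, 10.0)
    texture = (rng.uniform(0.15, 0.45)
               * np.sin(freq * np.pi * xx + rng.uniform(0, 2 * np.pi))
               * (yy > horizon))
    return 0.8 * sky - 0.4 + texture


_FAMILIES = (_face, _animate, _object, _scene)
# fixed colour tint per category (applied weakly; structure carries the signal)
_TINTS = np.array([
    [1.0, 0.85, 0.75],
    [0.8, 1.0, 0.8],
    [0.85, 0.85, 1.0],
    [1.0, 1.0, 0.85],
])


def generate_image_dataset(n_per_category: int, size: int = 64,
                           seed: int = 0) -> ImageSet:
    """Draw ``4 * n_per_category`` procedural category images.

    Categories are visually distinct parametric families with per-image
    random variation.  Images are returned category-blocked (all faces,
    then animates, objects, scenes) with intensities in [-1, 1].
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    xx, yy = _grid(size)
    images = np.empty((4 * n_per_category, size, size, 3))
    labels = np.empty(4 * n_per_category, dtype=np.int64)
    i = 0
    for cat, family in enumerate(_FAMILIES):
        for _ in range(n_per_category):
            # global translation jitter: large pixel-space variability that
            # a compressed representation can absorb into few factors, so
            # category structure dominates deep but not shallow geometry
            dx, dy = rng.uniform(-0.2, 0.2, size=2)
            base = family(xx - dx, yy - dy, rng)
            base = base + 0.05 * rng.standard_normal(base.shape)
            rgb = base[..., None] * _TINTS[cat][None, None, :]
            images[i] = np.clip(rgb, -1.0, 1.0)
            labels[i] = cat
            i += 1
    return ImageSet(images=images, labels=labels)


def generate_probe_images(n_images: int, size: int = 64,
                          seed: int = 0) -> ImageSet:
    """Spectrally rich unstructured probe stimuli (octave-band noise).

    Unlike the category set, probe images share no dominant structural
    dimension, so network layers respond to them with clearly
    differentiated geometries; they are the right condition set for
    experiments that must tell individual layer RDMs apart.
    """
    if n_images < 2:
        raise ValueError("need at least 2 probe images")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    images = np.empty((n_images, size, size, 3))
    for i in range(n_images):
        base = _multiscale_texture(size, rng)
        images[i] = np.clip(base[..., None].repeat(3, axis=2), -1.0, 1.0)
    return ImageSet(images=images, labels=np.zeros(n_images, dtype=np.int64),
                    category_names=("probe",))


_OCTAVE_AMPS = (0.35, 0.25, 0.15, 0.08, 0.04)  # fine -> coarse pixel sd


def _multiscale_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-image random texture with one white-noise band per octave."""
    out = np.zeros((size, size))
    for octave, amp in enumerate(_OCTAVE_AMPS):
        cells = max(2, size >> octave)
        band = rng.standard_normal((cells, cells))
        rep = size // cells
        if rep > 1:
            band = band.repeat(rep, axis=0).repeat(rep, axis=1)
        out += amp * band[:size, :size]
    return out


# ---------------------------------------------------------------------------
# geometry embedding

def categorical_block_rdm(n_conditions: int, n_categories: int = 4,
                          within: float = 0.3, between: float = 1.0) -> np.ndarray:
    """Block RDM: low dissimilarity within category, high between.

    Conditions are assumed category-blocked (equal counts per category).
    """
    if n_conditions % n_categories:
        raise ValueError("n_conditions must be divisible by n_categories")
    labels = np.repeat(np.arange(n_categories), n_conditions // n_categories)
    rdm = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rescale_rdm(rdm: np.ndarray, lo: float = 0.4, hi: float = 1.4) -> np.ndarray:
    """Affinely map off-diagonal dissimilarities onto [lo, hi].

    Strictly increasing, so rank-based recovery statistics are unchanged,
    but geometries of very different absolute scale (e.g. deep-layer RDMs
    whose dissimilarities are a few percent) become equally decodable
    when embedded into sensor patterns.
    """
    rdm = np.asarray(rdm, dtype=np.float64)
    off = ~np.eye(rdm.shape[0], dtype=bool)
    vals = rdm[off]
    lo_v, hi_v = vals.min(), vals.max()
    if hi_v - lo_v < 1e-12:
        raise ValueError("cannot rescale an RDM with constant dissimilarities")
    out = np.zeros_like(rdm)
    out[off] = lo + (rdm[off] - lo_v) * (hi - lo) / (hi_v - lo_v)
    return out


def random_rdm(n_conditions: int, rng: np.random.Generator,
               n_features: int | None = None) -> np.ndarray:
    """Correlation-distance RDM of random Gaussian patterns.

    Guaranteed embeddable (its correlation matrix is a Gram matrix) with
    continuous, tie-free dissimilarities; two independent draws have
    uncorrelated geometries.
    """
    if n_features is None:
        n_features = n_conditions + 8
    pats = rng.standard_normal((n_conditions, n_features))
    rdm = 1.0 - np.corrcoef(pats)
    np.fill_diagonal(rdm, 0.0)
    return (rdm + rdm.T) / 2.0


def embed_rdm_patterns(rdm: np.ndarray, n_features: int,
                       rng: np.random.Generator,
                       amplitude: float = 1.0) -> np.ndarray:
    """Embed a correlation-distance RDM as condition x feature patterns.

    Factorizes the implied correlation matrix ``R = 1 - rdm`` (negative
    eigenvalues truncated) and maps the factors through a random
    orthonormal, zero-mean feature basis.  The Pearson correlation of any
    two output rows then equals ``R[i, j]`` exactly whenever R is positive
    semidefinite, so the patterns' correlation-distance RDM reproduces the
    target.
    """
    rdm = np.asarray(rdm, dtype=np.float64)
    n_cond = rdm.shape[0]
    if n_features < n_cond:
        raise ValueError("need n_features >= number of conditions")
    corr = 1.0 - rdm
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    keep = evals > 1e-10
    factors = evecs[:, keep] * np.sqrt(evals[keep])  # n_cond x d
    d = factors.shape[1]
    # orthonormal rows, each orthogonal to the constant vector so that
    # per-row means vanish and Pearson centering is a no-op
    basis = rng.standard_normal((d, n_features))
    basis -= basis.mean(axis=1, keepdims=True)
    basis = np.linalg.qr(basis.T)[0].T  # d x n_features, orthonormal rows
    basis -= basis.mean(axis=1, keepdims=True)  # re-center (QR can reintroduce mean)
    basis = np.linalg.qr(basis.T)[0].T
    basis -= basis.mean(axis=1, keepdims=True)
    return amplitude * np.sqrt(n_features) * (factors @ basis)


def gaussian_kernel(time_ms: np.ndarray, latency_ms: float,
                    width_ms: float) -> np.ndarray:
    """Unit-peak Gaussian bump; ``width_ms`` is twice the standard deviation."""
    sd = width_ms / 2.0
    return np.exp(-0.5 * ((time_ms - latency_ms) / sd) ** 2)


def generate_meg_recording(geometries: list[PlantedGeometry],
                           n_subjects: int = 15,
                           n_trials: int = 25,
                           n_sensors: int = 306,
                           noise_sd: float = 1.0,
                           seed: int = 0,
                           tmin_ms: float = -200.0,
                           tmax_ms: float = 1000.0,
                           sampling_rate_hz: float = 1000.0,
                           dtype=np.float32) -> MEGRecording:
    """Sensor epochs with planted geometries at known latencies.

    The condition signal at time t is the sum over geometries of a
    Gaussian temporal kernel times a sensor embedding of the geometry's
    target RDM; the embedding is shared across subjects (shared group
    geometry) while trial noise is white Gaussian per subject/trial.
    """
    if not geometries:
        raise ValueError("need at least one geometry")
    n_cond = geometries[0].n_conditions
    if any(g.n_conditions != n_cond for g in geometries):
        raise ValueError("all geometries must share one condition count")
    step = 1000.0 / sampling_rate_hz
    time_ms = np.arange(tmin_ms, tmax_ms, step)
    for g in geometries:
        if not (time_ms[0] < g.latency_ms < time_ms[-1]):
            raise ValueError(f"latency {g.latency_ms} ms outside epoch")
    rng = np.random.default_rng(seed)
    signal = np.zeros((n_cond, n_sensors, len(time_ms)))
    for g in geometries:
        patterns = embed_rdm_patterns(g.rdm_target, n_sensors, rng, g.amplitude)
        kernel = gaussian_kernel(time_ms, g.latency_ms, g.width_ms)
        signal += patterns[:, :, None] * kernel[None, None, :]
    shape = (n_subjects, n_cond, n_trials, n_sensors, len(time_ms))
    data = rng.standard_normal(shape, dtype=np.float32).astype(dtype, copy=False)
    data *= dtype(noise_sd) if dtype == np.float32 else noise_sd
    data += signal[None, :, None, :, :].astype(dtype)
    return MEGRecording(data=data, time_ms=time_ms,
                        sampling_rate_hz=sampling_rate_hz)


def generate_fmri_patterns(geometry: PlantedGeometry,
                           n_subjects: int = 15,
                           n_voxels: int = 500,
                           noise_sd: float = 1.0,
                           seed: int = 0,
                           roi_name: str = "ROI") -> FMRIPatterns:
    """Voxel patterns = shared geometry embedding + per-subject white noise."""
    if n_voxels < geometry.n_conditions:
        raise ValueError("n_voxels must be >= number of conditions")
    rng = np.random.default_rng(seed)
    shared = embed_rdm_patterns(geometry.rdm_target, n_voxels, rng,
                                geometry.amplitude)
    noise = noise_sd * rng.standard_normal(
        (n_subjects, geometry.n_conditions, n_voxels))
    return FMRIPatterns(data=shared[None] + noise, roi_name=roi_name)


# ---------------------------------------------------------------------------
# plain-text / HDF5 interchange

def write_imageset(imageset: ImageSet, directory: str | Path) -> Path:
    """PNG files plus a CSV manifest (filename, category)."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "category"])
        for i, (img, lab) in enumerate(zip(imageset.images, imageset.labels)):
            name = f"img_{i:04d}.png"
            arr = np.clip((img + 1.0) * 127.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / name)
            writer.writerow([name, imageset.category_names[lab]])
    return manifest


def read_imageset(directory: str | Path) -> ImageSet:
    from PIL import Image

    directory = Path(directory)
    rows = list(csv.DictReader(open(directory / "manifest.csv")))
    names = sorted({r["category"] for r in rows})
    order = {n: i for i, n in enumerate(CATEGORY_NAMES) if n in names}
    if len(order) != len(names):  # categories outside the canonical four
        order = {n: i for i, n in enumerate(names)}
    images, labels = [], []
    for r in rows:
        arr = np.asarray(Image.open(directory / r["filename"]), dtype=np.float64)
        images.append(arr / 127.5 - 1.0)
        labels.append(order[r["category"]])
    return ImageSet(images=np.stack(images), labels=np.asarray(labels),
                    category_names=tuple(order))


def write_recording_hdf5(rec: MEGRecording, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data)
        fh.create_dataset("time_ms", data=rec.time_ms)
        fh.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        fh.attrs["n_trials"] = rec.data.shape[2]
        fh.attrs["baseline_window_ms"] = rec.baseline_window_ms


def read_recording_hdf5(path: str | Path) -> MEGRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        return MEGRecording(
            data=fh["data"][...],
            time_ms=fh["time_ms"][...],
            sampling_rate_hz=float(fh.attrs["sampling_rate_hz"]),
            baseline_window_ms=tuple(fh.attrs["baseline_window_ms"]),
        )
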