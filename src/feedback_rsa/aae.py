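"""Convolutional adversarial autoencoder with per-block activation access.

The generator is an autoencoder: five convolutional encoder blocks
(E1-E5, each batch-norm -> conv -> leaky-ReLU -> 2x2 max-pool), a fully
connected layer E6, a linear latent projection LV, a fully connected
decoder entry D1, and five deconvolutional blocks (D2-D6, each
batch-norm -> conv -> leaky-ReLU -> 2x2 nearest upsampling; D6 maps to
image channels and ends in tanh).  That is 13 parameterized layers along
the generator.  A small fully connected discriminator receives the latent
vector concatenated with a one-hot category label and, through an
adversarial game, shapes the aggregate latent posterior toward a standard
normal prior.

Training alternates a reconstruction update (pixel MSE) with an
adversarial regularization update per minibatch.  Reported reconstruction
performance uses mean absolute error; the training criterion itself is
squared error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .synthetic import ImageSet

__all__ = [
    "AAEConfig",
    "AAEModel",
    "TrainingTrace",
    "LayerActivations",
    "LAYER_IDS",
    "build_model",
    "desk_scale_config",
    "make_plain_autoencoder",
    "make_untrained_model",
    "preprocess_images",
    "reconstruction_loss",
    "adversarial_step",
    "train",
    "extract_activations",
    "save_model",
    "load_model",
]

ENCODER_IDS = ("E1", "E2", "E3", "E4", "E5", "E6")
DECODER_IDS = ("D1", "D2", "D3", "D4", "D5", "D6")
LAYER_IDS = ENCODER_IDS + ("LV",) + DECODER_IDS


@dataclass
class AAEConfig:
    image_size: int = 64
    image_channels: int = 3
    channels_per_block: tuple[int, ...] = (16, 32, 64, 128, 256)
    decoder_channels: tuple[int, ...] | None = None  # None mirrors encoder
    latent_dim: int = 128
    n_categories: int = 4
    discriminator_layers: int = 3
    discriminator_width: int = 64
    leaky_slope: float = 0.2
    lr_generator: float = 1e-3
    lr_discriminator: float = 3e-3
    lr_adversarial: float = 2e-3
    epochs: int = 30
    batch_size: int = 64
    lr_decay: float = 0.05  # final lr fraction, linear schedule over epochs
    augment_shift_px: int = 0  # random circular shift augmentation (0 = off)
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 32 != 0:
            raise ValueError("image_size must be divisible by 2^5 = 32")
        if len(self.channels_per_block) != 5:
            raise ValueError("channels_per_block must list 5 widths")
        if (self.decoder_channels is not None
                and len(self.decoder_channels) != 5):
            raise ValueError("decoder_channels must list 5 widths")
        if self.latent_dim < self.n_categories:
            raise ValueError("latent_dim must be >= n_categories")
        if self.discriminator_layers < 2:
            raise ValueError("discriminator needs >= 2 layers")

    @property
    def bottleneck_spatial(self) -> int:
        return self.image_size // 32

    @property
    def e6_width(self) -> int:
        return 2 * self.latent_dim


@dataclass
class TrainingTrace:
    reconstruction_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    config: AAEConfig | None = None

    def __len__(self) -> int:
        return len(self.reconstruction_loss)


@dataclass
class LayerActivations:
    """Mapping layer id -> condition x feature matrix of flattened activations."""

    data: dict[str, np.ndarray]

    def __getitem__(self, layer_id: str) -> np.ndarray:
        return self.data[layer_id]

    @property
    def layer_ids(self) -> list[str]:
        return list(self.data)


class AAEModel:
    """Generator (encoder + decoder) and optional discriminator."""

    def __init__(self, config: AAEConfig, with_discriminator: bool = True):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels_per_block
        slope = config.leaky_slope
        s = config.bottleneck_spatial
        c_in = config.image_channels

        def conv_block(cin, cout):
            return nn.Sequential([
                nn.BatchNorm2d(cin),
                nn.Conv2d(cin, cout, 3, rng),
                nn.LeakyReLU(slope),
                nn.MaxPool2d(),
            ])

        self.blocks: dict[str, nn.Sequential] = {}
        prev = c_in
        for name, cout in zip(("E1", "E2", "E3", "E4", "E5"), ch):
            self.blocks[name] = conv_block(prev, cout)
            prev = cout
        flat = ch[4] * s * s
        self.blocks["E6"] = nn.Sequential([
            nn.Flatten(),
            nn.Dense(flat, config.e6_width, rng),
            nn.LeakyReLU(slope),
        ])
        self.blocks["LV"] = nn.Sequential([
            nn.Dense(config.e6_width, config.latent_dim, rng),
        ])
        dec_ch = config.decoder_channels or (ch[4], ch[3], ch[2], ch[1], ch[0])
        self.blocks["D1"] = nn.Sequential([
            nn.Dense(config.latent_dim, dec_ch[0] * s * s, rng),
            nn.LeakyReLU(slope),
            nn.Reshape((dec_ch[0], s, s)),
        ])
        for i, name in enumerate(("D2", "D3", "D4", "D5")):
            self.blocks[name] = nn.Sequential([
                nn.BatchNorm2d(dec_ch[i]),
                nn.Conv2d(dec_ch[i], dec_ch[i + 1], 3, rng),
                nn.LeakyReLU(slope),
                nn.Upsample2d(),
            ])
        self.blocks["D6"] = nn.Sequential([
            nn.BatchNorm2d(dec_ch[4]),
            nn.Conv2d(dec_ch[4], c_in, 3, rng),
            nn.Upsample2d(),
            nn.Tanh(),
        ])

        self.discriminator: nn.Sequential | None = None
        if with_discriminator:
            width = config.discriminator_width
            sizes = ([config.latent_dim + config.n_categories]
                     + [width] * (config.discriminator_layers - 1) + [1])
            layers: list[nn.Layer] = []
            for i in range(len(sizes) - 1):
                layers.append(nn.Dense(sizes[i], sizes[i + 1], rng))
                if i < len(sizes) - 2:
                    layers.append(nn.LeakyReLU(slope))
            self.discriminator = nn.Sequential(layers)

    # -- parameter groups ---------------------------------------------------
    def encoder_params(self) -> list[nn.Param]:
        out = []
        for name in ENCODER_IDS + ("LV",):
            out.extend(self.blocks[name].params())
        return out

    def generator_params(self) -> list[nn.Param]:
        out = self.encoder_params()
        for name in DECODER_IDS:
            out.extend(self.blocks[name].params())
        return out

    @property
    def n_parameterized_layers(self) -> int:
        """Count of conv/dense layers along the generator (13 by design)."""
        count = 0
        for name in LAYER_IDS:
            for layer in self.blocks[name].layers:
                if isinstance(layer, (nn.Conv2d, nn.Dense)):
                    count += 1
        return count

    # -- forward passes -----------------------------------------------------
    def forward_generator(self, x: np.ndarray, train: bool = True
                          ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Reconstruction plus every intermediate block output (NCHW in/out)."""
        acts: dict[str, np.ndarray] = {}
        h = x
        for name in LAYER_IDS:
            h = self.blocks[name].forward(h, train=train)
            acts[name] = h
        return h, acts

    def encode(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = x
        for name in ENCODER_IDS + ("LV",):
            h = self.blocks[name].forward(h, train=train)
        return h

    def backward_generator(self, grad: np.ndarray) -> None:
        for name in reversed(LAYER_IDS):
            grad = self.blocks[name].backward(grad)

    def backward_encoder(self, grad: np.ndarray) -> None:
        for name in reversed(ENCODER_IDS + ("LV",)):
            grad = self.blocks[name].backward(grad)

    def discriminate(self, latent: np.ndarray, onehot: np.ndarray,
                     train: bool = True) -> np.ndarray:
        if self.discriminator is None:
            raise RuntimeError("model has no discriminator")
        return self.discriminator.forward(
            np.concatenate([latent, onehot], axis=1), train=train)


def desk_scale_config(seed: int = 0, epochs: int = 250) -> AAEConfig:
    """Small 32x32 configuration that converges in minutes on one CPU.

    The full-scale 224x224 architecture is a config point
    (``AAEConfig(image_size=224, ...)``); this desk-scale variant keeps
    the same 13-layer structure at reduced width.
    """
    return AAEConfig(image_size=32, channels_per_block=(8, 12, 16, 24, 32),
                     latent_dim=16, epochs=epochs, batch_size=32, seed=seed)


def build_model(config: AAEConfig) -> AAEModel:
    """Initialized adversarial autoencoder with seeded random weights."""
    return AAEModel(config, with_discriminator=True)


def make_plain_autoencoder(config: AAEConfig) -> AAEModel:
    """Ablation: same generator, no discriminator, reconstruction loss only."""
    return AAEModel(config, with_discriminator=False)


def make_untrained_model(config: AAEConfig, seed: int | None = None) -> AAEModel:
    """Ablation: full architecture with seeded random weights, never updated."""
    if seed is not None:
        config = AAEConfig(**{**asdict(config), "seed": seed})
    return AAEModel(config, with_discriminator=True)


# ---------------------------------------------------------------------------
# data plumbing

def images_to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(images, (0, 3, 1, 2)),
                                dtype=nn.DTYPE)


def preprocess_images(raw: np.ndarray, size: int,
                      labels: np.ndarray | None = None,
                      category_names: tuple[str, ...] | None = None) -> ImageSet:
    """Resize to ``size`` and map intensities [0, 255] -> [-1, 1]."""
    from skimage.transform import resize

    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim == 3:
        raw = raw[None]
    if raw.size == 0:
        raise ValueError("empty image input")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw intensities must lie in [0, 255]")
    out = np.empty((raw.shape[0], size, size, raw.shape[3]))
    for i, img in enumerate(raw):
        if img.shape[:2] != (size, size):
            img = resize(img, (size, size), anti_aliasing=True,
                         preserve_range=True)
        out[i] = img
    out = out / 127.5 - 1.0
    if labels is None:
        labels = np.zeros(len(out), dtype=np.int64)
    kw = {}
    if category_names is not None:
        kw["category_names"] = category_names
    return ImageSet(images=np.clip(out, -1.0, 1.0), labels=labels, **kw)


def reconstruction_loss(x: np.ndarray, fx: np.ndarray, mode: str = "mse") -> float:
    """Per-pixel reconstruction error.

    ``mode='mse'`` is the training criterion (mean squared error);
    ``mode='mae'`` is the reporting metric (mean absolute error).
    """
    x, fx = np.asarray(x), np.asarray(fx)
    if x.shape != fx.shape:
        raise ValueError("x and fx must have the same shape")
    if mode == "mse":
        return float(np.mean((x - fx) ** 2))
    if mode == "mae":
        return float(np.mean(np.abs(x - fx)))
    raise ValueError(f"unknown mode {mode!r}")


def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(idx), n))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def draw_fake_codes(n: int, n_categories: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Uniform random one-hot category codes for prior-side samples."""
    return _onehot(rng.integers(0, n_categories, size=n), n_categories)


def adversarial_step(model: AAEModel, batch_x: np.ndarray,
                     batch_labels: np.ndarray, rng: np.random.Generator,
                     opt_d: nn.Adam | None = None,
                     opt_e: nn.Adam | None = None) -> tuple[float, float]:
    """One adversarial regularization update.

    The discriminator is trained to score (encoder latent, true one-hot
    label) as one class and (standard-normal prior draw, random one-hot)
    as the other; the encoder is then updated to push its latents across
    the boundary.  At the equilibrium of this game the aggregate latent
    posterior matches the prior.  Returns (discriminator loss, generator
    loss).  ``batch_x`` is NCHW.
    """
    if model.discriminator is None:
        raise RuntimeError("model has no discriminator; adversarial step undefined")
    cfg = model.config
    if opt_d is None:
        opt_d = nn.Adam(model.discriminator.params(), lr=cfg.lr_discriminator)
    if opt_e is None:
        opt_e = nn.Adam(model.encoder_params(), lr=cfg.lr_adversarial)
    n = batch_x.shape[0]
    onehot_true = _onehot(batch_labels, cfg.n_categories)

    # discriminator update
    latent = model.encode(batch_x, train=True)
    z_prior = rng.standard_normal((n, cfg.latent_dim)).astype(nn.DTYPE)
    onehot_fake = draw_fake_codes(n, cfg.n_categories, rng)
    opt_d.zero_grad()
    logits_real = model.discriminate(latent, onehot_true, train=True)
    loss_real, g_real = nn.bce_with_logits(logits_real, np.ones_like(logits_real))
    model.discriminator.backward(g_real)
    logits_fake = model.discriminate(z_prior, onehot_fake, train=True)
    loss_fake, g_fake = nn.bce_with_logits(logits_fake, np.zeros_like(logits_fake))
    model.discriminator.backward(g_fake)
    opt_d.step()
    d_loss = loss_real + loss_fake

    # encoder (generator side) update: push latents toward the prior class
    opt_e.zero_grad()
    latent = model.encode(batch_x, train=True)
    logits = model.discriminate(latent, onehot_true, train=True)
    g_loss, g_logits = nn.bce_with_logits(logits, np.zeros_like(logits))
    for p in model.discriminator.params():
        p.zero_grad()  # discriminator only relays the gradient here
    grad_input = model.discriminator.backward(g_logits)
    model.backward_encoder(grad_input[:, :cfg.latent_dim])
    opt_e.step()
    return float(d_loss), float(g_loss)


def train(model: AAEModel, data: ImageSet, config: AAEConfig | None = None
          ) -> TrainingTrace:
    """Alternate reconstruction and adversarial updates each epoch.

    With ``epochs=0`` the trace is empty and weights stay at
    initialization.  Raises on non-finite loss.
    """
    config = config or model.config
    if len(data) == 0:
        raise ValueError("training data is empty")
    x_all = images_to_nchw(data.images)
    labels = data.labels
    rng = np.random.default_rng(config.seed + 1)
    opt_g = nn.Adam(model.generator_params(), lr=config.lr_generator)
    adversarial = model.discriminator is not None
    if adversarial:
        opt_d = nn.Adam(model.discriminator.params(), lr=config.lr_discriminator)
        opt_e = nn.Adam(model.encoder_params(), lr=config.lr_adversarial)
    trace = TrainingTrace(config=config)
    n = len(data)
    for _epoch in range(config.epochs):
        # linear lr decay settles the adversarial game near its equilibrium
        frac = _epoch / max(1, config.epochs - 1)
        decay = 1.0 - (1.0 - config.lr_decay) * frac
        opt_g.lr = config.lr_generator * decay
        if adversarial:
            opt_d.lr = config.lr_discriminator * decay
            opt_e.lr = config.lr_adversarial * decay
        order = rng.permutation(n)
        ep_rec, ep_d, ep_g, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, lb = x_all[idx], labels[idx]
            if config.augment_shift_px:
                s = config.augment_shift_px
                xb = np.roll(xb, rng.integers(-s, s + 1, size=2), axis=(2, 3))
            # reconstruction phase (pixel MSE)
            opt_g.zero_grad()
            recon, _ = model.forward_generator(xb, train=True)
            diff = recon - xb
            rec_loss = float(np.mean(diff**2))
            model.backward_generator(2.0 * diff / diff.size)
            opt_g.step()
            if not np.isfinite(rec_loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {_epoch}")
            ep_rec += rec_loss
            # adversarial regularization phase
            if adversarial:
                d_l, g_l = adversarial_step(model, xb, lb, rng, opt_d, opt_e)
                if not (np.isfinite(d_l) and np.isfinite(g_l)):
                    raise FloatingPointError(
                        f"non-finite adversarial loss at epoch {_epoch}")
                ep_d += d_l
                ep_g += g_l
            n_batches += 1
        trace.reconstruction_loss.append(ep_rec / n_batches)
        if adversarial:
            trace.discriminator_loss.append(ep_d / n_batches)
            trace.generator_loss.append(ep_g / n_batches)
    return trace


def extract_activations(model: AAEModel, images: ImageSet | np.ndarray,
                        layers: list[str] | None = None) -> LayerActivations:
    """Per-layer condition x feature matrices, evaluation mode.

    Batch-norm layers use running statistics, so each image's activation
    row is independent of the rest of the batch and extraction is
    deterministic.
    """
    layers = list(layers) if layers is not None else list(LAYER_IDS)
    unknown = set(layers) - set(LAYER_IDS)
    if unknown:
        raise ValueError(f"unknown layer ids: {sorted(unknown)}")
    imgs = images.images if isinstance(images, ImageSet) else images
    x = images_to_nchw(imgs)
    _, acts = model.forward_generator(x, train=False)
    out = {lid: acts[lid].reshape(x.shape[0], -1).copy() for lid in layers}
    return LayerActivations(data=out)


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: AAEModel, path) -> None:
    """Single-file HDF5 checkpoint with the config embedded."""
    import h5py

    cfg = asdict(model.config)
    cfg["channels_per_block"] = list(cfg["channels_per_block"])
    with h5py.File(path, "w") as fh:
        fh.attrs["config"] = json.dumps(cfg)
        fh.attrs["with_discriminator"] = model.discriminator is not None
        for name in LAYER_IDS:
            grp = fh.create_group(name)
            _dump_seq(grp, model.blocks[name])
        if model.discriminator is not None:
            _dump_seq(fh.create_group("discriminator"), model.discriminator)


def _dump_seq(grp, seq: nn.Sequential) -> None:
    for i, layer in enumerate(seq.layers):
        for j, p in enumerate(layer.params()):
            grp.create_dataset(f"{i}/{j}", data=p.value)
        if isinstance(layer, nn._BatchNormBase):
            grp.create_dataset(f"{i}/running_mean", data=layer.running_mean)
            grp.create_dataset(f"{i}/running_var", data=layer.running_var)


def _load_seq(grp, seq: nn.Sequential) -> None:
    for i, layer in enumerate(seq.layers):
        for j, p in enumerate(layer.params()):
            p.value[...] = grp[f"{i}/{j}"][...]
        if isinstance(layer, nn._BatchNormBase):
            layer.running_mean[...] = grp[f"{i}/running_mean"][...]
            layer.running_var[...] = grp[f"{i}/running_var"][...]


def load_model(path) -> AAEModel:
    import h5py

    with h5py.File(path, "r") as fh:
        cfg = json.loads(fh.attrs["config"])
        cfg["channels_per_block"] = tuple(cfg["channels_per_block"])
        model = AAEModel(AAEConfig(**cfg),
                         with_discriminator=bool(fh.attrs["with_discriminator"]))
        for name in LAYER_IDS:
            _load_seq(fh[name], model.blocks[name])
        if model.discriminator is not None:
            _load_seq(fh["discriminator"], model.discriminator)
    return model
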