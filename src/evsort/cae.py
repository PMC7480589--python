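"""Channel-wise convolutional autoencoder (CAE) and its 256-d features.

Each of the two input channels (brightfield, fluorescence) is encoded by its
own convolutional encoder into a 4x4x8 bottleneck tensor; the two bottlenecks
are concatenated (4x4x16) and a single decoder reconstructs the 2-channel
32x32 image. After unsupervised training the decoder is discarded: the
flattened concatenated bottleneck — 128 brightfield values followed by 128
fluorescence values — is the cell's 256-dimensional feature vector.

Every convolution is 3x3 and is followed by batch normalisation and ReLU,
except the final convolution, which has 2 output channels, a linear
activation and no batch normalisation. Default widths put the model at
~225k trainable parameters. Training minimises reconstruction MSE (MAE
optional) with Adam at batch size 64 on a seeded 90/10 train/validation
split, keeping the checkpoint with the best validation loss.

Pixel intensities enter as-is up to division by the fixed 16-bit full-scale
constant (65535); the first batch-normalisation layer makes the extracted
features exactly invariant to that constant, which exists purely to keep the
reconstruction loss well-conditioned for Adam.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .io import CellImage, DatasetManifest

__all__ = [
    "CAEConfig",
    "CAEWeights",
    "TrainHistory",
    "ChannelWiseCAE",
    "build_cae",
    "train_cae",
    "extract_features",
    "reconstruct",
    "count_parameters",
    "feature_channel_map",
]

FULL_SCALE = 65535.0
FEATURE_DIM = 256
BOTTLENECK_CHANNELS = 8  # per channel: 4 x 4 x 8 = 128 values


@dataclass
class CAEConfig:
    """Architecture and training hyperparameters.

    ``encoder_widths`` are the three per-channel encoder stage widths (each
    stage is conv-BN-ReLU-maxpool, halving 32->16->8->4); the last width must
    be 8 so the per-channel bottleneck is 4x4x8. ``decoder_widths`` are the
    five intermediate decoder stages: three at 4x4 resolution, then one after
    each of the first two 2x upsamplings; a final linear 3x3 convolution to
    2 channels follows the last upsampling.
    """

    encoder_widths: tuple = (16, 32, 8)
    decoder_widths: tuple = (128, 128, 32, 8, 8)
    loss: str = "mse"  # or "mae"
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 300
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class TrainHistory:
    train_loss: list
    val_loss: list
    best_epoch: int  # 0-based index of the checkpointed epoch


class ChannelWiseCAE:
    """Two independent single-channel encoders + one joint decoder."""

    def __init__(self, config: CAEConfig | None = None):
        self.config = config or CAEConfig()
        cfg = self.config
        if len(cfg.encoder_widths) != 3 or any(w < 1 for w in cfg.encoder_widths):
            raise ValueError(
                "encoder_widths must be three positive stage widths "
                f"(got {cfg.encoder_widths})")
        if cfg.encoder_widths[-1] != BOTTLENECK_CHANNELS:
            raise ValueError(
                "last encoder width must be 8 to produce the 4x4x8 "
                f"per-channel bottleneck (got {cfg.encoder_widths[-1]})")
        if len(cfg.decoder_widths) != 5 or any(w < 1 for w in cfg.decoder_widths):
            raise ValueError(
                f"decoder_widths must be five positive widths (got "
                f"{cfg.decoder_widths})")
        rng = np.random.default_rng(cfg.seed)
        self.enc0 = self._make_encoder(rng)
        self.enc1 = self._make_encoder(rng)
        self.dec = self._make_decoder(rng)

    def _make_encoder(self, rng) -> nn.Sequential:
        layers: list[nn.Layer] = []
        c_in = 1
        for w in self.config.encoder_widths:
            layers += [nn.Conv3x3(c_in, w, rng, input_grad=bool(layers)),
                       nn.BatchNorm2d(w), nn.ReLU(), nn.MaxPool2()]
            c_in = w
        return nn.Sequential(layers)

    def _make_decoder(self, rng) -> nn.Sequential:
        w = self.config.decoder_widths
        c_bot = 2 * BOTTLENECK_CHANNELS

        def block(ci, co):
            return [nn.Conv3x3(ci, co, rng), nn.BatchNorm2d(co), nn.ReLU()]

        layers = (block(c_bot, w[0]) + block(w[0], w[1]) + block(w[1], w[2])
                  + [nn.Upsample2()] + block(w[2], w[3])
                  + [nn.Upsample2()] + block(w[3], w[4])
                  + [nn.Upsample2(), nn.Conv3x3(w[4], 2, rng)])  # linear, no BN
        return nn.Sequential(layers)

    # -- computation (arrays are NHWC: (n, 32, 32, 2) scaled floats) ----

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(n, 32, 32, 2) scaled floats -> (n, 256) features (BF half first)."""
        z0 = self.enc0.forward(x[..., 0:1], train)
        z1 = self.enc1.forward(x[..., 1:2], train)
        n = x.shape[0]
        return np.concatenate([z0.reshape(n, -1), z1.reshape(n, -1)], axis=1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z0 = self.enc0.forward(x[..., 0:1], train)
        z1 = self.enc1.forward(x[..., 1:2], train)
        return self.dec.forward(np.concatenate([z0, z1], axis=3), train)

    def backward(self, grad_y: np.ndarray) -> None:
        dz = self.dec.backward(grad_y)
        self.enc0.backward(dz[..., :BOTTLENECK_CHANNELS])
        self.enc1.backward(dz[..., BOTTLENECK_CHANNELS:])

    def params(self) -> list[nn.Param]:
        return self.enc0.params() + self.enc1.params() + self.dec.params()

    # -- state ----------------------------------------------------------

    def _modules(self):
        return (("enc0", self.enc0), ("enc1", self.enc1), ("dec", self.dec))

    def state_dict(self) -> dict:
        state = {}
        for name, seq in self._modules():
            for i, lay in enumerate(seq.layers):
                if isinstance(lay, nn.Conv3x3):
                    state[f"{name}.{i}.w"] = lay.w.data.copy()
                    state[f"{name}.{i}.b"] = lay.b.data.copy()
                elif isinstance(lay, nn.BatchNorm2d):
                    state[f"{name}.{i}.gamma"] = lay.gamma.data.copy()
                    state[f"{name}.{i}.beta"] = lay.beta.data.copy()
                    state[f"{name}.{i}.running_mean"] = lay.running_mean.copy()
                    state[f"{name}.{i}.running_var"] = lay.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, seq in self._modules():
            for i, lay in enumerate(seq.layers):
                if isinstance(lay, nn.Conv3x3):
                    lay.w.data = state[f"{name}.{i}.w"].copy()
                    lay.b.data = state[f"{name}.{i}.b"].copy()
                elif isinstance(lay, nn.BatchNorm2d):
                    lay.gamma.data = state[f"{name}.{i}.gamma"].copy()
                    lay.beta.data = state[f"{name}.{i}.beta"].copy()
                    lay.running_mean = state[f"{name}.{i}.running_mean"].copy()
                    lay.running_var = state[f"{name}.{i}.running_var"].copy()


@dataclass
class CAEWeights:
    """Serialised CAE parameters plus the config they belong to."""

    state: dict
    config: CAEConfig
    train_seed: int = 0

    @property
    def config_hash(self) -> str:
        return self.config.hash()

    def save(self, path) -> Path:
        path = Path(path)
        meta = json.dumps({"config": asdict(self.config),
                           "train_seed": self.train_seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state)
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz")

    @classmethod
    def load(cls, path) -> "CAEWeights":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = meta["config"]
        cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
        cfg["decoder_widths"] = tuple(cfg["decoder_widths"])
        return cls(state, CAEConfig(**cfg), meta["train_seed"])

    def build_model(self) -> ChannelWiseCAE:
        model = ChannelWiseCAE(self.config)
        model.load_state_dict(self.state)
        return model


def build_cae(config: CAEConfig | None = None) -> ChannelWiseCAE:
    """Construct an (untrained) channel-wise CAE from a config."""
    return ChannelWiseCAE(config)


def count_parameters(model: ChannelWiseCAE) -> int:
    """Trainable parameter count (conv weights/biases + BN scale/shift)."""
    return nn.count_params([model.enc0, model.enc1, model.dec])


def _as_pixel_array(images) -> np.ndarray:
    if isinstance(images, DatasetManifest):
        return images.load_pixel_array()
    if isinstance(images, CellImage):
        return images.pixels[None]
    if isinstance(images, (list, tuple)) and images and isinstance(
            images[0], CellImage):
        return np.stack([im.pixels for im in images])
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1:] != (2, 32, 32):
        raise ValueError(f"expected (n, 2, 32, 32) images, got {arr.shape}")
    return arr


def _scaled(images) -> np.ndarray:
    """(n, 2, 32, 32) integer pixels -> NHWC float32 scaled by full scale."""
    x = _as_pixel_array(images).astype(np.float32) / np.float32(FULL_SCALE)
    return np.ascontiguousarray(x.transpose(0, 2, 3, 1))


def _loss_and_grad(y: np.ndarray, x: np.ndarray, kind: str):
    diff = y - x
    if kind == "mse":
        return float(np.mean(diff ** 2)), (2.0 / diff.size) * diff
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def train_cae(model: ChannelWiseCAE, images,
              config: CAEConfig | None = None,
              ) -> tuple[CAEWeights, TrainHistory]:
    """Unsupervised training; returns the best-on-validation checkpoint.

    ``images`` may be a DatasetManifest, a list of CellImages or an
    (n, 2, 32, 32) array; labels are never consulted. The data are split
    90/10 by a seeded shuffle, trained with Adam at the configured batch
    size, and the epoch with the lowest validation loss is the one whose
    weights (and batch-norm running statistics) are returned.
    """
    config = config or model.config
    x = _scaled(images)
    n = x.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n_val = max(1, int(round(n * config.val_fraction)))
    if n - n_val < config.batch_size:
        raise ValueError(
            f"dataset of {n} cells is smaller than one training batch "
            f"({config.batch_size}) after the validation split")
    perm = rng.permutation(n)
    val_x, train_x = x[perm[:n_val]], x[perm[n_val:]]

    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = TrainHistory([], [], 0)
    best_val, best_state = np.inf, None
    n_train = train_x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:  # batch norm needs at least two samples
                continue
            xb = train_x[idx]
            yb = model.forward(xb, train=True)
            loss, grad = _loss_and_grad(yb, xb, config.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad.astype(np.float32, copy=False))
            opt.step()
            ep_loss += loss
            n_batches += 1
        val_loss = _eval_loss(model, val_x, config.loss, config.batch_size)
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(ep_loss / max(n_batches, 1))
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
    model.load_state_dict(best_state)
    return CAEWeights(best_state, copy.deepcopy(config), config.seed), history


def _eval_loss(model: ChannelWiseCAE, x: np.ndarray, kind: str,
               batch: int) -> float:
    total, count = 0.0, 0
    for start in range(0, x.shape[0], batch):
        xb = x[start:start + batch]
        yb = model.forward(xb, train=False)
        loss, _ = _loss_and_grad(yb, xb, kind)
        total += loss * xb.shape[0]
        count += xb.shape[0]
    return total / count


def _as_model(weights_or_model) -> ChannelWiseCAE:
    if isinstance(weights_or_model, ChannelWiseCAE):
        return weights_or_model
    if isinstance(weights_or_model, CAEWeights):
        return weights_or_model.build_model()
    raise TypeError("expected a ChannelWiseCAE or CAEWeights")


def extract_features(weights_or_model, images, batch: int = 512) -> np.ndarray:
    """Encode images into (n, 256) feature vectors.

    Pure function of (weights, image): runs the encoders only, in eval mode
    (batch-norm running statistics), never the decoder. Columns 0-127 belong
    to the brightfield encoder, 128-255 to the fluorescence encoder.
    """
    model = _as_model(weights_or_model)
    x = _scaled(images)
    out = np.empty((x.shape[0], FEATURE_DIM), dtype=np.float32)
    for start in range(0, x.shape[0], batch):
        out[start:start + batch] = model.encode(x[start:start + batch],
                                                train=False)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite feature values")
    return out


def reconstruct(weights_or_model, image) -> np.ndarray:
    """Decode back to image space; real-valued, in intensity units.

    The final activation is linear, so values may fall outside [0, 65535];
    clamp only for display.
    """
    model = _as_model(weights_or_model)
    x = _scaled(image)
    y = model.forward(x, train=False).transpose(0, 3, 1, 2) * FULL_SCALE
    single = isinstance(image, CellImage) or (
        not isinstance(image, (DatasetManifest, list, tuple))
        and np.asarray(image).ndim == 3)
    return y[0] if single else y


def feature_channel_map() -> np.ndarray:
    """Channel ownership of each CAE feature coordinate (for importance)."""
    return np.array(["brightfield"] * 128 + ["fluorescence"] * 128)
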