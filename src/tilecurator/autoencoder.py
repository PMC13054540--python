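"""The tissue-tile convolutional autoencoder and its SSIM-loss training loop.

The encoder is six convolutional layers (batch normalization + LeakyReLU
after each), five of them stride-2, taking a 256x256x3 tile to an 8x8x512
feature map — a 32,768-dimensional latent when flattened. The decoder
mirrors the encoder with transposed convolutions and a final sigmoid so
reconstructions live in [0, 1]. Training minimizes ``1 - mean SSIM`` between
tiles and reconstructions under the standard augmentations (rotations,
flips, affine warps, color jitter, Gaussian blur) with Adam.

The network is pure NumPy (see :mod:`tilecurator.nn`), which keeps the whole
model dependency-light and finite-difference checkable; a reduced-width
configuration (channels scaled by 1/8) is provided so CPU training runs in
minutes. The 32,768-dimensional latent contract always refers to the default
full-width configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from . import nn
from .ssim import ssim_loss, ssim_loss_and_grad

DEFAULT_CHANNELS = (32, 64, 128, 256, 512, 512)
DEFAULT_STRIDES = (2, 2, 2, 2, 2, 1)
AUGMENT_NAMES = ("rotation", "flip", "affine", "color_jitter", "gaussian_blur")


@dataclass(frozen=True)
class EncoderConfig:
    """Six-layer convolutional encoder: 256x256x3 -> 8x8x512 by default."""

    input_size: int = 256
    in_channels: int = 3
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    strides: tuple[int, ...] = DEFAULT_STRIDES
    kernel: int = 3
    negative_slope: float = 0.2

    @property
    def downsample(self) -> int:
        return int(np.prod(self.strides))

    @property
    def final_spatial(self) -> int:
        return self.input_size // self.downsample

    @property
    def final_channels(self) -> int:
        return self.channels[-1]

    @property
    def latent_dim(self) -> int:
        return self.final_spatial ** 2 * self.final_channels

    def validate(self) -> None:
        if len(self.channels) != 6 or len(self.strides) != 6:
            raise ValueError("encoder must have exactly 6 convolutional layers")
        if self.downsample != 32:
            raise ValueError(f"cumulative downsample must be 32 (256 -> 8), got {self.downsample}")
        if self.input_size % self.downsample:
            raise ValueError("input_size must be divisible by the cumulative downsample")

    def reduced(self, factor: int = 8) -> "EncoderConfig":
        """Width-reduced config for CPU-scale training; same shape contract."""
        return EncoderConfig(
            input_size=self.input_size,
            in_channels=self.in_channels,
            channels=tuple(max(1, c // factor) for c in self.channels),
            strides=self.strides,
            kernel=self.kernel,
            negative_slope=self.negative_slope,
        )


@dataclass(frozen=True)
class DecoderConfig:
    """Mirror of the encoder using transposed convolutions, sigmoid output."""

    channels: tuple[int, ...]
    strides: tuple[int, ...]
    out_channels: int = 3
    kernel: int = 3
    negative_slope: float = 0.2

    @classmethod
    def mirror(cls, enc: EncoderConfig) -> "DecoderConfig":
        return cls(channels=tuple(reversed(enc.channels)), strides=tuple(reversed(enc.strides)),
                   out_channels=enc.in_channels, kernel=enc.kernel, negative_slope=enc.negative_slope)

    def validate(self, enc: EncoderConfig) -> None:
        if self.channels != tuple(reversed(enc.channels)) or self.strides != tuple(reversed(enc.strides)):
            raise ValueError("decoder must mirror the encoder's channel/stride schedule")


@dataclass
class TrainState:
    epochs: int
    loss_history: list[float]
    learning_rate: float
    batch_size: int
    seed: int

    def validate(self) -> None:
        if len(self.loss_history) != self.epochs:
            raise ValueError("loss history length must equal completed epochs")
        if any(l < 0 for l in self.loss_history):
            raise ValueError("SSIM losses are nonnegative")


class Autoencoder:
    """Encoder/decoder pair with seeded initialization and npz checkpoints."""

    def __init__(self, enc: EncoderConfig, dec: DecoderConfig | None = None, seed: int = 0):
        enc.validate()
        dec = dec or DecoderConfig.mirror(enc)
        dec.validate(enc)
        self.enc_config, self.dec_config, self.seed = enc, dec, seed
        rng = np.random.default_rng(seed)

        layers: list[nn.Layer] = []
        cin = enc.in_channels
        for cout, s in zip(enc.channels, enc.strides):
            layers += [nn.Conv2d(cin, cout, enc.kernel, stride=s, padding=enc.kernel // 2, rng=rng),
                       nn.BatchNorm2d(cout), nn.LeakyReLU(enc.negative_slope)]
            cin = cout
        self.encoder = nn.Sequential(layers)

        layers = []
        chans = list(dec.channels[1:]) + [dec.out_channels]
        cin = dec.channels[0]
        for i, (cout, s) in enumerate(zip(chans, dec.strides)):
            last = i == len(chans) - 1
            layers.append(nn.ConvTranspose2d(cin, cout, dec.kernel, stride=s, padding=dec.kernel // 2,
                                             output_padding=s - 1, rng=rng))
            if last:
                layers.append(nn.Sigmoid())
            else:
                layers += [nn.BatchNorm2d(cout), nn.LeakyReLU(dec.negative_slope)]
            cin = cout
        self.decoder = nn.Sequential(layers)

    # -- inference -------------------------------------------------------------
    def encode(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Feature maps ``(B, C, h, w)`` for a ``(B, 3, H, W)`` batch in [0, 1]."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 4 or batch.shape[1] != self.enc_config.in_channels:
            raise ValueError(f"expected (B, {self.enc_config.in_channels}, H, W), got {batch.shape}")
        if batch.shape[2] != self.enc_config.input_size or batch.shape[3] != self.enc_config.input_size:
            raise ValueError(f"expected {self.enc_config.input_size}-pixel square tiles, got {batch.shape}")
        return self.encoder.forward(batch, training=training)

    def decode(self, feature_maps: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decoder.forward(np.asarray(feature_maps, dtype=np.float32), training=training)

    def reconstruct(self, batch: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(batch))

    # -- persistence -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: one .npz weight blob plus a JSON config sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = {**self.encoder.named_params("enc."), **self.decoder.named_params("dec.")}
        np.savez(path, **state)
        sidecar = {"encoder": asdict(self.enc_config), "decoder": asdict(self.dec_config), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        for cfg in (sidecar["encoder"], sidecar["decoder"]):
            for k, v in cfg.items():
                if isinstance(v, list):
                    cfg[k] = tuple(v)
        model = cls(EncoderConfig(**sidecar["encoder"]), DecoderConfig(**sidecar["decoder"]), seed=sidecar["seed"])
        with np.load(path) as state:
            model.encoder.load_named_params(dict(state), "enc.")
            model.decoder.load_named_params(dict(state), "dec.")
        return model


def build_autoencoder(enc: EncoderConfig | None = None, dec: DecoderConfig | None = None,
                      seed: int = 0) -> Autoencoder:
    return Autoencoder(enc or EncoderConfig(), dec, seed=seed)


# -- augmentation ---------------------------------------------------------------

def augment(tile: np.ndarray, rng: np.random.Generator | int, p: float = 0.5,
            apply: set[str] | None = None) -> np.ndarray:
    """Seeded random subset of rotation / flip / affine / color jitter / blur.

    ``tile`` is (H, W, 3) in [0, 1]. Each transform fires independently with
    probability ``p`` unless ``apply`` names an explicit subset (used by
    tests to pin down a single transform). The identity draw — no transform
    selected — returns the input unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    tile = np.asarray(tile, dtype=np.float32)
    out = tile

    def on(name: str) -> bool:
        if apply is not None:
            return name in apply
        return bool(rng.random() < p)

    if on("rotation"):
        out = np.rot90(out, k=int(rng.integers(1, 4)), axes=(0, 1))
    if apply is not None and "hflip" in apply:
        out = out[:, ::-1]
    elif apply is not None and "vflip" in apply:
        out = out[::-1, :]
    elif on("flip"):
        if rng.random() < 0.5:
            out = out[:, ::-1]
        else:
            out = out[::-1, :]
    if on("affine"):
        tf = AffineTransform(
            scale=rng.uniform(0.9, 1.1),
            rotation=np.deg2rad(rng.uniform(-15, 15)),
            translation=rng.uniform(-8, 8, size=2),
        )
        out = warp(out, tf.inverse, mode="reflect", preserve_range=True).astype(np.float32)
    if on("color_jitter"):
        gains = rng.uniform(0.8, 1.2, size=3).astype(np.float32)
        offsets = rng.uniform(-0.1, 0.1, size=3).astype(np.float32)
        out = np.clip(out * gains[None, None, :] + offsets[None, None, :], 0.0, 1.0)
    if on("gaussian_blur"):
        sigma = rng.uniform(0.3, 1.5)
        out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0)).astype(np.float32)
    return np.ascontiguousarray(out, dtype=np.float32)


def tiles_to_batch(tiles: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8/float tiles -> (N, 3, H, W) float32 in [0, 1]."""
    tiles = np.asarray(tiles)
    if tiles.dtype == np.uint8:
        tiles = tiles.astype(np.float32) / 255.0
    return np.ascontiguousarray(np.moveaxis(tiles.astype(np.float32), -1, 1))


def train_autoencoder(
    tiles: np.ndarray,
    enc: EncoderConfig | None = None,
    dec: DecoderConfig | None = None,
    epochs: int = 5,
    batch_size: int = 8,
    learning_rate: float = 1e-4,
    seed: int = 0,
    augment_prob: float = 0.5,
) -> tuple[Autoencoder, TrainState]:
    """Train on ``(N, H, W, 3)`` tiles with SSIM loss; returns the loss history.

    Each epoch shuffles the tiles, augments every tile with a fresh seeded
    draw, and takes one Adam step per mini-batch on ``1 - mean SSIM``. With
    ``epochs=0`` the returned model is exactly the seeded initialization.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4 or tiles.shape[0] < 1:
        raise ValueError("need at least one (H, W, 3) tile")
    if epochs < 0 or batch_size < 1 or learning_rate <= 0:
        raise ValueError("hyperparameters must be positive")

    model = build_autoencoder(enc, dec, seed=seed)
    optim = nn.Adam([model.encoder, model.decoder], lr=learning_rate)
    rng = np.random.default_rng(seed)
    n = tiles.shape[0]
    history: list[float] = []

    norm = tiles.astype(np.float32) / 255.0 if tiles.dtype == np.uint8 else tiles.astype(np.float32)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch_imgs = np.stack([augment(norm[i], rng, p=augment_prob) for i in idx])
            batch = np.moveaxis(batch_imgs, -1, 1)
            feats = model.encode(batch, training=True)
            recon = model.decode(feats, training=True)
            loss, grad = ssim_loss_and_grad(batch, recon)
            model.encoder.zero_grad()
            model.decoder.zero_grad()
            model.encoder.backward(model.decoder.backward(grad))
            optim.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))

    state = TrainState(epochs=epochs, loss_history=history, learning_rate=learning_rate,
                       batch_size=batch_size, seed=seed)
    state.validate()
    return model, state


def reconstruction_ssim(model: Autoencoder, tiles: np.ndarray, batch_size: int = 8) -> float:
    """Mean SSIM between tiles and their reconstructions (inference mode)."""
    batch = tiles_to_batch(tiles)
    vals = []
    for start in range(0, batch.shape[0], batch_size):
        chunk = batch[start : start + batch_size]
        vals.append((1.0 - ssim_loss(chunk, model.reconstruct(chunk))) * chunk.shape[0])
    return float(np.sum(vals) / batch.shape[0])


def save_training_curve(state: TrainState, path: str | Path) -> None:
    path = Path(path)
    lines = ["epoch,mean_loss"] + [f"{i + 1},{l:.8f}" for i, l in enumerate(state.loss_history)]
    path.write_text("\n".join(lines) + "\n")
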