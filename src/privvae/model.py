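"""The per-frame variational autoencoder.

Architecture
------------
Encoder: ``n_blocks`` (default 5) dense convolutional blocks.  Each block
applies a same-padded convolution (kernel 5) + batch normalization + leaky
ReLU, concatenates the block input to that sub-block output (the dense skip
connection), and downsamples by a stride-2 convolution.  Every block halves
the spatial resolution and doubles the feature depth, starting from
``initial_filters`` (default 8).  The final feature map is globally
average-pooled and two affine heads predict the mean and log-variance of a
diagonal Normal over the ``code_length``-dimensional latent space.

Sampling: the reparameterization trick, ``code = mean + exp(log_var/2) * eps``
with standard-normal ``eps``; at inference the deterministic mean is used.

Decoder: an affine map expands the code back to the coarsest feature map,
then ``n_blocks`` upsampling blocks mirror the encoder: each combines a
parameter-free skip connection (nearest-neighbour 2x upsampling with
grouped channel averaging) with a stride-2 transposed convolution, doubling
resolution and halving feature depth; the last block maps to the image
channels through a sigmoid so outputs live in [0, 1].

The model is per-frame by construction: no information flows between frames
of a video, so an encoded video is simply the ordered sequence of per-frame
codes (`CodeSequence`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cosine as _scipy_cosine

from .autodiff import Tensor, concat, upsample_nearest2x
from .nn import DTYPE, BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module

FORMAT_VERSION = 1


class FingerprintMismatchError(RuntimeError):
    """Raised when codes are presented to a decoder they were not made by."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the published configuration: 256x256 RGB-D input, 5 blocks,
    8 initial filters, code length 256, kernel size 5.  Use
    ``ModelConfig.desk()`` for the 64x64 configuration used in tests and
    examples.
    """

    input_resolution: int = 256
    input_channels: int = 4
    n_blocks: int = 5
    initial_filters: int = 8
    code_length: int = 256
    kernel_size: int = 5

    def __post_init__(self):
        for name in ("input_resolution", "n_blocks", "initial_filters",
                     "code_length", "kernel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.input_channels not in (3, 4):
            raise ValueError("input_channels must be 3 (RGB) or 4 (RGB-D)")
        if self.input_resolution % (2**self.n_blocks) != 0:
            raise ValueError(
                f"input_resolution {self.input_resolution} must be divisible "
                f"by 2^n_blocks = {2**self.n_blocks}"
            )

    @classmethod
    def desk(cls, channels: int = 4, code_length: int = 256) -> "ModelConfig":
        """Small 64x64 configuration for CPU-scale experiments."""
        return cls(input_resolution=64, input_channels=channels,
                   code_length=code_length)

    def filters_at(self, block_index: int) -> int:
        return self.initial_filters * 2 ** (block_index - 1)


def block_output_shape(config: ModelConfig, block_index: int) -> tuple[int, int, int]:
    """(height, width, feature_depth) after encoder block `block_index` (1-based).

    Each block halves the resolution and doubles the feature depth.
    """
    if not 1 <= block_index <= config.n_blocks:
        raise ValueError(
            f"block_index must be in 1..{config.n_blocks}, got {block_index}"
        )
    hw = config.input_resolution // 2**block_index
    return hw, hw, config.filters_at(block_index)


@dataclass(frozen=True)
class LatentDistribution:
    """Per-frame predicted diagonal Normal over the latent space."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(
            self, "log_variance", np.asarray(self.log_variance, dtype=np.float64)
        )
        if self.mean.shape != self.log_variance.shape or self.mean.ndim != 1:
            raise ValueError("mean and log_variance must be 1-D and equal length")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.log_variance).all()):
            raise ValueError("latent distribution must be finite")


@dataclass(frozen=True)
class LatentCode:
    """A sampled fixed-length code — the privacy-preserving representation."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 1:
            raise ValueError("code must be a 1-D vector")
        if not np.isfinite(self.values).all():
            raise ValueError("code must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CodeSequence:
    """Ordered per-frame codes of one video plus provenance header."""

    codes: np.ndarray  # (n_frames, code_length) float32
    header: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float32)
        if self.codes.ndim != 2:
            raise ValueError("codes must be (n_frames, code_length)")
        defaults = {
            "format_version": FORMAT_VERSION,
            "code_length": self.codes.shape[1],
            "n_frames": self.codes.shape[0],
        }
        self.header = {**defaults, **self.header}
        if self.header["n_frames"] != self.codes.shape[0]:
            raise ValueError("header n_frames does not match payload")
        if self.header["code_length"] != self.codes.shape[1]:
            raise ValueError("header code_length does not match payload")

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __iter__(self):
        for row in self.codes:
            yield LatentCode(row)


class _EncoderBlock(Module):
    def __init__(self, c_in: int, f_out: int, kernel: int, rng):
        self.conv = Conv2d(c_in, f_out, kernel, stride=1,
                           padding=(kernel - 1) // 2, rng=rng)
        self.bn1 = BatchNorm2d(f_out)
        self.down = Conv2d(c_in + f_out, f_out, 2, stride=2, padding=0, rng=rng)
        self.bn2 = BatchNorm2d(f_out)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        h = self.bn1(self.conv(x), train).leaky_relu()
        dense = concat([x, h], axis=1)  # skip between block input and output
        return self.bn2(self.down(dense), train).leaky_relu()


def _group_mean_channels(x: Tensor, c_out: int) -> Tensor:
    """Reduce channel count by averaging contiguous channel groups."""
    N, C, H, W = x.shape
    if C % c_out == 0:
        return x.reshape(N, c_out, C // c_out, H, W).mean(axis=2)
    bounds = np.linspace(0, C, c_out + 1).round().astype(int)
    parts = [
        x.slice_axis(1, int(lo), int(hi)).mean(axis=1, keepdims=True)
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    return concat(parts, axis=1)


class _DecoderBlock(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng, final: bool):
        self.c_out = c_out
        self.final = final
        self.convt = ConvTranspose2d(c_in, c_out, kernel, rng=rng)
        self.bn = None if final else BatchNorm2d(c_out)

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        skip = _group_mean_channels(upsample_nearest2x(x), self.c_out)
        y = self.convt(x) + skip
        if self.final:
            return y.sigmoid()
        return self.bn(y, train).leaky_relu()


class VideoAutoencoder(Module):
    """Per-frame VAE; weights are a deterministic function of (config, seed)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.enc_blocks = []
        c_in = c.input_channels
        for i in range(1, c.n_blocks + 1):
            f = c.filters_at(i)
            self.enc_blocks.append(_EncoderBlock(c_in, f, c.kernel_size, rng))
            c_in = f
        self._bottom_hw = c.input_resolution // 2**c.n_blocks
        f_top = c.filters_at(c.n_blocks)
        self.fc_mean = Linear(f_top, c.code_length, rng)
        self.fc_log_var = Linear(f_top, c.code_length, rng)
        self.fc_decode = Linear(c.code_length, f_top * self._bottom_hw**2, rng)
        self.dec_blocks = []
        for j in range(1, c.n_blocks + 1):
            cin = c.filters_at(c.n_blocks - j + 1)
            final = j == c.n_blocks
            cout = c.input_channels if final else c.filters_at(c.n_blocks - j)
            self.dec_blocks.append(_DecoderBlock(cin, cout, c.kernel_size, rng, final))

    # -- batched Tensor paths (training & inference share these) -------------
    def encode_batch(self, x: Tensor, train: bool = False) -> tuple[Tensor, Tensor]:
        h = x
        for block in self.enc_blocks:
            h = block(h, train)
        pooled = h.mean(axis=(2, 3))  # global average pool of the top map
        return self.fc_mean(pooled), self.fc_log_var(pooled)

    def encoder_activations(self, x: Tensor) -> list[Tensor]:
        """Per-block activations (for shape introspection)."""
        acts = []
        h = x
        for block in self.enc_blocks:
            h = block(h)
            acts.append(h)
        return acts

    def decode_batch(self, z: Tensor, train: bool = False) -> Tensor:
        n = z.shape[0]
        f_top = self.config.filters_at(self.config.n_blocks)
        h = self.fc_decode(z).leaky_relu().reshape(
            n, f_top, self._bottom_hw, self._bottom_hw
        )
        for block in self.dec_blocks:
            h = block(h, train)
        return h

    def decoder_activations(self, z: Tensor) -> list[Tensor]:
        acts = []
        f_top = self.config.filters_at(self.config.n_blocks)
        h = self.fc_decode(z).leaky_relu().reshape(
            z.shape[0], f_top, self._bottom_hw, self._bottom_hw
        )
        for block in self.dec_blocks:
            h = block(h)
            acts.append(h)
        return acts

    # -- provenance ----------------------------------------------------------
    def fingerprint(self) -> str:
        """Short hash of architecture + weights; stamped into CodeSequences."""
        h = hashlib.sha256()
        h.update(json.dumps(vars(self.config) | {}, sort_keys=True,
                            default=int).encode())
        for name in sorted(self.parameters()):
            h.update(np.ascontiguousarray(self.parameters()[name].data).tobytes())
        for name in sorted(self.buffers()):
            h.update(np.ascontiguousarray(self.buffers()[name]).tobytes())
        return h.hexdigest()[:16]


def _check_frame(frame: np.ndarray, config: ModelConfig) -> np.ndarray:
    frame = np.asarray(frame, dtype=DTYPE)
    expected = (config.input_resolution, config.input_resolution,
                config.input_channels)
    if frame.shape != expected:
        raise ValueError(f"frame shape mismatch: expected {expected}, "
                         f"got {frame.shape}")
    return frame


def encode_frame(frame: np.ndarray, model: VideoAutoencoder) -> LatentDistribution:
    """Encode one (H, W, C) frame to its latent Normal (inference mode)."""
    frame = _check_frame(frame, model.config)
    x = Tensor(frame.transpose(2, 0, 1)[None])
    mean, log_var = model.encode_batch(x, train=False)
    return LatentDistribution(mean.data[0], log_var.data[0])


def sample_code(
    dist: LatentDistribution,
    seed: int | None = None,
    deterministic: bool = False,
) -> LatentCode:
    """Reparameterized sample; with `deterministic`, the mean itself."""
    if deterministic:
        return LatentCode(dist.mean.copy())
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(dist.mean.size)
    return LatentCode(dist.mean + np.exp(0.5 * dist.log_variance) * eps)


def decode_code(code: LatentCode | np.ndarray, model: VideoAutoencoder) -> np.ndarray:
    """Decode a latent code back to an (H, W, C) frame in [0, 1]."""
    values = code.values if isinstance(code, LatentCode) else np.asarray(code)
    if values.size != model.config.code_length:
        raise ValueError(
            f"code length mismatch: expected {model.config.code_length}, "
            f"got {values.size}"
        )
    z = Tensor(values.reshape(1, -1).astype(DTYPE))
    out = model.decode_batch(z, train=False)
    return out.data[0].transpose(1, 2, 0).astype(DTYPE)


def encode_video(
    frames: np.ndarray,
    model: VideoAutoencoder,
    mode: str = "deterministic",
    seed: int | None = None,
    batch_size: int = 16,
) -> CodeSequence:
    """Encode a stack of frames (n, H, W, C) into a CodeSequence.

    Encoding is strictly per-frame (no temporal context), so permuting the
    input frames permutes the codes identically.
    """
    frames = np.asarray(frames, dtype=DTYPE)
    if frames.ndim != 4 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (n, H, W, C) stack")
    for f in frames[:1]:
        _check_frame(f, model.config)
    if mode not in ("deterministic", "sample"):
        raise ValueError("mode must be 'deterministic' or 'sample'")
    rng = np.random.default_rng(seed)
    rows = []
    for lo in range(0, frames.shape[0], batch_size):
        batch = frames[lo : lo + batch_size].transpose(0, 3, 1, 2)
        mean, log_var = model.encode_batch(Tensor(batch), train=False)
        if mode == "deterministic":
            rows.append(mean.data)
        else:
            eps = rng.standard_normal(mean.shape)
            rows.append(mean.data + np.exp(0.5 * log_var.data) * eps)
    codes = np.concatenate(rows, axis=0)
    header = {
        "format_version": FORMAT_VERSION,
        "code_length": model.config.code_length,
        "n_frames": frames.shape[0],
        "source_resolution": model.config.input_resolution,
        "model_fingerprint": model.fingerprint(),
    }
    return CodeSequence(codes, header)


def decode_video(
    codes: CodeSequence, model: VideoAutoencoder, batch_size: int = 16
) -> np.ndarray:
    """Decode a CodeSequence back into frames; refuses mismatched models."""
    if len(codes) == 0:
        raise ValueError("empty code sequence")
    fp = codes.header.get("model_fingerprint")
    if fp is not None and fp != model.fingerprint():
        raise FingerprintMismatchError(
            f"codes were produced by model {fp}, decoder is {model.fingerprint()}"
        )
    if codes.header["code_length"] != model.config.code_length:
        raise ValueError("code length does not match decoder configuration")
    out = []
    for lo in range(0, len(codes), batch_size):
        z = Tensor(codes.codes[lo : lo + batch_size])
        out.append(model.decode_batch(z, train=False).data.transpose(0, 2, 3, 1))
    return np.concatenate(out, axis=0).astype(DTYPE)


def latent_cosine_distance(a, b) -> float:
    """Cosine distance 1 - cos(a, b) between two codes, in [0, 2]."""
    av = a.values if isinstance(a, LatentCode) else np.asarray(a, dtype=np.float64)
    bv = b.values if isinstance(b, LatentCode) else np.asarray(b, dtype=np.float64)
    if av.shape != bv.shape:
        raise ValueError(f"code length mismatch: {av.shape} vs {bv.shape}")
    if np.linalg.norm(av) == 0 or np.linalg.norm(bv) == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(_scipy_cosine(av, bv))


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: VideoAutoencoder, path) -> None:
    """Save weights + running stats + embedded config as a .npz archive."""
    arrays = {f"param:{k}": v.data for k, v in model.parameters().items()}
    arrays |= {f"buffer:{k}": v for k, v in model.buffers().items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(vars(model.config), default=int).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> VideoAutoencoder:
    with np.load(path) as archive:
        cfg = json.loads(bytes(archive["config_json"].tobytes()).decode())
        model = VideoAutoencoder(ModelConfig(**cfg))
        params = model.parameters()
        for key in archive.files:
            if key.startswith("param:"):
                params[key[6:]].data = archive[key].copy()
        bufs = {k[7:]: archive[k].copy() for k in archive.files
                if k.startswith("buffer:")}
        model.load_buffers(bufs)
    return model
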