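"""Reproducible CPU training of the video autoencoder.

Published hyperparameters are the defaults where stated (learning rate
0.001, kernel 5, 8 initial filters); the optimizer (Adam) and batch size
(16) are exposed choices.  Videos are split 90/10 into train/validation by
video, not by frame, so held-out frames always come from unseen videos.
One stochastic latent sample per frame is drawn during training; inference
uses the deterministic mean code.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .losses import LossConfig, kl_normal, ms_ssim, total_loss_t
from .model import (
    LatentDistribution,
    ModelConfig,
    VideoAutoencoder,
    save_checkpoint,
)
from .nn import DTYPE, Adam


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; epochs default to the desk-scale 20."""

    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 16
    seed: int = 0
    checkpoint_every: int = 0  # 0 disables periodic checkpoints
    checkpoint_dir: str | None = None
    device: str = "cpu"
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.device != "cpu":
            raise ValueError("only the cpu device is available")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        if not all(np.isfinite(v) for v in record.values() if isinstance(v, float)):
            raise ValueError(f"non-finite history record: {record}")
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FrameDataset:
    """A flat stack of frames with the video each frame came from."""

    frames: np.ndarray  # (n_frames_total, H, W, C) in [0, 1]
    video_ids: np.ndarray  # (n_frames_total,) str or int labels

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=DTYPE)
        self.video_ids = np.asarray(self.video_ids)
        if self.frames.ndim != 4 or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (n, H, W, C) stack")
        if len(self.video_ids) != len(self.frames):
            raise ValueError("one video id per frame required")

    @classmethod
    def from_videos(cls, videos) -> "FrameDataset":
        """Build from `simulate_dataset` output: a list of (frames, spec)."""
        frames = np.concatenate([f for f, _ in videos], axis=0)
        ids = np.concatenate(
            [np.repeat(spec.subject.subject_id + f"/{i}", len(f))
             for i, (f, spec) in enumerate(videos)]
        )
        return cls(frames, ids)

    def __len__(self) -> int:
        return len(self.frames)


def _split_by_video(
    dataset: FrameDataset, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    vids = np.unique(dataset.video_ids)
    rng.shuffle(vids)
    n_val = int(round(val_fraction * len(vids))) if len(vids) > 1 else 0
    val_set = set(vids[:n_val])
    mask = np.array([v in val_set for v in dataset.video_ids])
    return np.where(~mask)[0], np.where(mask)[0]


def train(
    dataset: FrameDataset,
    model_config: ModelConfig,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[VideoAutoencoder, TrainHistory]:
    """Train the VAE; deterministic given the config seed.

    Returns the trained model and a per-epoch history of the total loss,
    its MS-SSIM and KL components, and validation MS-SSIM (NaN-free; a
    non-finite loss aborts with the offending epoch and step named).
    """
    loss_config = loss_config or LossConfig()
    train_config = train_config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    expected = (model_config.input_resolution, model_config.input_resolution,
                model_config.input_channels)
    if dataset.frames.shape[1:] != expected:
        raise ValueError(
            f"dataset frames {dataset.frames.shape[1:]} do not match the "
            f"model configuration {expected}"
        )

    rng = np.random.default_rng(train_config.seed)
    model = VideoAutoencoder(model_config, seed=train_config.seed)
    params = model.parameters()
    opt = Adam(params, lr=train_config.learning_rate)
    train_idx, val_idx = _split_by_video(dataset, train_config.val_fraction, rng)
    history = TrainHistory()

    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(train_idx)
        totals, recons, kls = [], [], []
        for step, lo in enumerate(range(0, len(order), train_config.batch_size)):
            batch = dataset.frames[order[lo : lo + train_config.batch_size]]
            x = Tensor(batch.transpose(0, 3, 1, 2))
            mean, log_var = model.encode_batch(x, train=True)
            eps = Tensor(rng.standard_normal(mean.shape).astype(DTYPE))
            z = mean + (log_var * 0.5).exp() * eps  # reparameterization
            recon = model.decode_batch(z, train=True)
            loss, comps = total_loss_t(x, recon, mean, log_var, loss_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            totals.append(float(loss.data))
            recons.append(comps["reconstruction"])
            kls.append(comps["kl"])

        record = {
            "epoch": epoch,
            "loss": float(np.mean(totals)),
            "reconstruction": float(np.mean(recons)),
            "kl": float(np.mean(kls)),
        }
        if len(val_idx):
            summary = evaluate_reconstruction(model, dataset.frames[val_idx])
            record["val_ms_ssim"] = summary["mean_ms_ssim"]
        history.append(**record)

        if (
            train_config.checkpoint_dir
            and train_config.checkpoint_every
            and epoch % train_config.checkpoint_every == 0
        ):
            os.makedirs(train_config.checkpoint_dir, exist_ok=True)
            save_checkpoint(
                model,
                os.path.join(train_config.checkpoint_dir, f"epoch{epoch:04d}.npz"),
            )

    return model, history


def evaluate_reconstruction(
    model: VideoAutoencoder,
    frames: np.ndarray,
    loss_config: LossConfig | None = None,
    batch_size: int = 16,
) -> dict:
    """Deterministic reconstruction summary over a stack of frames.

    Encodes each frame to its mean code, decodes, and reports the mean
    MS-SSIM between input and reconstruction plus the mean per-frame KL.
    """
    loss_config = loss_config or LossConfig()
    frames = np.asarray(frames, dtype=DTYPE)
    if frames.ndim != 4 or len(frames) == 0:
        raise ValueError("need a non-empty (n, H, W, C) stack of frames")
    ms_vals, kl_vals = [], []
    for lo in range(0, len(frames), batch_size):
        batch = frames[lo : lo + batch_size]
        x = Tensor(batch.transpose(0, 3, 1, 2))
        mean, log_var = model.encode_batch(x, train=False)
        recon = model.decode_batch(Tensor(mean.data), train=False)
        out = recon.data.transpose(0, 2, 3, 1)
        for i in range(len(batch)):
            ms_vals.append(ms_ssim(batch[i], out[i], loss_config))
            kl_vals.append(
                kl_normal(LatentDistribution(mean.data[i], log_var.data[i]))
            )
    return {
        "mean_ms_ssim": float(np.mean(ms_vals)),
        "mean_kl": float(np.mean(kl_vals)),
        "n_frames": len(frames),
    }
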