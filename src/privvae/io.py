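"""File formats: PNG frame sequences, the codes container, ratings CSV, YAML config.

Frames travel as zero-padded PNG sequences (``frame_0001.png`` ...) with an
optional JSON sidecar holding the generating `SyntheticVideoSpec`; a
4-channel frame stores its depth map in the PNG alpha slot (documented
meaning: synthetic distance-to-camera in [0, 1], not opacity).  Because
frames are quantized to the 8-bit grid, the PNG round trip is lossless.

Encoded videos travel in a small container: magic bytes ``PVAE``, a 4-byte
little-endian header length, a JSON header (format_version, code_length,
n_frames, source_resolution, model_fingerprint), then n_frames x
code_length little-endian float32 values.  A CSV export (one row per frame)
is provided for interoperability.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .agreement import NOT_RATABLE, RatingTable
from .losses import LossConfig
from .model import FORMAT_VERSION, CodeSequence, ModelConfig
from .synthetic import SubjectIdentity, SyntheticVideoSpec, TrajectorySpec
from .training import TrainConfig

MAGIC = b"PVAE"


# -- video frames ------------------------------------------------------------

def write_video(frames: np.ndarray, directory, spec: SyntheticVideoSpec | None = None) -> None:
    """Write frames as a zero-padded PNG sequence (+ optional spec sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    if frames.ndim != 4:
        raise ValueError("expected an (n, H, W, C) frame stack")
    for i, frame in enumerate(frames):
        data = np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{i + 1:04d}.png", data)
    if spec is not None:
        (directory / "spec.json").write_text(
            json.dumps(dataclasses.asdict(spec), indent=2)
        )


def read_video(directory, expected_channels: int | None = None) -> np.ndarray:
    """Read a PNG frame sequence back to an (n, H, W, C) float stack in [0, 1]."""
    directory = Path(directory)
    files = sorted(directory.glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    frames, shapes = [], {}
    for f in files:
        arr = iio.imread(f)
        if arr.ndim == 2:
            arr = arr[..., None]
        frames.append(arr)
        shapes.setdefault(arr.shape, []).append(f.name)
    if len(shapes) > 1:
        listing = "; ".join(f"{s}: {names[:3]}" for s, names in shapes.items())
        raise ValueError(f"mixed frame shapes in {directory}: {listing}")
    stack = np.stack(frames).astype(np.float32) / 255.0
    if expected_channels is not None and stack.shape[-1] != expected_channels:
        raise ValueError(
            f"channel mismatch in {directory}: expected {expected_channels}, "
            f"found {stack.shape[-1]}"
        )
    return stack


def read_video_spec(directory) -> SyntheticVideoSpec:
    """Load the spec.json sidecar written next to a synthetic PNG sequence."""
    payload = json.loads((Path(directory) / "spec.json").read_text())
    payload["subject"] = SubjectIdentity(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["subject"].items()
        }
    )
    payload["trajectory"] = TrajectorySpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["trajectory"].items()
        }
    )
    return SyntheticVideoSpec(**payload)


# -- codes container ---------------------------------------------------------

def write_codes(seq: CodeSequence, path) -> None:
    """Write a CodeSequence to the binary container format."""
    header = json.dumps(seq.header, sort_keys=True).encode()
    payload = np.ascontiguousarray(seq.codes, dtype="<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        fh.write(payload)


def read_codes(path) -> CodeSequence:
    """Read and validate a codes container; corrupt files raise, never decode."""
    raw = Path(path).read_bytes()
    if len(raw) < 8 or raw[:4] != MAGIC:
        raise ValueError(f"{path} is not a codes container (bad magic bytes)")
    (hlen,) = struct.unpack("<I", raw[4:8])
    if len(raw) < 8 + hlen:
        raise ValueError(f"{path} is truncated inside its header")
    try:
        header = json.loads(raw[8 : 8 + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path} has a corrupt header: {exc}") from exc
    if header.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported codes format version {header.get('format_version')}"
        )
    n, L = header["n_frames"], header["code_length"]
    payload = raw[8 + hlen :]
    expected = n * L * 4
    if len(payload) != expected:
        raise ValueError(
            f"{path} payload is {len(payload)} bytes but the header promises "
            f"{expected} ({n} frames x {L} floats): truncated or corrupt"
        )
    codes = np.frombuffer(payload, dtype="<f4").reshape(n, L)
    return CodeSequence(codes.copy(), header)


def codes_to_csv(seq: CodeSequence, path) -> None:
    df = pd.DataFrame(seq.codes)
    df.insert(0, "frame", np.arange(len(seq)))
    df.to_csv(path, index=False)


def codes_from_csv(path, header: dict | None = None) -> CodeSequence:
    df = pd.read_csv(path)
    codes = df.drop(columns=["frame"]).to_numpy(dtype=np.float32)
    return CodeSequence(codes, header or {})


# -- ratings CSV -------------------------------------------------------------

def write_ratings(table: RatingTable, path) -> None:
    """Long-format CSV: video_id, rater_id, rating in {0..4, NR}."""
    table.to_long().to_csv(path, index=False)


def read_ratings(path, condition: str = "original") -> RatingTable:
    df = pd.read_csv(path, dtype={"rating": str})
    required = {"video_id", "rater_id", "rating"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    wide = df.pivot(index="video_id", columns="rater_id", values="rating")
    columns = {r: list(wide[r]) for r in wide.columns}
    return RatingTable.from_columns(columns, list(wide.index), condition=condition)


# -- run configuration -------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimulationParams:
    n_videos: int = 10
    n_frames: int = 30
    resolution: int = 64
    channels: int = 4
    seed: int = 0
    n_subjects: int | None = None


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated composition of all stage configurations."""

    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)
    paths: dict = dataclasses.field(default_factory=dict)


def _build(cls, payload: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(
            f"unknown keys in config section '{section}': {sorted(unknown)}"
        )
    for f in dataclasses.fields(cls):
        if f.name in payload and isinstance(payload[f.name], list):
            payload[f.name] = tuple(payload[f.name])
    return cls(**payload)


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "model": ModelConfig,
        "loss": LossConfig,
        "train": TrainConfig,
        "simulation": SimulationParams,
    }
    unknown = set(payload) - set(sections) - {"paths"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, dict(payload.get(name, {})), name)
        for name, cls in sections.items()
    }
    kwargs["paths"] = dict(payload.get("paths", {}))
    return RunConfig(**kwargs)


def save_run_config(config: RunConfig, path) -> None:
    payload = {
        "model": dataclasses.asdict(config.model),
        "loss": dataclasses.asdict(config.loss),
        "train": dataclasses.asdict(config.train),
        "simulation": dataclasses.asdict(config.simulation),
        "paths": dict(config.paths),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
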