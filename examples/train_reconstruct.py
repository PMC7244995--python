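"""Train a small autoencoder on synthetic videos and check reconstruction.

Uses a reduced 32x32 configuration so the run finishes in well under a
minute; the published configuration (256x256 RGB-D, code length 256) is
`ModelConfig()` and trains the same way, just longer.
"""

from privvae.losses import LossConfig
from privvae.model import ModelConfig, VideoAutoencoder
from privvae.synthetic import simulate_dataset
from privvae.training import FrameDataset, TrainConfig, evaluate_reconstruction, train

videos = simulate_dataset(6, seed=3, resolution=32, n_frames=10, n_subjects=3)
dataset = FrameDataset.from_videos(videos)
config = ModelConfig(input_resolution=32, input_channels=4, code_length=64)

model, history = train(
    dataset, config, LossConfig(),
    TrainConfig(epochs=25, batch_size=16, seed=1, val_fraction=0.2),
)

df = history.to_dataframe()
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

trained = evaluate_reconstruction(model, dataset.frames)
untrained = evaluate_reconstruction(VideoAutoencoder(config, seed=1), dataset.frames)
print(f"\nmean MS-SSIM, trained model:   {trained['mean_ms_ssim']:.3f}")
print(f"mean MS-SSIM, untrained model: {untrained['mean_ms_ssim']:.3f}")
print("\nThe loss (1 - MS-SSIM + KL/code_length) falls epoch over epoch and the")
print("trained model reconstructs frames far better than fresh random weights;")
print("MS-SSIM of 1.0 would be a pixel-structure-perfect reconstruction.")
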