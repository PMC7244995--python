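"""Training objective: multi-scale structural similarity + KL regularization.

The reconstruction term is 1 - MS-SSIM between the input frame and its
decoded reconstruction; the regularizer is the Kullback-Leibler divergence
of the per-frame latent Normal from the standard-normal prior, normalized by
code length so the two terms stay on comparable scales.

SSIM follows Wang et al.: Gaussian-weighted local statistics (window 11,
sigma 1.5), stability constants C1 = (k1 L)^2, C2 = (k2 L)^2 with L = 1 for
frames in [0, 1].  MS-SSIM multiplies contrast-structure terms across
dyadic scales, applying the luminance term only at the coarsest scale, with
the published five-scale weights; scales that the input resolution cannot
support are dropped automatically and the remaining weights renormalized.

Every operation exists in two views of one implementation: a `Tensor`
(autodiff) path used during training, and ndarray wrappers for metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d

#: Wang et al. five-scale MS-SSIM weights (coarse scale last), normalized to
#: sum exactly to 1 (the published values sum to 1.0001).
_RAW_WANG = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
WANG_WEIGHTS = tuple(float(w) for w in np.asarray(_RAW_WANG) / np.sum(_RAW_WANG))

_CS_FLOOR = 1e-6  # clamp before fractional powers; negative cs is treated as 0


@dataclass(frozen=True)
class LossConfig:
    """Configuration of the MS-SSIM + KL objective."""

    ms_ssim_scales: int = 5
    ms_ssim_scale_weights: tuple[float, ...] = WANG_WEIGHTS
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    stability_constants: tuple[float, float] = (0.01, 0.03)
    kl_weight: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.ms_ssim_scale_weights, dtype=float)
        if len(w) != self.ms_ssim_scales:
            raise ValueError(
                f"{self.ms_ssim_scales} scales need {self.ms_ssim_scales} weights, "
                f"got {len(w)}"
            )
        if (w < 0).any():
            raise ValueError("scale weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"scale weights must sum to 1, got {w.sum()!r}")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be non-negative")

    def resolve_scales(self, resolution: int) -> tuple[int, np.ndarray]:
        """Number of usable scales at `resolution` and renormalized weights.

        A scale is usable if the twice-downsampled image still contains at
        least one full SSIM window: resolution / 2^(m-1) >= window.
        """
        feasible = 0
        r = resolution
        while r >= self.ssim_window and feasible < self.ms_ssim_scales:
            feasible += 1
            r //= 2
        if feasible == 0:
            raise ValueError(
                f"resolution {resolution} is smaller than the SSIM window "
                f"{self.ssim_window}; lower ssim_window or use larger frames"
            )
        w = np.asarray(self.ms_ssim_scale_weights[:feasible], dtype=float)
        return feasible, w / w.sum()


def _gaussian_1d(window: int, sigma: float, dtype) -> np.ndarray:
    half = (window - 1) / 2.0
    x = np.arange(window) - half
    k = np.exp(-(x**2) / (2 * sigma**2))
    return (k / k.sum()).astype(dtype)


def _blur(x: Tensor, window: int, sigma: float) -> Tensor:
    """Depthwise Gaussian filter (separable, valid padding), NCHW."""
    N, C, H, W = x.shape
    k = _gaussian_1d(window, sigma, x.dtype)
    kx = Tensor(k.reshape(1, 1, 1, window))
    ky = Tensor(k.reshape(1, 1, window, 1))
    flat = x.reshape(N * C, 1, H, W)
    out = conv2d(conv2d(flat, kx), ky)
    return out.reshape(N, C, H - window + 1, W - window + 1)


def _avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling; trailing odd row/column cropped first."""
    N, C, H, W = x.shape
    He, We = H - H % 2, W - W % 2
    if (He, We) != (H, W):
        parent = x
        data = parent.data[:, :, :He, :We]

        def bwd(g):
            full = np.zeros((N, C, H, W), dtype=g.dtype)
            full[:, :, :He, :We] = g
            parent._accum(full)

        x = Tensor(data, _parents=(parent,), _backward=bwd)
    return x.reshape(N, C, He // 2, 2, We // 2, 2).mean(axis=(3, 5))


def _ssim_stats(a: Tensor, b: Tensor, config: LossConfig) -> tuple[Tensor, Tensor]:
    """Mean luminance*cs map and mean cs map over windows and channels."""
    k1, k2 = config.stability_constants
    c1, c2 = k1 * k1, k2 * k2  # data range L = 1
    win, sig = config.ssim_window, config.ssim_sigma
    mu_a = _blur(a, win, sig)
    mu_b = _blur(b, win, sig)
    ea2 = _blur(a * a, win, sig)
    eb2 = _blur(b * b, win, sig)
    eab = _blur(a * b, win, sig)
    var_a = ea2 - mu_a * mu_a
    var_b = eb2 - mu_b * mu_b
    cov = eab - mu_a * mu_b
    lum = (2.0 * mu_a * mu_b + c1) / (mu_a * mu_a + mu_b * mu_b + c1)
    cs = (2.0 * cov + c2) / (var_a + var_b + c2)
    return (lum * cs).mean(), cs.mean()


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    if a.ndim != 3:
        raise ValueError(f"expected (H, W) or (H, W, C) frames, got {a.shape}")
    return a, b


def _to_nchw(frame: np.ndarray) -> Tensor:
    return Tensor(frame.transpose(2, 0, 1)[None])


def ssim(a, b, config: LossConfig | None = None) -> float:
    """Single-scale structural similarity between two [0,1] frames.

    Computed per channel over Gaussian-weighted sliding windows and averaged;
    symmetric, 1.0 exactly at identity.
    """
    config = config or LossConfig()
    a, b = _check_pair(a, b)
    val, _ = _ssim_stats(_to_nchw(a), _to_nchw(b), config)
    return float(val.data)


def ms_ssim_t(a: Tensor, b: Tensor, config: LossConfig) -> Tensor:
    """Differentiable MS-SSIM on NCHW tensors (mean over the batch)."""
    n_scales, weights = config.resolve_scales(min(a.shape[2], a.shape[3]))
    total: Tensor | None = None
    for m in range(n_scales):
        lum_cs, cs = _ssim_stats(a, b, config)
        term = (lum_cs if m == n_scales - 1 else cs).clamp_min(_CS_FLOOR) ** float(
            weights[m]
        )
        total = term if total is None else total * term
        if m < n_scales - 1:
            a, b = _avgpool2(a), _avgpool2(b)
    return total


def ms_ssim(a, b, config: LossConfig | None = None) -> float:
    """Multi-scale structural similarity between two [0,1] frames."""
    config = config or LossConfig()
    a, b = _check_pair(a, b)
    return float(ms_ssim_t(_to_nchw(a), _to_nchw(b), config).data)


def _dist_arrays(dist) -> tuple[np.ndarray, np.ndarray]:
    mean = np.asarray(dist.mean, dtype=np.float64)
    log_var = np.asarray(dist.log_variance, dtype=np.float64)
    if not (np.isfinite(mean).all() and np.isfinite(log_var).all()):
        raise ValueError("latent distribution contains non-finite values")
    return mean, log_var


def kl_normal(dist) -> float:
    """KL divergence of N(mean, exp(log_variance)) from the N(0, I) prior.

    Closed form: -0.5 * sum_d (1 + log_var_d - mean_d^2 - exp(log_var_d)).
    Non-negative; zero exactly when the posterior equals the prior.
    """
    mean, log_var = _dist_arrays(dist)
    return float(-0.5 * np.sum(1.0 + log_var - mean**2 - np.exp(log_var)))


def kl_normal_t(mean: Tensor, log_var: Tensor) -> Tensor:
    """Differentiable per-sample-summed KL, averaged over the batch."""
    per_dim = -0.5 * (1.0 + log_var - mean * mean - log_var.exp())
    return per_dim.sum(axis=1).mean()


def total_loss(original, reconstruction, dist, config: LossConfig | None = None):
    """(1 - MS-SSIM) + kl_weight * KL / code_length, with named components."""
    config = config or LossConfig()
    ms = ms_ssim(original, reconstruction, config)
    kl = kl_normal(dist)
    code_length = np.asarray(dist.mean).size
    kl_term = config.kl_weight * kl / code_length
    total = (1.0 - ms) + kl_term
    components = {
        "ms_ssim": ms,
        "reconstruction": 1.0 - ms,
        "kl": kl,
        "kl_term": kl_term,
        "total": total,
    }
    return total, components


def total_loss_t(
    original: Tensor,
    reconstruction: Tensor,
    mean: Tensor,
    log_var: Tensor,
    config: LossConfig,
) -> tuple[Tensor, dict[str, float]]:
    """Batched differentiable objective used by the training loop."""
    ms = ms_ssim_t(original, reconstruction, config)
    kl = kl_normal_t(mean, log_var)
    code_length = mean.shape[1]
    total = (1.0 - ms) + (config.kl_weight / code_length) * kl
    components = {
        "ms_ssim": float(ms.data),
        "reconstruction": 1.0 - float(ms.data),
        "kl": float(kl.data),
        "kl_term": config.kl_weight * float(kl.data) / code_length,
    }
    return total, components
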