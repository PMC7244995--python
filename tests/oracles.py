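"""Independent reference implementations used only to check the package.

Everything here is deliberately written by a different route than the
implementation under test: explicit window loops instead of im2col
convolution, explicit double-loop contingency tables instead of sklearn,
closed-form Gaussian cell probabilities instead of simulation.
"""

import numpy as np
from scipy.stats import norm

WINDOW = 11
SIGMA = 1.5
K1, K2 = 0.01, 0.03


def _gauss2d(window=WINDOW, sigma=SIGMA):
    half = (window - 1) / 2.0
    x = np.arange(window) - half
    k = np.exp(-(x**2) / (2 * sigma**2))
    k = k / k.sum()
    return np.outer(k, k)


def ssim_maps_loop(a, b, window=WINDOW, sigma=SIGMA, k1=K1, k2=K2):
    """Per-window luminance*cs and cs maps via explicit position loops."""
    w = _gauss2d(window, sigma)
    c1, c2 = k1 * k1, k2 * k2
    H, W, C = a.shape
    Ho, Wo = H - window + 1, W - window + 1
    lum_cs = np.empty((Ho, Wo, C))
    cs = np.empty((Ho, Wo, C))
    for i in range(Ho):
        for j in range(Wo):
            pa = a[i : i + window, j : j + window, :]
            pb = b[i : i + window, j : j + window, :]
            mu_a = np.einsum("ij,ijc->c", w, pa)
            mu_b = np.einsum("ij,ijc->c", w, pb)
            va = np.einsum("ij,ijc->c", w, pa * pa) - mu_a**2
            vb = np.einsum("ij,ijc->c", w, pb * pb) - mu_b**2
            cov = np.einsum("ij,ijc->c", w, pa * pb) - mu_a * mu_b
            l_term = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
            cs_term = (2 * cov + c2) / (va + vb + c2)
            lum_cs[i, j] = l_term * cs_term
            cs[i, j] = cs_term
    return lum_cs, cs


def ssim_loop(a, b, **kw):
    lum_cs, _ = ssim_maps_loop(a, b, **kw)
    return float(lum_cs.mean())


def _block_mean_2x(img):
    H, W, C = img.shape
    He, We = H - H % 2, W - W % 2
    img = img[:He, :We]
    return img.reshape(He // 2, 2, We // 2, 2, C).mean(axis=(1, 3))


def ms_ssim_loop(a, b, weights, **kw):
    """Multi-scale SSIM: cs terms at fine scales, luminance at the coarsest."""
    weights = np.asarray(weights, dtype=float)
    total = 1.0
    n = len(weights)
    for m in range(n):
        lum_cs, cs = ssim_maps_loop(a, b, **kw)
        term = lum_cs.mean() if m == n - 1 else cs.mean()
        total *= max(term, 1e-6) ** weights[m]
        if m < n - 1:
            a, b = _block_mean_2x(a), _block_mean_2x(b)
    return float(total)


def kappa_loop(a, b, scheme="linear", categories=(0, 1, 2, 3, 4)):
    """Weighted Cohen kappa by explicit double loops over the 5x5 table."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask].astype(int), b[mask].astype(int)
    n = len(a)
    k = len(categories)
    O = np.zeros((k, k))
    for x, y in zip(a, b):
        O[x, y] += 1
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            E[i, j] = row[i] * col[j] / n
    W = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            W[i, j] = abs(i - j) if scheme == "linear" else (i - j) ** 2
    denom = (W * E).sum()
    if denom == 0:
        return np.nan
    return 1.0 - (W * O).sum() / denom


def rater_category_probs(bias, sd, grade, categories=(0, 1, 2, 3, 4)):
    """P(emitted rating = k | true grade) under the Gaussian-discretized rater.

    The rater emits clip(round(grade + bias + N(0, sd)), 0, 4): interior
    categories collect one rounding bin each, the end categories absorb the
    clipped tails.  sd = 0 degenerates to a point mass.
    """
    mu = grade + bias
    k_lo, k_hi = categories[0], categories[-1]
    if sd == 0:
        p = np.zeros(len(categories))
        p[int(np.clip(np.round(mu), k_lo, k_hi)) - k_lo] = 1.0
        return p
    probs = []
    for k in categories:
        lo = -np.inf if k == k_lo else (k - 0.5 - mu) / sd
        hi = np.inf if k == k_hi else (k + 0.5 - mu) / sd
        probs.append(norm.cdf(hi) - norm.cdf(lo))
    return np.asarray(probs)


def analytic_rater_kappa(rater_a, rater_b, grade_probs, scheme="linear"):
    """Exact linearly weighted kappa implied by two rater models.

    `grade_probs[g]` is the probability of true grade g; O is the exact
    joint rating distribution, E the outer product of its marginals.
    """
    cats = (0, 1, 2, 3, 4)
    k = len(cats)
    O = np.zeros((k, k))
    for g, pg in enumerate(grade_probs):
        pa = rater_category_probs(rater_a.bias, rater_a.miscode_sd, g)
        pb = rater_category_probs(rater_b.bias, rater_b.miscode_sd, g)
        O += pg * np.outer(pa, pb)
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    W = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    if scheme == "quadratic":
        W = W**2
    return 1.0 - (W * O).sum() / (W * E).sum()
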