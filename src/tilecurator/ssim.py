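"""Structural similarity (SSIM) with an analytic gradient for training.

SSIM compares two images through local luminance, contrast and structure
statistics under a Gaussian window:

    SSIM(p) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
              / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

with C1 = (0.01 L)^2, C2 = (0.03 L)^2 for dynamic range L = 1. Statistics are
computed per channel at every fully supported ("valid") window position and
averaged over positions, channels and batch. The reconstruction loss is
``1 - mean SSIM``; because the Gaussian windowing is linear, the gradient of
the mean SSIM with respect to the reconstruction has a closed form, returned
by :func:`ssim_loss_and_grad` for the autoencoder's backward pass.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

DEFAULT_WINDOW = 11
DEFAULT_SIGMA = 1.5
C1 = 0.01 ** 2
C2 = 0.03 ** 2


def gaussian_window(size: int = DEFAULT_WINDOW, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian window (sums to 1)."""
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w2 = np.outer(g, g)
    return w2 / w2.sum()


def _as_bchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None, None]
    if x.ndim == 3:
        return x[None]
    if x.ndim == 4:
        return x
    raise ValueError(f"expected 2-4 dims (H,W)/(C,H,W)/(B,C,H,W), got shape {x.shape}")


def _filt_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return fftconvolve(x, w[None, None], mode="valid", axes=(2, 3))


def _filt_full(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Adjoint of the valid correlation: full convolution (the window is symmetric)
    return fftconvolve(x, w[None, None], mode="full", axes=(2, 3))


def _ssim_terms(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    mu_x = _filt_valid(x, w)
    mu_y = _filt_valid(y, w)
    var_x = _filt_valid(x * x, w) - mu_x ** 2
    var_y = _filt_valid(y * y, w) - mu_y ** 2
    cov = _filt_valid(x * y, w) - mu_x * mu_y
    a1 = 2 * mu_x * mu_y + C1
    a2 = 2 * cov + C2
    b1 = mu_x ** 2 + mu_y ** 2 + C1
    b2 = var_x + var_y + C2
    return mu_x, mu_y, a1, a2, b1, b2


def ssim(a: np.ndarray, b: np.ndarray, window_size: int = DEFAULT_WINDOW,
         sigma: float = DEFAULT_SIGMA) -> float:
    """Mean SSIM between ``a`` and ``b`` (values expected in [0, 1])."""
    x, y = _as_bchw(a), _as_bchw(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(x.shape[2], x.shape[3]) < window_size:
        raise ValueError(f"images must be at least {window_size} pixels on each side")
    w = gaussian_window(window_size, sigma)
    _, _, a1, a2, b1, b2 = _ssim_terms(x, y, w)
    return float(np.mean(a1 * a2 / (b1 * b2)))


def ssim_loss(batch: np.ndarray, reconstructions: np.ndarray,
              window_size: int = DEFAULT_WINDOW, sigma: float = DEFAULT_SIGMA) -> float:
    """Reconstruction loss ``1 - mean SSIM``; zero iff SSIM-identical."""
    return 1.0 - ssim(batch, reconstructions, window_size, sigma)


def ssim_loss_and_grad(batch: np.ndarray, reconstructions: np.ndarray,
                       window_size: int = DEFAULT_WINDOW, sigma: float = DEFAULT_SIGMA
                       ) -> tuple[float, np.ndarray]:
    """Loss ``1 - mean SSIM`` and its gradient w.r.t. the reconstructions.

    Chain rule through the three windowed statistics that depend on the
    reconstruction y (mu_y, sigma_y^2, sigma_xy); the adjoint of a valid
    Gaussian correlation is a full convolution with the same (symmetric)
    window.
    """
    x, y = _as_bchw(batch), _as_bchw(reconstructions)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {batch.shape} vs {reconstructions.shape}")
    w = gaussian_window(window_size, sigma)
    mu_x, mu_y, a1, a2, b1, b2 = _ssim_terms(x, y, w)
    s = a1 * a2 / (b1 * b2)
    loss = 1.0 - float(np.mean(s))

    # dS/d(mu_y), dS/d(var_y), dS/d(cov) at each window position
    d_mu = (2 * mu_x * b1 - 2 * mu_y * a1) / b1 ** 2 * (a2 / b2)
    d_var = -s / b2
    d_cov = 2 * (a1 / b1) / b2

    # fold the statistic definitions' own mu_y dependence into d_mu
    d_mu_total = d_mu - 2 * mu_y * d_var - mu_x * d_cov

    n = s.size  # mean over batch, channels and window positions
    grad_y = (_filt_full(d_mu_total, w)
              + 2 * y * _filt_full(d_var, w)
              + x * _filt_full(d_cov, w)) / n
    grad = (-grad_y).reshape(np.asarray(reconstructions).shape)  # d(1 - mean S)/dy
    return loss, grad.astype(np.float32)
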