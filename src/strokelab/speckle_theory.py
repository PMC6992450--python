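"""Closed-form statistics of time-integrated dynamic speckle.

For a camera exposure ``T`` integrating a speckle field whose intensity
autocorrelation decays exponentially with decorrelation time ``tau_c``
(Lorentzian field spectrum, Siegert relation), the spatial speckle contrast
is

    K(x)^2 = beta * (exp(-2x) - 1 + 2x) / (2 x^2),    x = T / tau_c,

where ``beta`` (0 < beta <= 1) is the instrument coherence factor.  In the
long-exposure limit (x >> 1) this reduces to K^2 ~ beta / x, so the blood
flow index BFI = 1/K^2 is proportional to 1/tau_c, i.e. to scatterer speed.
These closed forms are the single source of truth that both the synthetic
speckle generator and the flowmetry oracle tests evaluate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["contrast", "contrast_squared", "bfi_ratio"]


def contrast_squared(x, beta: float = 1.0):
    """Squared speckle contrast K^2 at exposure/decorrelation ratio ``x``.

    Parameters
    ----------
    x : array_like
        Ratio exposure / tau_c, non-negative. ``x = 0`` (static scatterers)
        returns ``beta`` (fully developed speckle).
    beta : float
        Coherence factor, 0 < beta <= 1.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("exposure/tau_c ratio must be non-negative")
    out = np.empty_like(x)
    small = x < 1e-4
    # series: (e^{-2x} - 1 + 2x) / (2x^2) = 1 - 2x/3 + x^2/3 - ...
    xs = x[small]
    out[small] = 1.0 - 2.0 * xs / 3.0 + xs * xs / 3.0
    xl = x[~small]
    out[~small] = (np.exp(-2.0 * xl) - 1.0 + 2.0 * xl) / (2.0 * xl * xl)
    result = beta * out
    return result if result.ndim else float(result)


def contrast(x, beta: float = 1.0):
    """Speckle contrast K = sigma_s / <I> at exposure/tau_c ratio ``x``."""
    return np.sqrt(contrast_squared(x, beta))


def bfi_ratio(tau_c_baseline: float, tau_c_post: float, exposure_s: float,
              beta: float = 1.0) -> float:
    """Theoretical post/baseline ratio of the blood flow index 1/K^2.

    Used as the oracle for percent-drop targets: a five-fold increase in
    tau_c at 5-ms exposure gives a ratio of ~0.202, i.e. an ~80% drop.
    """
    k2_base = contrast_squared(exposure_s / tau_c_baseline, beta)
    k2_post = contrast_squared(exposure_s / tau_c_post, beta)
    return float(k2_base / k2_post)
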