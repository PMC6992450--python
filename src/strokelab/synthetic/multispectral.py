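"""Hemodynamic forward model: multispectral reflectance movies.

Generates the three-LED reflectance record that the Beer-Lambert inversion
consumes, by running that model forward: a spatial response footprint times
per-trial oxy/deoxy concentration time courses gives dHbO/dHbR per pixel,
the extinction matrix gives the absorption change per wavelength, and
I = I0 * exp(-dmu_a * L) gives the recorded intensity, optionally corrupted
by multiplicative Gaussian relative-intensity noise. At zero noise the
inversion must recover the generator's time courses to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from strokelab.mbll import (ExtinctionTable, MultispectralStack,
                            PathlengthTable, TrialDesign)

__all__ = ["HemoForwardSpec", "canonical_response", "gaussian_kernel",
           "gen_multispectral_movie"]


def canonical_response(design: TrialDesign | None = None,
                       rate_hz: float = 10.0,
                       peak_dHbO: float = 1e-5,
                       peak_dHbR: float = -2.5e-6):
    """Smooth single-trial hemodynamic response (molar), zero at baseline.

    Ramps up over the stimulus period (functional hyperemia raises HbO and
    washes out HbR, hence opposite signs) and decays exponentially during
    recovery. Exactly zero over the baseline window so that per-trial
    baseline referencing is lossless.
    """
    design = design or TrialDesign()
    n = int(round(design.trial_s * rate_hz))
    t = np.arange(n) / rate_hz
    t_on = design.baseline_s
    t_off = design.baseline_s + design.stim_s
    shape = np.zeros(n)
    rising = (t >= t_on) & (t < t_off)
    shape[rising] = (1.0 - np.cos(np.pi * (t[rising] - t_on)
                                  / design.stim_s)) / 2.0
    decay = t >= t_off
    shape[decay] = np.exp(-(t[decay] - t_off) / 3.0)
    return peak_dHbO * shape, peak_dHbR * shape


def gaussian_kernel(shape: tuple[int, int] = (64, 64),
                    center: tuple[float, float] | None = None,
                    sigma_px: float = 8.0) -> np.ndarray:
    """Unit-peak Gaussian response footprint (the activated cortical patch)."""
    ny, nx = shape
    cy, cx = center if center is not None else ((ny - 1) / 2, (nx - 1) / 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))


@dataclass
class HemoForwardSpec:
    """Forward-model inputs for one multispectral acquisition.

    dHbO_t / dHbR_t: single-trial concentration time courses (molar),
    sampled at ``rate_hz``, tiled over ``trial_design.n_trials``;
    spatial_kernel: unitless response footprint multiplying both;
    wavelengths: exactly the LED set the inversion will use;
    noise_sd: multiplicative relative-intensity noise fraction.
    """

    dHbO_t: np.ndarray
    dHbR_t: np.ndarray
    spatial_kernel: np.ndarray
    wavelengths: tuple[float, ...] = (470.0, 530.0, 625.0)
    trial_design: TrialDesign = field(default_factory=TrialDesign)
    rate_hz: float = 10.0
    noise_sd: float = 0.0

    def __post_init__(self):
        n = int(round(self.trial_design.trial_s * self.rate_hz))
        if len(self.dHbO_t) != n or len(self.dHbR_t) != n:
            raise ValueError(
                f"time courses must have {n} samples for this design")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_multispectral_movie(spec: HemoForwardSpec, extinction: ExtinctionTable,
                            pathlength: PathlengthTable, seed: int = 0,
                            i0: float = 2000.0) -> MultispectralStack:
    """Forward-model a full block-design multispectral record.

    Raises if either table lacks any of the spec's wavelengths.
    """
    E = extinction.matrix(spec.wavelengths)      # (n_wl, 2), cm^-1 M^-1
    L = pathlength.vector(spec.wavelengths)      # (n_wl,), cm
    n_trials = spec.trial_design.n_trials
    dHbO = np.tile(np.asarray(spec.dHbO_t, float), n_trials)
    dHbR = np.tile(np.asarray(spec.dHbR_t, float), n_trials)
    kernel = np.asarray(spec.spatial_kernel, dtype=float)

    rng = np.random.default_rng(seed)
    frames = {}
    for (eps_o, eps_r), l_wl, wl in zip(E, L, spec.wavelengths):
        # dmu_a(t, y, x), cm^-1
        dmua = (eps_o * dHbO + eps_r * dHbR)[:, None, None] * kernel
        intensity = i0 * np.exp(-dmua * l_wl)
        if spec.noise_sd > 0:
            intensity = intensity * (
                1.0 + spec.noise_sd * rng.standard_normal(intensity.shape))
        frames[wl] = intensity
    trial_s = spec.trial_design.trial_s
    triggers = np.arange(n_trials) * trial_s
    return MultispectralStack(frames=frames, wavelengths=spec.wavelengths,
                              per_wavelength_rate_hz=spec.rate_hz,
                              trigger_log=triggers)
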