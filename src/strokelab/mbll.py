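"""Multispectral intrinsic optical signal analysis via the modified
Beer–Lambert law.

Chain: reflectance movies at three LED wavelengths -> change in optical
density ``dOD(lambda, t) = -ln(I / I0)`` with I0 the per-trial baseline
(first 5 s) -> change in absorption ``dmu_a = dOD / L(lambda)`` using
wavelength-dependent mean pathlengths -> least-squares inversion of
``dmu_a = eps_HbO * dHbO + eps_HbR * dHbR`` across wavelengths -> block
averaging over the stimulation trials and a stimulus-period dHbT response
map used to pick the supplying arterial branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MultispectralStack", "ExtinctionTable", "PathlengthTable",
    "HemodynamicSeries", "TrialDesign", "DEFAULT_EXTINCTION",
    "DEFAULT_PATHLENGTH", "delta_od", "invert_mua", "solve_hemoglobin",
    "block_average", "response_roi",
]


@dataclass(frozen=True)
class TrialDesign:
    """Block design of one stimulation trial, in seconds."""

    baseline_s: float = 5.0
    stim_s: float = 5.0
    recovery_s: float = 20.0
    n_trials: int = 20
    stim_rate_hz: float = 3.0

    def __post_init__(self):
        if min(self.baseline_s, self.stim_s, self.recovery_s) <= 0:
            raise ValueError("trial phase durations must be positive")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stim_s + self.recovery_s


@dataclass
class MultispectralStack:
    """Demultiplexed per-wavelength reflectance movies.

    frames: dict wavelength (nm) -> (n_t, ny, nx) camera counts, all with
    the same length; per_wavelength_rate_hz: effective frame rate at each
    wavelength after demultiplexing the interleaved acquisition (10 Hz
    default, from 30-Hz sequential illumination of three LEDs);
    trigger_log: trial-onset timestamps in seconds.
    """

    frames: dict[float, np.ndarray]
    wavelengths: tuple[float, ...] = (470.0, 530.0, 625.0)
    per_wavelength_rate_hz: float = 10.0
    trigger_log: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self):
        lengths = {wl: np.asarray(f).shape[0] for wl, f in self.frames.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"inconsistent per-wavelength lengths: {lengths}")
        missing = set(self.wavelengths) - set(self.frames)
        if missing:
            raise ValueError(f"frames missing for wavelengths {sorted(missing)}")


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (cm^-1 M^-1) per wavelength (nm)."""

    eps: dict[float, tuple[float, float]]  # wavelength -> (eps_HbO, eps_HbR)

    def __post_init__(self):
        for wl, (eo, er) in self.eps.items():
            if eo <= 0 or er <= 0:
                raise ValueError(f"non-positive extinction at {wl} nm")

    def matrix(self, wavelengths) -> np.ndarray:
        missing = [wl for wl in wavelengths if wl not in self.eps]
        if missing:
            raise KeyError(f"extinction table missing wavelengths {missing}")
        return np.array([self.eps[wl] for wl in wavelengths], dtype=float)


@dataclass(frozen=True)
class PathlengthTable:
    """Mean pathlength L (cm) through tissue per wavelength (nm).

    Defaults follow published Monte Carlo estimates of visible-light
    pathlength in rodent cortex; both tables are configuration inputs, so
    downstream results are exact in whatever tables are supplied.
    """

    L: dict[float, float]

    def __post_init__(self):
        for wl, l in self.L.items():
            if l <= 0:
                raise ValueError(f"non-positive pathlength at {wl} nm")

    def vector(self, wavelengths) -> np.ndarray:
        missing = [wl for wl in wavelengths if wl not in self.L]
        if missing:
            raise KeyError(f"pathlength table missing wavelengths {missing}")
        return np.array([self.L[wl] for wl in wavelengths], dtype=float)


# Compiled in-vitro hemoglobin extinction spectra, cm^-1 M^-1.
DEFAULT_EXTINCTION = ExtinctionTable(eps={
    470.0: (33209.2, 16156.4),
    530.0: (40092.0, 39036.4),
    625.0: (740.8, 5763.4),
})

# Mean visible-light pathlengths in cortex (cm): short in the strongly
# absorbed blue/green bands, long in the red.
DEFAULT_PATHLENGTH = PathlengthTable(L={
    470.0: 0.039,
    530.0: 0.048,
    625.0: 0.297,
})


@dataclass
class HemodynamicSeries:
    """Per-pixel oxy/deoxy/total hemoglobin concentration changes (molar).

    dHbT is dHbO + dHbR by construction, never estimated separately.
    """

    dHbO: np.ndarray
    dHbR: np.ndarray
    wavelengths: tuple[float, ...] = (470.0, 530.0, 625.0)
    rate_hz: float = 10.0

    @property
    def dHbT(self) -> np.ndarray:
        return self.dHbO + self.dHbR


def delta_od(stack: MultispectralStack, baseline_window_s: float = 5.0,
             design: TrialDesign | None = None) -> dict[float, np.ndarray]:
    """Change in optical density -ln(I/I0), I0 = per-trial baseline mean.

    Each trial's first ``baseline_window_s`` seconds define its own I0, so
    slow drifts between trials are removed. Non-positive intensities are
    masked to NaN with a warning.
    """
    design = design or TrialDesign()
    rate = stack.per_wavelength_rate_hz
    n_trial = int(round(design.trial_s * rate))
    n_base = int(round(baseline_window_s * rate))
    out = {}
    for wl in stack.wavelengths:
        frames = np.asarray(stack.frames[wl], dtype=float)
        if np.any(frames <= 0):
            warnings.warn("non-positive intensities masked in delta_od")
            frames = np.where(frames > 0, frames, np.nan)
        n_t = frames.shape[0]
        n_full = n_t // n_trial
        if n_full < 1:
            raise ValueError("record shorter than one trial")
        od = np.full_like(frames, np.nan)
        for k in range(n_full):
            sl = slice(k * n_trial, (k + 1) * n_trial)
            i0 = np.nanmean(frames[sl][:n_base], axis=0)
            od[sl] = -np.log(frames[sl] / i0)
        out[wl] = od
    return out


def invert_mua(dod: dict[float, np.ndarray],
               pathlength: PathlengthTable) -> dict[float, np.ndarray]:
    """Change in absorption coefficient dmu_a = dOD / L(lambda), cm^-1."""
    wavelengths = list(dod)
    L = pathlength.vector(wavelengths)
    return {wl: np.asarray(dod[wl]) / l for wl, l in zip(wavelengths, L)}


def solve_hemoglobin(dmua: dict[float, np.ndarray], ext: ExtinctionTable,
                     rate_hz: float = 10.0,
                     max_condition: float = 1e6) -> HemodynamicSeries:
    """Least-squares inversion of the extinction system per pixel and time.

    With three wavelengths and two chromophores the system is
    overdetermined; ordinary least squares via the pseudoinverse of the
    (n_wavelengths x 2) extinction matrix solves it. Rejects
    rank-deficient or ill-conditioned systems.
    """
    wavelengths = tuple(dmua)
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelengths to separate HbO/HbR")
    E = ext.matrix(wavelengths)
    cond = np.linalg.cond(E)
    if cond > max_condition:
        raise ValueError(
            f"extinction matrix ill-conditioned (condition number {cond:.3g})")
    pinv = np.linalg.pinv(E)  # (2, n_wl)
    stacked = np.stack([np.asarray(dmua[wl], dtype=float)
                        for wl in wavelengths], axis=0)
    sol = np.tensordot(pinv, stacked, axes=(1, 0))  # (2, n_t, ny, nx)
    return HemodynamicSeries(dHbO=sol[0], dHbR=sol[1],
                             wavelengths=wavelengths, rate_hz=rate_hz)


def block_average(series: HemodynamicSeries,
                  design: TrialDesign | None = None):
    """Trial-aligned mean time course and the stimulus-period dHbT map.

    A truncated final trial is dropped with a warning. The response map is
    the time-mean dHbT over the stimulus window of the trial-averaged
    series.

    Returns (trial_mean: HemodynamicSeries over one trial, response_map).
    """
    design = design or TrialDesign()
    rate = series.rate_hz
    n_trial = int(round(design.trial_s * rate))
    n_t = series.dHbO.shape[0]
    n_full = n_t // n_trial
    if n_full < 1:
        raise ValueError("no complete trial in record")
    if n_t % n_trial:
        warnings.warn(f"dropping truncated final trial "
                      f"({n_t - n_full * n_trial} frames)")

    def fold(arr):
        arr = arr[: n_full * n_trial]
        return arr.reshape((n_full, n_trial) + arr.shape[1:]).mean(axis=0)

    trial_mean = HemodynamicSeries(
        dHbO=fold(series.dHbO), dHbR=fold(series.dHbR),
        wavelengths=series.wavelengths, rate_hz=rate)
    s0 = int(round(design.baseline_s * rate))
    s1 = int(round((design.baseline_s + design.stim_s) * rate))
    response_map = trial_mean.dHbT[s0:s1].mean(axis=0)
    return trial_mean, response_map


def response_roi(response_map: np.ndarray, threshold_fraction: float = 0.5):
    """Candidate target region: connected components above a fraction of the
    map maximum, largest flagged.

    Returns (mask of the largest suprathreshold component, flags list).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    m = np.asarray(response_map, dtype=float)
    peak = np.nanmax(m)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("response map empty or non-positive everywhere")
    above = m >= threshold_fraction * peak
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    flags = []
    if mask.mean() > 0.9:
        flags.append("non-localized response: component spans >90% of field")
    return mask, flags
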