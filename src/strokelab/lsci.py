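"""Laser speckle contrast flowmetry and closed-loop illumination guidance.

Implements the spatial-contrast analysis chain used to monitor cerebral
blood flow during targeted photothrombosis:

* spatial speckle contrast ``K = sigma_s / <I>`` over a sliding 7x7 bin,
* blood flow index ``BFI = 1/K^2`` (relative flow surrogate),
* percent-of-baseline flow maps and ROI time courses,
* the feedback state machine that holds the photoactivation laser at full
  power until the target vessel occludes, drops to half power for a fixed
  hold, switches off, and re-arms on recanalization,
* the fixed-duration (nonoptimized) illumination protocol for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SpeckleStack", "ContrastMap", "BFIMap", "LaserState", "ProtocolTrace",
    "GuidanceParams", "spatial_contrast", "blood_flow_index", "relative_cbf",
    "occlusion_guidance", "nonoptimized_protocol", "field_of_view_mm",
]


@dataclass
class SpeckleStack:
    """Time-ordered raw speckle frames with acquisition metadata.

    frames are camera counts, shape (n_frames, ny, nx); exposure_s is the
    integration time of each frame (5 ms default) and fps the acquisition
    rate (40 Hz default), so exposure must not exceed the frame interval.
    """

    frames: np.ndarray
    exposure_s: float = 0.005
    fps: float = 40.0
    pixel_size_um: float = 2.75

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.exposure_s > 1.0 / self.fps:
            raise ValueError(
                f"exposure {self.exposure_s} s exceeds frame interval "
                f"{1.0 / self.fps} s")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class ContrastMap:
    """Per-pixel spatial speckle contrast over an odd square window."""

    K: np.ndarray
    window: int = 7

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclass
class BFIMap:
    """Per-pixel blood flow index 1/K^2, NaN where contrast is unreliable."""

    bfi: np.ndarray


class LaserState(str, Enum):
    FULL = "FULL"
    HALF = "HALF"
    OFF = "OFF"


STATE_POWER_MW = {LaserState.FULL: 0.6, LaserState.HALF: 0.3, LaserState.OFF: 0.0}


@dataclass
class ProtocolTrace:
    """Timestamped laser-state sequence emitted by a protocol.

    ``events`` is a DataFrame with columns (t_s, state, power_mw); the laser
    holds each state until the next event. ``occlusion_confirmed`` is set by
    the guidance controller when both the vessel-drop and region-drop
    criteria were met simultaneously.
    """

    events: pd.DataFrame
    occlusion_confirmed: bool = False
    flags: list = field(default_factory=list)

    def state_at(self, t: float) -> LaserState:
        ev = self.events[self.events.t_s <= t]
        if ev.empty:
            return LaserState.OFF
        return LaserState(ev.iloc[-1].state)

    def total_time_in(self, state: LaserState, end_t: float) -> float:
        total = 0.0
        ev = self.events
        for i in range(len(ev)):
            t0 = ev.iloc[i].t_s
            t1 = ev.iloc[i + 1].t_s if i + 1 < len(ev) else end_t
            if LaserState(ev.iloc[i].state) is state:
                total += max(0.0, min(t1, end_t) - t0)
        return total


def field_of_view_mm(n_pixels: int = 2048, pixel_pitch_um: float = 5.5,
                     magnification: float = 2.0) -> float:
    """Object-plane field of view of the speckle camera in mm.

    With a 2048-px sensor of 5.5-um pitch behind 2x magnification the field
    is 5.6 mm on a side.
    """
    return n_pixels * pixel_pitch_um / magnification / 1000.0


def spatial_contrast(frame: np.ndarray, window: int = 7,
                     border: str = "reflect") -> ContrastMap:
    """Spatial speckle contrast: local population std / local mean.

    Parameters
    ----------
    frame : 2-D array of camera counts.
    window : odd sliding-bin size (7 default).
    border : "reflect" (default) pads the frame so edge pixels get a full
        window; "mask" sets the half-window border to NaN instead.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(frame.shape):
        raise ValueError("window larger than frame")
    if border not in ("reflect", "mask"):
        raise ValueError(f"unknown border policy {border!r}")

    m = ndimage.uniform_filter(frame, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(frame * frame, size=window, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(m > 0, np.sqrt(var) / np.where(m > 0, m, 1.0), np.nan)
    if border == "mask":
        h = window // 2
        K[:h, :] = np.nan
        K[-h:, :] = np.nan
        K[:, :h] = np.nan
        K[:, -h:] = np.nan
    return ContrastMap(K=K, window=window)


def blood_flow_index(cmap: ContrastMap, k_floor: float = 1e-3) -> BFIMap:
    """Blood flow index 1/K^2, masked (NaN) where K < k_floor."""
    if k_floor <= 0:
        raise ValueError("k_floor must be positive")
    K = cmap.K
    with np.errstate(invalid="ignore", divide="ignore"):
        bfi = np.where(K >= k_floor, 1.0 / (K * K), np.nan)
    return BFIMap(bfi=bfi)


def _stack_bfi(stack: SpeckleStack, window: int, k_floor: float) -> np.ndarray:
    out = np.empty_like(stack.frames, dtype=float)
    for i, frame in enumerate(stack.frames):
        out[i] = blood_flow_index(spatial_contrast(frame, window), k_floor).bfi
    return out


def relative_cbf(stack: SpeckleStack, baseline_window: tuple[float, float],
                 roi_set: dict[str, np.ndarray], window: int = 7,
                 k_floor: float = 1e-3, smooth_s: float = 1.0,
                 gaps: Sequence[tuple[float, float]] = ()):
    """Percent-of-baseline blood flow maps and ROI time courses.

    The per-frame BFI is smoothed with a ``smooth_s``-second sliding mean,
    then referenced to the mean BFI over ``baseline_window`` (start, stop in
    seconds; must precede the rest of the record). ``gaps`` are (start, stop)
    intervals (e.g. animal repositioning) reported as NaN, never
    interpolated.

    Returns
    -------
    percent_maps : (n_frames, ny, nx) percent-of-baseline maps.
    traces : DataFrame (t_s, roi, percent_baseline), one row per frame per
        ROI; ROI traces are ROI-mean BFI over ROI-mean baseline BFI.
    """
    t = stack.times_s
    b0, b1 = baseline_window
    base_sel = (t >= b0) & (t < b1)
    if not np.any(base_sel):
        raise ValueError("empty baseline window")
    bfi = _stack_bfi(stack, window, k_floor)
    if smooth_s > 0:
        n = max(1, int(round(smooth_s * stack.fps)))
        if n > 1:
            kernel = np.ones(n) / n
            bfi = ndimage.convolve1d(bfi, kernel, axis=0, mode="nearest")

    baseline_map = np.nanmean(bfi[base_sel], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent_maps = 100.0 * bfi / baseline_map

    in_gap = np.zeros(stack.n_frames, dtype=bool)
    for g0, g1 in gaps:
        in_gap |= (t >= g0) & (t < g1)
    percent_maps[in_gap] = np.nan

    rows = []
    for name, roi in roi_set.items():
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != stack.frames.shape[1:]:
            raise ValueError(f"ROI {name!r} shape does not match frames")
        roi_base = np.nanmean(baseline_map[roi])
        roi_trace = 100.0 * np.nanmean(bfi[:, roi], axis=1) / roi_base
        roi_trace[in_gap] = np.nan
        rows.append(pd.DataFrame(
            {"t_s": t, "roi": name, "percent_baseline": roi_trace}))
    traces = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["t_s", "roi", "percent_baseline"])
    return percent_maps, traces


@dataclass
class GuidanceParams:
    """Thresholds of the occlusion-guidance controller.

    occlusion_drop_pct: vessel BFI drop (percent of baseline) that counts as
    occluded (>= 80 confirms occlusion); region_drop_pct: supplied-region
    drop required for confirmation (> 50); half_power_hold_s: half-power
    hold after occlusion before switching off (120 s); persistence_s:
    debounce — criteria must hold continuously this long before any state
    change; rearm_drop_pct: from OFF, drops below this re-arm full power
    (recanalization).
    """

    occlusion_drop_pct: float = 80.0
    region_drop_pct: float = 50.0
    half_power_hold_s: float = 120.0
    persistence_s: float = 5.0
    rearm_drop_pct: float = 50.0


def _sustained(cond: np.ndarray, i: int, n_persist: int) -> bool:
    """True when cond holds at every sample in [i - n_persist + 1, i]."""
    if i - n_persist + 1 < 0:
        return False
    return bool(np.all(cond[i - n_persist + 1: i + 1]))


def occlusion_guidance(vessel_trace: np.ndarray, region_trace: np.ndarray,
                       t_s: np.ndarray,
                       params: GuidanceParams | None = None) -> ProtocolTrace:
    """Closed-loop illumination controller driven by percent-baseline traces.

    Walks a deterministic automaton over the sampled traces: FULL until the
    vessel drop has persisted at or beyond ``occlusion_drop_pct``, then HALF
    for ``half_power_hold_s``, then OFF; from OFF, a persistent
    recanalization (drop below ``rearm_drop_pct``) returns to FULL.
    Occlusion is confirmed only if, in some persistence window, the vessel
    and supplied-region criteria held simultaneously. NaN samples (gaps)
    satisfy no criterion, so the automaton holds state through them.
    """
    params = params or GuidanceParams()
    vessel_trace = np.asarray(vessel_trace, dtype=float)
    region_trace = np.asarray(region_trace, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if not (vessel_trace.shape == region_trace.shape == t_s.shape):
        raise ValueError("traces and clock must share one sampling grid")
    if len(t_s) < 2:
        raise ValueError("need at least two samples")
    dt = float(np.median(np.diff(t_s)))
    if not np.allclose(np.diff(t_s), dt, rtol=0, atol=1e-9 + 1e-6 * dt):
        raise ValueError("traces must be uniformly sampled on a common clock")

    n_persist = max(1, int(round(params.persistence_s / dt)))
    with np.errstate(invalid="ignore"):
        vessel_drop = 100.0 - vessel_trace
        region_drop = 100.0 - region_trace
        occluded = vessel_drop >= params.occlusion_drop_pct
        recanalized = vessel_drop < params.rearm_drop_pct
        region_ok = region_drop >= params.region_drop_pct
    occluded &= np.isfinite(vessel_trace)
    recanalized &= np.isfinite(vessel_trace)
    region_ok &= np.isfinite(region_trace)

    state = LaserState.FULL
    events = [(float(t_s[0]), state)]
    confirmed = False
    half_until = np.inf
    for i, t in enumerate(t_s):
        if _sustained(occluded & region_ok, i, n_persist):
            confirmed = True
        if state is LaserState.FULL:
            if _sustained(occluded, i, n_persist):
                state = LaserState.HALF
                half_until = t + params.half_power_hold_s
                events.append((float(t), state))
        elif state is LaserState.HALF:
            if t >= half_until:
                state = LaserState.OFF
                events.append((float(t), state))
        else:  # OFF
            if _sustained(recanalized, i, n_persist):
                state = LaserState.FULL
                events.append((float(t), state))

    df = pd.DataFrame(
        [(t, s.value, STATE_POWER_MW[s]) for t, s in events],
        columns=["t_s", "state", "power_mw"])
    return ProtocolTrace(events=df, occlusion_confirmed=confirmed)


def nonoptimized_protocol(duration_s: float = 900.0) -> ProtocolTrace:
    """Fixed-duration illumination: FULL for ``duration_s`` (15 min default),
    then OFF, independent of any feedback."""
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    flags = []
    if duration_s == 0:
        flags.append("empty illumination: zero duration requested")
        df = pd.DataFrame([(0.0, LaserState.OFF.value, 0.0)],
                          columns=["t_s", "state", "power_mw"])
        return ProtocolTrace(events=df, flags=flags)
    df = pd.DataFrame(
        [(0.0, LaserState.FULL.value, STATE_POWER_MW[LaserState.FULL]),
         (float(duration_s), LaserState.OFF.value, 0.0)],
        columns=["t_s", "state", "power_mw"])
    return ProtocolTrace(events=df)
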