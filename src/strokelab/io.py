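"""Reading and writing the pipeline's on-disk formats.

Image stacks travel as multi-page grayscale TIFF with a JSON sidecar
carrying the acquisition metadata (exposure, frame rate, wavelength order,
voxel size, seed); multispectral movies are stored wavelength-interleaved
in the declared order; fluence and angiogram volumes as raw .npy plus a
JSON header; tabular outputs (ROI traces, protocol events, paw events,
ring profiles) as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from strokelab.beam_optics import FluenceGrid
from strokelab.lsci import ProtocolTrace, SpeckleStack
from strokelab.mbll import MultispectralStack

__all__ = [
    "write_speckle_stack", "read_speckle_stack",
    "write_multispectral_stack", "read_multispectral_stack",
    "write_volume", "read_volume", "write_fluence_grid",
    "write_protocol_trace", "read_protocol_trace",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_speckle_stack(path, stack: SpeckleStack, seed: int | None = None,
                        extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    meta = {"exposure_s": stack.exposure_s, "fps": stack.fps,
            "pixel_size_um": stack.pixel_size_um, "seed": seed}
    meta.update(extra or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_speckle_stack(path) -> SpeckleStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return SpeckleStack(frames=np.asarray(frames, dtype=float),
                        exposure_s=meta["exposure_s"], fps=meta["fps"],
                        pixel_size_um=meta.get("pixel_size_um", 2.75))


def write_multispectral_stack(path, stack: MultispectralStack,
                              seed: int | None = None) -> None:
    """Wavelength-interleaved multi-page TIFF in the declared LED order."""
    path = Path(path)
    wls = list(stack.wavelengths)
    per = [np.asarray(stack.frames[wl], dtype=np.float32) for wl in wls]
    n_t = per[0].shape[0]
    interleaved = np.empty((n_t * len(wls),) + per[0].shape[1:],
                           dtype=np.float32)
    for i, arr in enumerate(per):
        interleaved[i::len(wls)] = arr
    tifffile.imwrite(path, interleaved, photometric="minisblack")
    meta = {"wavelengths_nm": wls,
            "per_wavelength_rate_hz": stack.per_wavelength_rate_hz,
            "trigger_log_s": np.asarray(stack.trigger_log).tolist(),
            "seed": seed}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_multispectral_stack(path) -> MultispectralStack:
    path = Path(path)
    interleaved = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    wls = [float(w) for w in meta["wavelengths_nm"]]
    frames = {wl: np.asarray(interleaved[i::len(wls)], dtype=float)
              for i, wl in enumerate(wls)}
    return MultispectralStack(
        frames=frames, wavelengths=tuple(wls),
        per_wavelength_rate_hz=meta["per_wavelength_rate_hz"],
        trigger_log=np.asarray(meta["trigger_log_s"]))


def write_volume(path, volume: np.ndarray, header: dict) -> None:
    """Raw volume as .npy with a JSON header alongside."""
    path = Path(path)
    np.save(path, volume)
    hdr = dict(header)
    hdr["shape"] = list(volume.shape)
    hdr["dtype"] = str(volume.dtype)
    _sidecar(path.with_suffix(".npy")).write_text(json.dumps(hdr, indent=2))


def read_volume(path):
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    volume = np.load(path)
    header = json.loads(_sidecar(path).read_text())
    return volume, header


def write_fluence_grid(path, grid: FluenceGrid) -> None:
    write_volume(path, grid.deposited, {
        "voxel_um": grid.voxel_um, "n_photons": grid.n_photons,
        "seed": grid.seed, "escaped_weight": grid.escaped_weight})


def write_protocol_trace(path, trace: ProtocolTrace) -> None:
    trace.events.to_csv(path, index=False)


def read_protocol_trace(path) -> ProtocolTrace:
    return ProtocolTrace(events=pd.read_csv(path))
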