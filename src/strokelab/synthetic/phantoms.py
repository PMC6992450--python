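"""Latent flow phantoms for speckle simulation.

A FlowPhantom holds the per-pixel speckle decorrelation time tau_c (the
latent flow state: faster flow, shorter tau_c), a pial-vessel mask, and
coarse region labels (stroke core / remote control / background). The
deterministic geometry mimics a cranial-window field: one target arterial
branch with two collateral branches over parenchyma, a supplied core
territory beside the vessel, and a remote territory on the far side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw, morphology

__all__ = ["FlowPhantom", "make_flow_phantom", "occlude",
           "REGION_BACKGROUND", "REGION_CORE", "REGION_REMOTE"]

REGION_BACKGROUND = 0
REGION_CORE = 1
REGION_REMOTE = 2


@dataclass
class FlowPhantom:
    """Per-pixel decorrelation-time field with vessel and region maps.

    tau_c_map: seconds, strictly positive; vessel_mask: boolean pial-vessel
    map; region_labels: integer ROI map (0 background, 1 core, 2 remote);
    beta: speckle coherence factor in (0, 1].
    """

    tau_c_map: np.ndarray
    vessel_mask: np.ndarray
    region_labels: np.ndarray
    beta: float = 1.0

    def __post_init__(self):
        self.tau_c_map = np.asarray(self.tau_c_map, dtype=float)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        self.region_labels = np.asarray(self.region_labels)
        if np.any(self.tau_c_map <= 0):
            raise ValueError("tau_c_map must be strictly positive everywhere")
        if not (self.tau_c_map.shape == self.vessel_mask.shape
                == self.region_labels.shape):
            raise ValueError("tau_c_map, vessel_mask and region_labels must "
                             "share one grid shape")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")

    def rois(self) -> dict[str, np.ndarray]:
        """Named analysis ROIs: the target vessel, the supplied core, and a
        remote control region."""
        return {
            "vessel": self.vessel_mask,
            "core": self.region_labels == REGION_CORE,
            "remote": self.region_labels == REGION_REMOTE,
        }


def make_flow_phantom(shape: tuple[int, int] = (256, 256),
                      tau_c_vessel_s: float = 20e-6,
                      tau_c_parenchyma_s: float = 40e-6,
                      vessel_width_px: int = 40,
                      region_radius_px: int = 72,
                      beta: float = 1.0) -> FlowPhantom:
    """Deterministic cranial-window phantom.

    The target branch runs vertically through the field with two collateral
    branches leaving it at 45 degrees (occluding two collaterals on average
    is what stabilizes the stroke in practice, so the geometry keeps them).
    ``vessel_width_px`` is generous by default (a perivascular ROI, not the
    lumen) so that the vessel ROI holds >= 10^4 pixels on a 256 x 256 field.
    The core region is the territory beside the vessel; the remote region
    mirrors it on the far side.
    """
    ny, nx = shape
    vessel = np.zeros(shape, dtype=bool)
    cx = nx // 3
    rr, cc = draw.line(0, cx, ny - 1, cx)
    vessel[rr, cc] = True
    for y0 in (ny // 4, 3 * ny // 4):  # two collaterals
        length = min(nx - cx - 2, ny - y0 - 2, nx // 3)
        rr, cc = draw.line(y0, cx, y0 + length, cx + length)
        vessel[rr, cc] = True
    vessel = morphology.dilation(
        vessel, morphology.disk(max(1, vessel_width_px // 2)))

    regions = np.full(shape, REGION_BACKGROUND, dtype=np.int8)
    yy, xx = np.mgrid[0:ny, 0:nx]
    core_c = (ny // 2, min(nx - region_radius_px - 2, cx + nx // 3 + 10))
    remote_c = (ny // 2, max(region_radius_px // 4, cx - nx // 4))
    core = (yy - core_c[0]) ** 2 + (xx - core_c[1]) ** 2 <= region_radius_px ** 2
    remote = ((yy - remote_c[0]) ** 2 + (xx - remote_c[1]) ** 2
              <= (region_radius_px // 2) ** 2)
    regions[core & ~vessel] = REGION_CORE
    regions[remote & ~vessel] = REGION_REMOTE

    tau = np.full(shape, tau_c_parenchyma_s, dtype=float)
    tau[vessel] = tau_c_vessel_s
    return FlowPhantom(tau_c_map=tau, vessel_mask=vessel,
                       region_labels=regions, beta=beta)


def occlude(phantom: FlowPhantom, vessel_factor: float = 5.0,
            core_factor: float = 2.5) -> FlowPhantom:
    """Post-occlusion phantom: decorrelation times lengthen where flow
    slows — by ``vessel_factor`` in the target vessel and ``core_factor``
    in the supplied core territory; the remote region is untouched."""
    if vessel_factor <= 0 or core_factor <= 0:
        raise ValueError("occlusion factors must be positive")
    tau = phantom.tau_c_map.copy()
    tau[phantom.vessel_mask] *= vessel_factor
    tau[phantom.region_labels == REGION_CORE] *= core_factor
    return FlowPhantom(tau_c_map=tau, vessel_mask=phantom.vessel_mask,
                       region_labels=phantom.region_labels, beta=phantom.beta)
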