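"""Spatial network templates on the synthetic voxel grid.

Each template is a set of compact Gaussian blobs standing in for the
anatomical nodes of a network: the olfactory network (ON: primary olfactory
cortex, hippocampus, insula, striatum) and the default mode network (DMN:
PCC/precuneus, bilateral inferior parietal cortex, mPFC, medial temporal
lobe).  Blob supports are hard-truncated so blobs are disjoint within and
across templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

ON = "ON"
DMN = "DMN"

DEFAULT_GRID = (24, 24, 12)

# Blob centres (voxel coordinates).  ON sits on the z=3 plane, DMN on z=9:
# the 6-voxel plane separation alone keeps the 2.8-voxel supports disjoint.
ON_BLOBS: Dict[str, Tuple[float, float, float]] = {
    "POC": (5, 5, 3),
    "hippocampus": (13, 5, 3),
    "insula": (5, 13, 3),
    "striatum": (13, 13, 3),
}
DMN_BLOBS: Dict[str, Tuple[float, float, float]] = {
    "PCC_precuneus": (11, 11, 9),
    "IPC_left": (5, 5, 9),
    "IPC_right": (18, 5, 9),
    "mPFC": (5, 18, 9),
    "MTL": (18, 18, 9),
}


@dataclass(frozen=True)
class NetworkTemplate:
    """Non-negative spatial weight map with named, disjoint blobs."""

    label: str
    map: np.ndarray  # 3-D, non-negative
    blobs: Dict[str, Tuple[float, float, float]]

    def __post_init__(self):
        if np.any(self.map < 0):
            raise ValueError("template weights must be non-negative")

    @property
    def support(self) -> np.ndarray:
        return self.map > 0


def _blob_field(
    shape: Tuple[int, int, int],
    centers: Dict[str, Tuple[float, float, float]],
    sigma: float,
    radius: float,
) -> np.ndarray:
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    field = np.zeros(shape)
    for center in centers.values():
        d2 = np.sum((grid - np.asarray(center)) ** 2, axis=-1)
        blob = np.exp(-d2 / (2.0 * sigma**2))
        blob[d2 > radius**2] = 0.0
        if np.any((field > 0) & (blob > 0)):
            raise ValueError("blob supports overlap within template")
        field += blob
    return field


def default_templates(
    shape: Tuple[int, int, int] = DEFAULT_GRID,
    sigma: float = 1.6,
    radius: float = 2.8,
) -> Tuple[NetworkTemplate, NetworkTemplate]:
    """Build the (ON, DMN) template pair on ``shape``.

    ``sigma`` is the Gaussian width and ``radius`` the hard support radius,
    both in voxels.  Raises if the requested geometry makes any two blobs
    overlap.
    """
    on = NetworkTemplate(ON, _blob_field(shape, ON_BLOBS, sigma, radius), ON_BLOBS)
    dmn = NetworkTemplate(DMN, _blob_field(shape, DMN_BLOBS, sigma, radius), DMN_BLOBS)
    if np.any(on.support & dmn.support):
        raise ValueError("ON and DMN blob supports overlap")
    return on, dmn
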