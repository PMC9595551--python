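"""Mean-threshold (MT) void segmentation.

One global threshold per volume: the arithmetic mean of all voxel
intensities.  Voxels strictly below the threshold are classified as void
(lacunae, canals) — mineralized bone is X-ray bright, voids are dark.
The strict inequality makes a constant image yield no voids.

The threshold can alternatively be supplied as a fixed number (the
shared-threshold reading of applying one threshold to every sample); the
value actually used is always reported in the run report.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import NumericError
from .volume_io import BinaryMask, VoxelGrid


def mean_threshold(grid: VoxelGrid, within: np.ndarray | None = None) -> float:
    """Arithmetic mean intensity of the volume (one global value).

    Parameters
    ----------
    grid
        Intensity volume.
    within
        Optional boolean restriction mask (e.g. a bone mask excluding
        exterior air).  Default: the full volume, matching scans whose field
        of view is bone-filled.
    """
    if grid.data.size == 0:
        raise NumericError("cannot compute mean threshold of an empty volume")
    if within is None:
        return float(np.mean(grid.data, dtype=np.float64))
    within = np.asarray(within, dtype=bool)
    if within.shape != grid.data.shape:
        raise NumericError(
            f"restriction mask shape {within.shape} != volume shape {grid.data.shape}"
        )
    if not within.any():
        raise NumericError("restriction mask selects no voxels")
    return float(np.mean(grid.data[within], dtype=np.float64))


def segment_voids(grid: VoxelGrid, threshold: float) -> BinaryMask:
    """Binarize: void where intensity is strictly below ``threshold``."""
    threshold = float(threshold)
    if not math.isfinite(threshold):
        raise NumericError(f"threshold must be finite, got {threshold}")
    return BinaryMask(data=grid.data < threshold, spacing=grid.spacing, name=grid.name)


def segment(grid: VoxelGrid, threshold: float | None = None) -> tuple[BinaryMask, float]:
    """Segment voids; compute the mean threshold unless one is given.

    Returns the mask together with the threshold value actually used.
    """
    t = mean_threshold(grid) if threshold is None else float(threshold)
    return segment_voids(grid, t), t
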