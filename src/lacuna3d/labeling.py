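"""6-connected component labeling of the void mask.

Two voxels belong to the same object iff they are connected by a chain of
face adjacencies (the 6-neighborhood); edge- and corner-touching voxels are
distinct objects.  Labels are dense in ``{1..n_labels}`` and assigned in the
lexicographic (C-scan) order of each component's first voxel, so the same
mask always yields the same label map.

`label_components` delegates the flood fill to ``scipy.ndimage.label`` and
canonicalizes its output; `flood_fill_oracle` is an independent pure-Python
breadth-first implementation used to cross-check it.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NumericError
from .volume_io import BinaryMask, Spacing

#: face-adjacency structuring element
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)

_NEIGHBORS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass
class LabelMap:
    """Integer component map: 0 = background, labels 1..n_labels dense."""

    data: np.ndarray
    n_labels: int
    spacing: Spacing
    name: str = ""

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def voxel_counts(self) -> np.ndarray:
        """Voxels per label, index i -> label i+1."""
        counts = np.bincount(self.data.ravel(), minlength=self.n_labels + 1)
        return counts[1:]

    def volumes_um3(self) -> np.ndarray:
        """Physical volume per label in um^3 (voxel count x voxel volume)."""
        return self.voxel_counts() * self.voxel_volume_um3


def _canonicalize(raw: np.ndarray, n: int) -> np.ndarray:
    """Relabel so labels follow first-voxel lexicographic (C-scan) order."""
    if n == 0:
        return raw.astype(np.int32)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    labs, first = np.unique(flat[nz], return_index=True)
    order = np.argsort(first, kind="stable")
    lut = np.zeros(int(labs.max()) + 1, dtype=np.int32)
    lut[labs[order]] = np.arange(1, n + 1, dtype=np.int32)
    return lut[raw]


def label_components(mask: BinaryMask) -> LabelMap:
    """Partition the mask into 6-connected components (deterministic labels)."""
    raw, n = ndimage.label(mask.data, structure=STRUCTURE_6)
    data = _canonicalize(raw, n)
    return LabelMap(data=data, n_labels=int(n), spacing=mask.spacing, name=mask.name)


def flood_fill_oracle(mask: BinaryMask) -> LabelMap:
    """Breadth-first flood-fill labeling over the 6-neighborhood.

    Independent reference implementation; intended for test-scale masks
    (explicit Python queue traversal).
    """
    m = mask.data
    out = np.zeros(m.shape, dtype=np.int32)
    nz, ny, nx = m.shape
    n = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not m[z, y, x] or out[z, y, x]:
                    continue
                n += 1
                queue = deque([(z, y, x)])
                out[z, y, x] = n
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in _NEIGHBORS_6:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                            if m[pz, py, px] and not out[pz, py, px]:
                                out[pz, py, px] = n
                                queue.append((pz, py, px))
    return LabelMap(data=out, n_labels=n, spacing=mask.spacing, name=mask.name)


def exclude_border(labelmap: LabelMap) -> LabelMap:
    """Drop components touching any face of the volume; relabel densely.

    Off by default in the pipeline (border components are retained, as no
    border exclusion is part of the counting procedure); provided for users
    who want unbiased per-object statistics.
    """
    d = labelmap.data
    border_labels = np.unique(
        np.concatenate(
            [
                d[0].ravel(), d[-1].ravel(),
                d[:, 0].ravel(), d[:, -1].ravel(),
                d[:, :, 0].ravel(), d[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels > 0]
    keep = np.ones(labelmap.n_labels + 1, dtype=bool)
    keep[border_labels] = False
    keep[0] = False
    lut = np.zeros(labelmap.n_labels + 1, dtype=np.int32)
    kept = np.flatnonzero(keep)
    lut[kept] = np.arange(1, kept.size + 1, dtype=np.int32)
    return LabelMap(
        data=lut[d], n_labels=int(kept.size), spacing=labelmap.spacing, name=labelmap.name
    )


def partition_sets(labelmap: LabelMap) -> set[frozenset]:
    """The component partition as a set of voxel-index sets (labeling-order
    independent; used to compare two labelings as partitions)."""
    flat = labelmap.data.ravel()
    nz = np.flatnonzero(flat)
    groups: dict[int, list[int]] = {}
    for idx, lab in zip(nz.tolist(), flat[nz].tolist()):
        groups.setdefault(lab, []).append(idx)
    return {frozenset(v) for v in groups.values()}


def component_mask(labelmap: LabelMap, label_id: int) -> np.ndarray:
    if not 1 <= label_id <= labelmap.n_labels:
        raise NumericError(f"label {label_id} outside 1..{labelmap.n_labels}")
    return labelmap.data == label_id
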