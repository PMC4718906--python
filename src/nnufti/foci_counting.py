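"""Connected-component labelling of uptake foci.

A voxel is foreground iff it lies inside the liver VOI *and* its value is
greater than or equal to the threshold (inclusive, so the hottest voxel
always survives at C_thr = C_max).  Connected components of the
foreground are the uptake foci; their count is the NUF.  The VOI is a
hard boundary: above-threshold voxels outside it never join a focus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .volume_io import LiverVOI, SpectVolume, check_same_grid

#: map face/edge/corner connectivity to a scipy binary structure
_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(connectivity)]
    except (KeyError, TypeError, ValueError):
        raise ParameterError(
            f"connectivity must be one of 6, 18, 26; got {connectivity!r}"
        ) from None


@dataclass(frozen=True)
class FociLabeling:
    """Labelled uptake foci at one threshold.

    ``labels`` holds 0 for background and 1..count for foci; label ids
    follow lexicographic (C-order) first-voxel order, so repeated runs on
    the same inputs produce identical arrays.
    """

    labels: np.ndarray
    count: int
    threshold: float
    connectivity: int
    min_size: int


def _relabel_scan_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels by first occurrence in C scan order; 0 stays background."""
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    nz = ids != 0
    ids, first = ids[nz], first[nz]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    mapping[ids[order]] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return mapping[labels], len(ids)


def label_foci(
    volume: SpectVolume,
    voi: LiverVOI,
    threshold: float,
    connectivity: int = 26,
    min_size: int = 1,
) -> FociLabeling:
    """Label connected above-threshold regions inside the VOI.

    Components with fewer than ``min_size`` voxels are relabelled to
    background and excluded from the count.
    """
    check_same_grid(volume, voi)
    structure = _structure(connectivity)
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    if min_size < 1:
        raise ParameterError(f"min_size must be a positive integer, got {min_size}")
    foreground = voi.mask & (volume.values >= threshold)
    labels, _ = ndi.label(foreground, structure=structure)
    if min_size > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size)
        keep = np.ones(len(sizes), dtype=bool)
        keep[small] = False
        keep[0] = False
        labels = np.where(keep[labels], labels, 0)
    labels, count = _relabel_scan_order(labels)
    return FociLabeling(
        labels=labels,
        count=count,
        threshold=float(threshold),
        connectivity=int(connectivity),
        min_size=int(min_size),
    )


def count_foci(
    volume: SpectVolume,
    voi: LiverVOI,
    threshold: float,
    connectivity: int = 26,
    min_size: int = 1,
) -> int:
    """Number of uptake foci (NUF) at one threshold."""
    return label_foci(volume, voi, threshold, connectivity, min_size).count


def _count_components(
    values: np.ndarray, threshold: float, structure: np.ndarray, min_size: int
) -> int:
    # fast path used by the threshold sweep: no VOI re-masking, no relabel
    labels, n = ndi.label(values >= threshold, structure=structure)
    if min_size <= 1 or n == 0:
        return int(n)
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_size).sum())
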