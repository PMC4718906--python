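"""The nNUFTI curve: normalized number of uptake foci versus threshold index.

For one liver the VOI is thresholded at G equally spaced levels between 0
(excluded) and the maximum VOI voxel value C_max.  Each threshold C_thr
maps to the dimensionless threshold index

    ThI = (C_max - C_thr) / C_max

so ThI = 0 at the hottest voxel and ThI -> 1 as the threshold vanishes.
The number of uptake foci (NUF) at each level, divided by its maximum
over all levels, gives the normalized NUF (nNUF).  Tumour-free livers
produce a bell-shaped nNUF-vs-ThI curve; hot lesions compress and shift
it towards higher ThI, which the right-branch crossing statistic
(:func:`thi_at_nnuf`) quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DomainError, MaskValidationError, NoCrossingError
from .foci_counting import _count_components, _structure
from .volume_io import LiverVOI, SpectVolume, check_same_grid

DEFAULT_GRID_SIZE = 256


def threshold_index(c_max: float, c_thr: float) -> float:
    """Threshold index ThI = (C_max - C_thr) / C_max, in [0, 1]."""
    if c_max <= 0:
        raise DomainError(f"C_max must be > 0, got {c_max}")
    if not 0 <= c_thr <= c_max:
        raise DomainError(f"C_thr must lie in [0, C_max={c_max}], got {c_thr}")
    return (c_max - c_thr) / c_max


@dataclass(frozen=True)
class NNUFTICurve:
    """Sampled (C_thr, ThI, NUF, nNUF) table for one liver VOI.

    Rows are ordered by strictly increasing ThI (strictly decreasing
    C_thr); nNUF is normalized so its maximum over rows is exactly 1.
    """

    c_thr: np.ndarray
    thi: np.ndarray
    nuf: np.ndarray
    nnuf: np.ndarray
    c_max: float
    mean_conc: float
    grid_size: int
    connectivity: int = 26
    min_size: int = 1

    def __post_init__(self) -> None:
        c_thr = np.asarray(self.c_thr, dtype=np.float64)
        thi = np.asarray(self.thi, dtype=np.float64)
        nuf = np.asarray(self.nuf, dtype=np.int64)
        nnuf = np.asarray(self.nnuf, dtype=np.float64)
        n = len(c_thr)
        if not (len(thi) == len(nuf) == len(nnuf) == n) or n == 0:
            raise DomainError("curve columns must be nonempty and equal length")
        if np.any(np.diff(thi) <= 0) or np.any(np.diff(c_thr) >= 0):
            raise DomainError("rows must have strictly increasing ThI")
        expected = (self.c_max - c_thr) / self.c_max
        if not np.allclose(thi, expected, rtol=0, atol=64 * np.finfo(float).eps):
            raise DomainError("ThI column inconsistent with C_max and C_thr")
        if nnuf.max() != 1.0:
            raise DomainError("max nNUF must equal 1 exactly")
        if nuf.min() < 0:
            raise DomainError("NUF must be non-negative")
        at_cmax = np.flatnonzero(c_thr == self.c_max)
        if self.min_size <= 1 and at_cmax.size and nuf[at_cmax[0]] < 1:
            raise DomainError("NUF must be >= 1 at C_thr = C_max")
        for name, arr in (("c_thr", c_thr), ("thi", thi), ("nuf", nuf), ("nnuf", nnuf)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.thi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.c_thr, "thi": self.thi,
             "nuf": self.nuf, "nnuf": self.nnuf}
        )

    def argmax_row(self) -> int:
        """Index of the curve maximum (first row among ties)."""
        return int(np.argmax(self.nnuf))

    def equals(self, other: "NNUFTICurve") -> bool:
        return (
            np.array_equal(self.c_thr, other.c_thr)
            and np.array_equal(self.thi, other.thi)
            and np.array_equal(self.nuf, other.nuf)
            and np.array_equal(self.nnuf, other.nnuf)
            and self.c_max == other.c_max
            and self.mean_conc == other.mean_conc
            and self.grid_size == other.grid_size
            and self.connectivity == other.connectivity
            and self.min_size == other.min_size
        )


def mean_concentration(volume: SpectVolume, voi: LiverVOI) -> float:
    """Arithmetic mean activity concentration over VOI voxels (counts/voxel)."""
    check_same_grid(volume, voi)
    return float(volume.values[voi.mask].mean())


def compute_curve(
    volume: SpectVolume,
    voi: LiverVOI,
    grid_size: int = DEFAULT_GRID_SIZE,
    connectivity: int = 26,
    min_size: int = 1,
) -> NNUFTICurve:
    """Sweep thresholds over the VOI and build the nNUFTI curve.

    Thresholds are C_thr(k) = k * C_max / G for k = G .. 1 (threshold 0
    excluded), giving G rows at ThI = 0, 1/G, ..., (G-1)/G.
    """
    check_same_grid(volume, voi)
    if grid_size < 1:
        raise DomainError(f"grid_size must be >= 1, got {grid_size}")
    structure = _structure(connectivity)
    voi_values = volume.values[voi.mask]
    c_max = float(voi_values.max())
    if c_max <= 0:
        raise DomainError("maximum VOI voxel value must be > 0")
    mean_conc = float(voi_values.mean())

    # crop to the VOI bounding box and pin non-VOI voxels below any
    # threshold, so each labelling touches as few voxels as possible
    bbox = ndi.find_objects(voi.mask.astype(np.int8))[0]
    sub = np.where(voi.mask[bbox], volume.values[bbox], -1.0)

    ks = np.arange(grid_size, 0, -1)
    c_thr = ks * c_max / grid_size
    thi = (c_max - c_thr) / c_max
    nuf = np.empty(grid_size, dtype=np.int64)
    for i, thr in enumerate(c_thr):
        nuf[i] = _count_components(sub, thr, structure, min_size)
    nnuf = nuf / nuf.max()
    return NNUFTICurve(
        c_thr=c_thr, thi=thi, nuf=nuf, nnuf=nnuf,
        c_max=c_max, mean_conc=mean_conc, grid_size=int(grid_size),
        connectivity=int(connectivity), min_size=int(min_size),
    )


def thi_at_nnuf(curve: NNUFTICurve, level: float = 0.25, side: str = "right") -> float:
    """ThI where the curve crosses an nNUF level on one branch.

    The crossing is linearly interpolated between the two bracketing grid
    rows.  On the right branch (rows after the curve maximum) the first
    above-to-below crossing is returned; on the left branch the last
    below-to-above crossing before the maximum.
    """
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")
    if side not in ("left", "right"):
        raise DomainError(f"side must be 'left' or 'right', got {side!r}")
    peak = curve.argmax_row()
    thi, nnuf = curve.thi, curve.nnuf
    if side == "right":
        for i in range(peak, len(curve) - 1):
            if nnuf[i] >= level > nnuf[i + 1]:
                frac = (nnuf[i] - level) / (nnuf[i] - nnuf[i + 1])
                return float(thi[i] + frac * (thi[i + 1] - thi[i]))
        reached = float(nnuf[peak:].min())
    else:
        for i in range(peak - 1, -1, -1):
            if nnuf[i] < level <= nnuf[i + 1]:
                frac = (level - nnuf[i]) / (nnuf[i + 1] - nnuf[i])
                return float(thi[i] + frac * (thi[i + 1] - thi[i]))
        reached = float(nnuf[: peak + 1].min())
    raise NoCrossingError(side=side, level=level, min_nnuf=reached)
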