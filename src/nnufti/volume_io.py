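"""Reading and writing volumes, liver masks, curve tables and cohort tables.

Volumes and masks travel as NIfTI-1 files; the reconstructed emission
volume is stored one activity value (counts) per voxel.  Derived results
(nNUFTI curves, patient cohorts) are persisted as plain CSV with ``#``
metadata lines so they stay diffable and language neutral.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    CurveParseError,
    GeometryError,
    MaskValidationError,
    VolumeFormatError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .curve import NNUFTICurve

logger = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]

#: float format used for CSV persistence; round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class SpectVolume:
    """A reconstructed 3D emission volume.

    Parameters
    ----------
    values
        3D array of non-negative activity values, in counts per voxel.
    spacing
        Voxel edge lengths in mm, one per axis.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or min(values.shape) < 1:
            raise VolumeFormatError(
                f"expected a 3D volume, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise VolumeFormatError("volume contains non-finite values")
        if values.min() < 0:
            raise VolumeFormatError(
                "volume contains negative values; clamp before construction"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"invalid voxel spacing {spacing!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LiverVOI:
    """Binary liver volume-of-interest mask on the same grid as its volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask != 0
        if mask.ndim != 3:
            raise MaskValidationError(f"expected a 3D mask, got shape {mask.shape}")
        if not mask.any():
            raise MaskValidationError("liver VOI selects no voxels")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def check_same_grid(volume: SpectVolume, voi: LiverVOI) -> None:
    """Raise :class:`GeometryError` unless volume and VOI share a grid."""
    if volume.shape != voi.shape:
        raise GeometryError(
            f"volume grid {volume.shape} != mask grid {voi.shape}"
        )


def load_volume(path: PathLike) -> SpectVolume:
    """Load a NIfTI-1 emission volume.

    Negative voxels (float noise from the reconstruction) are clamped to
    zero; the number of clamped voxels is reported through the module
    logger at WARNING level.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O flavours
        raise VolumeFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path!r}: expected a 3D scalar image, got {data.ndim}D"
        )
    n_negative = int((data < 0).sum())
    if n_negative:
        logger.warning(
            "%s: clamped %d negative voxel(s) to 0", path, n_negative
        )
        data = np.clip(data, 0.0, None)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SpectVolume(values=data, spacing=spacing)


def save_volume(volume: SpectVolume, path: PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from its spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values, affine), str(path))


def load_mask(path: PathLike, shape: tuple[int, int, int] | None = None) -> LiverVOI:
    """Load a liver VOI mask; any nonzero voxel is treated as selected."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read NIfTI mask {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!r}: expected a 3D mask, got {data.ndim}D")
    if shape is not None and tuple(data.shape) != tuple(shape):
        raise GeometryError(
            f"mask grid {tuple(data.shape)} does not match volume grid {tuple(shape)}"
        )
    return LiverVOI(mask=data != 0)


def save_mask(voi: LiverVOI, path: PathLike,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(voi.mask.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# curve CSV persistence
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["threshold", "thi", "nuf", "nnuf"]


def write_curve(curve: "NNUFTICurve", path: PathLike) -> None:
    """Persist a curve as CSV with ``#`` metadata lines.

    Metadata records C_max, the mean VOI activity concentration and the
    analysis parameters so a curve file is self-describing.
    """
    meta = [
        f"# c_max={_FLOAT_FMT % curve.c_max}",
        f"# mean_conc={_FLOAT_FMT % curve.mean_conc}",
        f"# grid_size={curve.grid_size}",
        f"# connectivity={curve.connectivity}",
        f"# min_size={curve.min_size}",
    ]
    frame = curve.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(meta) + "\n")
        fh.write(buf.getvalue())


def _parse_metadata(path: PathLike) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_curve(path: PathLike) -> "NNUFTICurve":
    """Read a curve CSV written by :func:`write_curve`."""
    from .curve import NNUFTICurve

    meta = _parse_metadata(path)
    required_meta = {"c_max", "mean_conc", "grid_size", "connectivity", "min_size"}
    missing = required_meta - meta.keys()
    if missing:
        raise CurveParseError(f"{path!r}: missing metadata {sorted(missing)}")
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise CurveParseError(f"{path!r}: unreadable CSV: {exc}") from exc
    if list(frame.columns) != _CURVE_COLUMNS:
        raise CurveParseError(
            f"{path!r}: expected columns {_CURVE_COLUMNS}, got {list(frame.columns)}"
        )
    return NNUFTICurve(
        c_thr=frame["threshold"].to_numpy(dtype=np.float64),
        thi=frame["thi"].to_numpy(dtype=np.float64),
        nuf=frame["nuf"].to_numpy(dtype=np.int64),
        nnuf=frame["nnuf"].to_numpy(dtype=np.float64),
        c_max=float(meta["c_max"]),
        mean_conc=float(meta["mean_conc"]),
        grid_size=int(meta["grid_size"]),
        connectivity=int(meta["connectivity"]),
        min_size=int(meta["min_size"]),
    )


# ---------------------------------------------------------------------------
# cohort CSV persistence
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "group", "thi", "mean_conc", "nthi", "ppv", "band"]


def write_cohort(frame: pd.DataFrame, path: PathLike, metadata: dict | None = None) -> None:
    """Write a cohort table (one row per patient) with optional metadata lines."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveParseError(f"cohort table missing columns {missing}")
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame[COHORT_COLUMNS].to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read a cohort CSV; string columns stay strings, numbers become floats."""
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip",
                            dtype={"patient_id": str, "group": str, "band": str})
    except Exception as exc:
        raise CurveParseError(f"{path!r}: unreadable cohort CSV: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveParseError(f"{path!r}: cohort CSV missing columns {missing}")
    frame = frame[COHORT_COLUMNS]
    for column in ("thi", "mean_conc", "nthi", "ppv"):
        frame[column] = frame[column].astype(np.float64)
    return frame
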