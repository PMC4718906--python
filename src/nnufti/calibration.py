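"""Choosing the operating nNUF level and normalizing ThI for count rate.

Two calibration steps run on labelled cohorts of nNUFTI curves:

1. *Level selection.*  For a grid of candidate nNUF levels, the ThI
   crossing is extracted on each branch of every curve and the pooled
   Student t score between the tumour-free and tumour-bearing cohorts is
   computed.  The (level, side) pair with the highest t score separates
   the groups best; on clinical data this lands on the right branch.

2. *Concentration normalization.*  ThI at the chosen level falls with
   the mean activity concentration m of the liver (noise amplitude
   scales like sqrt(m)/m, so low-count livers sprout noise foci at lower
   ThI).  A quadratic f(m) fitted to tumour-free livers is used to
   correct every ThI additively to a reference concentration
   (60 counts/voxel): nThI = ThI - f(m) + f(m_ref).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .curve import NNUFTICurve, thi_at_nnuf
from .errors import (
    CalibrationError,
    DegenerateDataError,
    DomainError,
    ExtrapolationWarning,
    FitError,
    NoCrossingError,
)

#: reference mean activity concentration, counts per voxel
M_REF_DEFAULT = 60.0

#: candidate nNUF levels scanned by default
DEFAULT_NNUF_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))

#: extrapolation factor beyond the fitted m range that triggers a warning
EXTRAPOLATION_FACTOR = 2.0


def t_score(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> float:
    """Absolute two-sample Student t statistic (pooled variance).

    ``welch=True`` switches to the unequal-variance form for sensitivity
    analysis; the pooled form is the default throughout the package.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / len(a) + vb / len(b)
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se2 = sp2 * (1 / len(a) + 1 / len(b))
    if se2 == 0:
        raise DegenerateDataError("zero pooled variance; t score undefined")
    return float(abs(a.mean() - b.mean()) / np.sqrt(se2))


@dataclass(frozen=True)
class CalibrationResult:
    """Full t-score scan over candidate nNUF levels plus its argmax.

    ``t_left`` / ``t_right`` hold NaN at levels where any cohort curve
    lacks a crossing on that side (skipped, never imputed).
    """

    nnuf_grid: np.ndarray
    t_left: np.ndarray
    t_right: np.ndarray
    optimal_level: float
    optimal_side: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": np.concatenate([self.nnuf_grid, self.nnuf_grid]),
                "side": ["left"] * len(self.nnuf_grid) + ["right"] * len(self.nnuf_grid),
                "t_score": np.concatenate([self.t_left, self.t_right]),
            }
        )


def _cohort_thi(curves: Sequence[NNUFTICurve], level: float, side: str):
    values = []
    for curve in curves:
        try:
            values.append(thi_at_nnuf(curve, level, side))
        except NoCrossingError:
            return None
    return values


def scan_optimal_nnuf(
    neg_curves: Sequence[NNUFTICurve],
    pos_curves: Sequence[NNUFTICurve],
    nnuf_grid: Sequence[float] = DEFAULT_NNUF_GRID,
    welch: bool = False,
) -> CalibrationResult:
    """Scan nNUF levels on both branches for the best cohort separation."""
    if len(neg_curves) < 2 or len(pos_curves) < 2:
        raise DomainError("need at least 2 curves per cohort")
    grid = np.asarray(list(nnuf_grid), dtype=np.float64)
    scores = {"left": np.full(len(grid), np.nan), "right": np.full(len(grid), np.nan)}
    for side in ("left", "right"):
        for i, level in enumerate(grid):
            neg = _cohort_thi(neg_curves, level, side)
            pos = _cohort_thi(pos_curves, level, side)
            if neg is None or pos is None:
                continue
            try:
                scores[side][i] = t_score(neg, pos, welch=welch)
            except DegenerateDataError:
                continue
    all_scores = np.concatenate([scores["left"], scores["right"]])
    if np.all(np.isnan(all_scores)):
        raise CalibrationError("no nNUF level has crossings for every curve")
    best = int(np.nanargmax(all_scores))
    side = "left" if best < len(grid) else "right"
    level = float(grid[best % len(grid)])
    return CalibrationResult(
        nnuf_grid=grid,
        t_left=scores["left"],
        t_right=scores["right"],
        optimal_level=level,
        optimal_side=side,
    )


@dataclass(frozen=True)
class ConcentrationModel:
    """Quadratic ThI-vs-mean-concentration model, f(m) = c0 + c1 m + c2 m^2."""

    coefficients: tuple[float, float, float]
    m_ref: float = M_REF_DEFAULT
    r_squared: float = 0.0
    n_fit: int = 0
    m_range: tuple[float, float] = (0.0, np.inf)

    def predict(self, m: float) -> float:
        c0, c1, c2 = self.coefficients
        return c0 + c1 * m + c2 * m * m

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        payload = {
            "coefficients": list(self.coefficients),
            "m_ref": self.m_ref,
            "r_squared": self.r_squared,
            "n_fit": self.n_fit,
            "m_range": list(self.m_range),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: Union[str, os.PathLike]) -> "ConcentrationModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            coefficients=tuple(payload["coefficients"]),
            m_ref=float(payload["m_ref"]),
            r_squared=float(payload["r_squared"]),
            n_fit=int(payload["n_fit"]),
            m_range=tuple(payload["m_range"]),
        )


def fit_concentration_model(
    pairs: Sequence[tuple[float, float]],
    m_ref: float = M_REF_DEFAULT,
) -> ConcentrationModel:
    """Ordinary least-squares quadratic fit of ThI on mean concentration."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError("need at least 3 (m, thi) pairs")
    m, thi = arr[:, 0], arr[:, 1]
    if len(np.unique(m)) < 3:
        raise FitError("need at least 3 distinct mean concentrations")
    design = np.vander(m, 3, increasing=True)  # columns 1, m, m^2
    coef, *_ = np.linalg.lstsq(design, thi, rcond=None)
    fitted = design @ coef
    ss_res = float(((thi - fitted) ** 2).sum())
    ss_tot = float(((thi - thi.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ConcentrationModel(
        coefficients=(float(coef[0]), float(coef[1]), float(coef[2])),
        m_ref=float(m_ref),
        r_squared=r_squared,
        n_fit=len(m),
        m_range=(float(m.min()), float(m.max())),
    )


def normalize_thi(model: ConcentrationModel, thi: float, m: float) -> float:
    """Correct ThI to the reference concentration: nThI = ThI - f(m) + f(m_ref).

    The additive form preserves within-cohort spread and is the exact
    identity at m = m_ref.  Concentrations beyond twice (or below half)
    the fitted range trigger an :class:`ExtrapolationWarning` but the
    corrected value is still returned.
    """
    if m <= 0:
        raise DomainError(f"mean concentration must be > 0, got {m}")
    lo, hi = model.m_range
    if m < lo / EXTRAPOLATION_FACTOR or m > hi * EXTRAPOLATION_FACTOR:
        warnings.warn(
            f"mean concentration {m:g} is far outside the fitted range "
            f"[{lo:g}, {hi:g}]; nThI is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(thi - model.predict(m) + model.predict(model.m_ref))
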