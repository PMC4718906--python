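"""Patient-level decision statistics on normalized threshold indices.

Given per-patient nThI values, this module computes group comparisons
(pooled Student t, two-sided p), the positive predictive value of an
individual nThI used as a detection threshold, and a three-way decision
band.  Band edges follow the clinical reading of the benchmark cohorts:
nThI below 0.64 carries little extra information, values in [0.64, 0.70)
warrant follow-up with other modalities, and values at or above 0.70
strongly indicate tumour burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError, UndefinedPPVError

#: default decision-band edges on nThI
LOW_EDGE_DEFAULT = 0.64
HIGH_EDGE_DEFAULT = 0.70


class GroupSummary(NamedTuple):
    """Sufficient statistics (n, mean, sd) for one group of nThI values."""

    n: int
    mean: float
    sd: float


@dataclass
class CohortRecord:
    """One patient's nNUFTI read-out."""

    patient_id: str
    group: str  # radtech_neg | radtech_pos | octreotide_pos
    thi: float
    mean_conc: float
    nthi: float | None = None
    ppv: float | None = None
    band: str | None = None


def _summarize(values_or_summary) -> GroupSummary:
    if isinstance(values_or_summary, GroupSummary):
        return values_or_summary
    if isinstance(values_or_summary, tuple) and len(values_or_summary) == 3 \
            and isinstance(values_or_summary[0], (int, np.integer)):
        return GroupSummary(*values_or_summary)
    arr = np.asarray(list(values_or_summary), dtype=np.float64)
    if len(arr) < 2:
        raise DomainError("each group needs at least 2 values")
    return GroupSummary(n=len(arr), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def group_compare(
    values_a: Union[Sequence[float], GroupSummary],
    values_b: Union[Sequence[float], GroupSummary],
) -> tuple[float, int, float]:
    """Pooled two-sample Student t test; returns (t, df, two-sided p).

    Either argument may be a :class:`GroupSummary` so published
    (n, mean, sd) summaries can be compared against raw values.
    """
    a, b = _summarize(values_a), _summarize(values_b)
    if a.n < 2 or b.n < 2:
        raise DomainError("each group needs at least 2 values")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se2 = sp2 * (1 / a.n + 1 / b.n)
    if se2 == 0:
        raise DegenerateDataError("zero pooled variance; t test undefined")
    t = (a.mean - b.mean) / np.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), int(df), p


def compute_ppv(
    tau: float,
    pos_values: Sequence[float],
    neg_values: Sequence[float],
) -> float:
    """Positive predictive value at threshold tau.

    PPV = TP / (TP + FP) with TP the number of tumour-bearing patients
    at nThI >= tau and FP the number of tumour-free patients at
    nThI >= tau.  Comparisons are inclusive, so a patient's own nThI
    used as tau always contributes a true positive.
    """
    pos = np.asarray(list(pos_values), dtype=np.float64)
    neg = np.asarray(list(neg_values), dtype=np.float64)
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("both value lists must be nonempty")
    tp = int((pos >= tau).sum())
    fp = int((neg >= tau).sum())
    if tp + fp == 0:
        raise UndefinedPPVError(f"no patient reaches nThI >= {tau:g}")
    return tp / (tp + fp)


def assign_band(
    nthi: float,
    low_edge: float = LOW_EDGE_DEFAULT,
    high_edge: float = HIGH_EDGE_DEFAULT,
) -> str:
    """Decision band for one nThI: 'low', 'indeterminate' or 'high'."""
    if not np.isfinite(nthi):
        raise DomainError(f"nThI must be finite, got {nthi}")
    if nthi < low_edge:
        return "low"
    if nthi < high_edge:
        return "indeterminate"
    return "high"
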