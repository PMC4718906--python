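"""Published benchmark cohort values for the nNUFTI method.

The method was benchmarked on a retrospective cohort of patients whose
somatostatin-analogue SPECT was read as negative for liver tumours, then
followed for three years with CT, MRI, ultrasound and PET/CT.  Forty
patients stayed tumour-free (the radtech-negative group, published only
as summary statistics); thirteen were later diagnosed with liver tumours
(the radtech-positive group, published per patient with their nThI and
the positive predictive value of that nThI used as a threshold).

These printed values are shipped here so the decision statistics can be
exercised and reproduced without access to patient images.
"""

from __future__ import annotations

import pandas as pd

from .classification import GroupSummary

#: radtech(+) follow-up group: patient id, nThI, printed PPV at that nThI
_FOLLOWUP_ROWS = [
    ("42F", 0.748, 1.00),
    ("32F", 0.743, 1.00),
    ("41F", 0.718, 1.00),
    ("55F", 0.697, 1.00),
    ("84M", 0.659, 0.50),
    ("25M", 0.655, 0.50),
    ("43M", 0.642, 0.35),
    ("90M", 0.641, 0.38),
    ("30F", 0.637, 0.38),
    ("109F", 0.621, 0.32),
    ("111F", 0.619, 0.33),
    ("104F", 0.599, 0.27),
    ("103M", 0.581, 0.26),
]

#: tumour-free (radtech-negative) group, published as summary statistics
RADTECH_NEG_SUMMARY = GroupSummary(n=40, mean=0.623, sd=0.032)

#: largest nThI observed in the radtech-negative group
RADTECH_NEG_MAX_NTHI = 0.68

#: scan-positive reference group (clear tumour burden), summary statistics
OCTREOTIDE_POS_SUMMARY = GroupSummary(n=10, mean=0.84, sd=0.088)


def followup_cohort() -> pd.DataFrame:
    """Follow-up-confirmed tumour cohort as a DataFrame (patient_id, nthi, ppv)."""
    return pd.DataFrame(_FOLLOWUP_ROWS, columns=["patient_id", "nthi", "ppv"])
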