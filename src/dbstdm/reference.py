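"""The published nine-patient trough cohort used as the worked example.

Trough DBS concentrations of lamotrigine (LTG) and its N2-glucuronide
(LTG-N2-GLU) in nine adult patients on stable therapy, 100-400 mg/day, sampled
at steady state immediately before the morning dose. Subjects 1 and 4 are the
cohort's metabolic outliers (UGT inhibition and phenytoin-induced UGT activity,
respectively).
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # subject, dose mg/day, LTG µg/mL, LTG-N2-GLU µg/mL
    ("1", 100, 4.61, 0.37),
    ("2", 200, 3.14, 1.41),
    ("3", 250, 6.42, 1.63),
    ("4", 400, 3.50, 2.14),
    ("5", 100, 1.83, 0.60),
    ("6", 300, 6.09, 2.10),
    ("7", 100, 1.84, 0.31),
    ("8", 250, 3.48, 1.09),
    ("9", 400, 9.39, 3.22),
]


def trough_cohort() -> pd.DataFrame:
    """Return the reference trough table as a fresh DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["subject_id", "dose", "parent_conc", "metabolite_conc"]
    )
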