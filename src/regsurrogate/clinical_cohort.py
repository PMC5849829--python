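"""Published per-subject values of the 13-patient clinical validation cohort.

Two tables are carried as plain data so their summary statistics can be
recomputed: (1) subject descriptives and per-fiducial residual distances of
the planning-MRI to planning-CT rigid fiducial alignment; (2) expanded-ROI
normalized-mutual-information and Pearson scores of rigid versus deformable
registration of the diagnostic MRI.  A missing fiducial (one marker not
localizable) is an absent value, never a sentinel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["subject_table", "similarity_table", "fiducial_reports"]

# id, age, prostate volume mL, local alignment count, bladder (diag, plan) mL,
# rectum (diag, plan) mL, four per-fiducial residuals (mm; None = missing marker)
_SUBJECTS = [
    ("Subject #1", 73, 42.3, 29, 268, 124, 29, 27, (1.83, 2.19, 1.10, 0.83)),
    ("Subject #2", 67, 100.4, 41, 103, 226, 26, 20, (1.58, 0.37, 0.43, 0.66)),
    ("Subject #3", 68, 58.0, 82, 79, 427, 37, 54, (0.44, 1.10, 1.59, 0.70)),
    ("Subject #4", 71, 56.1, 53, 86, 217, 106, 39, (0.88, 0.72, 1.23, 0.40)),
    ("Subject #5", 72, 44.4, 37, 128, 94, 23, 26, (0.82, 0.42, 0.81, 0.83)),
    ("Subject #6", 73, 84.2, 38, 180, 129, 66, 60, (2.06, 1.12, 2.81, 1.56)),
    ("Subject #7", 62, 32.0, 41, 68, 52, 41, 36, (0.00, 0.11, 0.35, 0.42)),
    ("Subject #8", 86, 25.5, 44, 145, 140, 32, 36, (0.74, 0.39, 1.09, None)),
    ("Subject #9", 67, 94.8, 46, 274, 299, 39, 39, (0.87, 0.26, 1.02, 0.88)),
    ("Subject #10", 76, 35.1, 53, 119, 417, 45, 43, (0.58, 0.46, 0.45, None)),
    ("Subject #11", 64, 26.1, 41, 52, 109, 41, 36, (0.19, 0.20, 1.52, 0.56)),
    ("Subject #12", 69, 29.5, 93, 118, 174, 46, 39, (0.32, 0.61, 0.45, 0.24)),
    ("Subject #13", 67, 30.3, 80, 140, 230, 46, 45, (0.30, 0.22, 0.20, 0.19)),
]

# expanded-ROI scores: (id, NMI rigid, NMI deform, Pearson rigid, Pearson deform)
_SIMILARITY = [
    ("Subject #1", 0.076, 0.095, 0.609, 0.682),
    ("Subject #2", 0.065, 0.069, 0.609, 0.624),
    ("Subject #3", 0.041, 0.050, 0.422, 0.459),
    ("Subject #4", 0.070, 0.088, 0.541, 0.600),
    ("Subject #5", 0.035, 0.045, 0.436, 0.381),
    ("Subject #6", 0.101, 0.116, 0.664, 0.719),
    ("Subject #7", 0.152, 0.150, 0.777, 0.801),
    ("Subject #8", 0.081, 0.099, 0.641, 0.731),
    ("Subject #9", 0.056, 0.069, 0.603, 0.656),
    ("Subject #10", 0.101, 0.121, 0.696, 0.763),
    ("Subject #11", 0.058, 0.055, 0.572, 0.565),
    ("Subject #12", 0.051, 0.122, 0.516, 0.735),
    ("Subject #13", 0.052, 0.121, 0.493, 0.748),
]


def subject_table() -> pd.DataFrame:
    """Subject descriptives plus per-fiducial residual columns (NaN = missing)."""
    rows = []
    for sid, age, pvol, nalign, bd, bp, rd, rp, res in _SUBJECTS:
        rows.append(
            {
                "subject_id": sid,
                "age": age,
                "prostate_volume_ml": pvol,
                "n_local_alignments": nalign,
                "bladder_diagnostic_ml": bd,
                "bladder_plan_ml": bp,
                "rectum_diagnostic_ml": rd,
                "rectum_plan_ml": rp,
                **{
                    f"fiducial_{i+1}_mm": (np.nan if r is None else r)
                    for i, r in enumerate(res)
                },
            }
        )
    return pd.DataFrame(rows)


def similarity_table() -> pd.DataFrame:
    """Expanded-ROI NMI and Pearson scores, rigid vs deformable, per subject."""
    return pd.DataFrame(
        _SIMILARITY,
        columns=["subject_id", "nmi_rigid", "nmi_deform", "pearson_rigid", "pearson_deform"],
    )


def fiducial_reports() -> list:
    """Per-subject ResidualReport objects built from the per-fiducial columns."""
    from .fiducial_registration import ResidualReport

    reports = []
    for sid, *_rest, res in [(s[0],) + s[1:] for s in _SUBJECTS]:
        pts = [(f"F{i+1}", r) for i, r in enumerate(res) if r is not None]
        reports.append(ResidualReport(sid, pts))
    return reports
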