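"""Published per-patient MAE table for the clinical 13-patient test cohort.

These are the reported per-patient MAE values (HU) — all masked voxels,
air, soft tissue and bone — for the full-scale network evaluated on 13
held-out clinical head patients.  The rows serve as input data for
validating the cohort summary statistics (mean, population standard
deviation, minimum, maximum): feeding them to
:func:`mrct.evaluation.summarize_cohort` must reproduce the published
summary rows to two decimals.
"""

from __future__ import annotations

from .evaluation import PatientMAEReport

_ROWS: list[tuple[str, float, float, float, float]] = [
    ("Patient 1", 73.80, 213.5, 13.97, 170.02),
    ("Patient 2", 76.88, 227.54, 14.39, 182.83),
    ("Patient 3", 88.31, 234.27, 17.11, 217.24),
    ("Patient 4", 77.53, 229.34, 17.87, 174.08),
    ("Patient 5", 99.28, 271.21, 17.8, 227.25),
    ("Patient 6", 69.17, 220.9, 15.11, 169.53),
    ("Patient 7", 118.14, 293.7, 26.5, 302.54),
    ("Patient 8", 83.20, 218.69, 23.51, 188.98),
    ("Patient 9", 58.13, 197.96, 15.56, 154.99),
    ("Patient 10", 71.45, 216.57, 17.15, 181.51),
    ("Patient 11", 75.66, 200.88, 16.7, 158.48),
    ("Patient 12", 89.04, 274.47, 16.97, 214.17),
    ("Patient 13", 72.66, 239.77, 16.29, 169.13),
]

#: Published cohort summary rows (mean / population std / min / max), HU,
#: in column order (all, air, tissue, bone).
PUBLISHED_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "Mean": (81.02, 233.75, 17.61, 193.13),
    "Standard deviation": (14.60, 28.02, 3.41, 38.33),
    "Minimum": (58.13, 197.96, 13.97, 154.99),
    "Maximum": (118.14, 293.7, 26.5, 302.54),
}


def clinical_test_reports() -> list[PatientMAEReport]:
    """The 13 published per-patient rows as report objects (no voxel counts)."""
    return [
        PatientMAEReport(patient=p, mae_all=a, mae_air=air, mae_tissue=t, mae_bone=b)
        for p, a, air, t, b in _ROWS
    ]
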