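"""Per-tissue MAE evaluation of synthetic CT against ground truth.

A synthetic CT volume is compared with the true CT inside a head mask, both
voxelwise and restricted to the voxels the ground-truth CT assigns to each
Hounsfield window (air / soft tissue / bone).  Per-patient reports are
aggregated into cohort summary statistics (mean, population standard
deviation, minimum, maximum).

Regions are defined from the ground-truth CT, not the prediction, so the
metric does not depend on where the model thinks tissue boundaries are.
The exact decomposition identity holds: the all-voxel MAE equals the
voxel-count-weighted mean of the three regional MAEs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .hu_windows import TissueWindows

REPORT_COLUMNS = ("mae_all", "mae_air", "mae_tissue", "mae_bone")
SUMMARY_ROWS = ("Mean", "Standard deviation", "Minimum", "Maximum")


@dataclass(frozen=True)
class PatientMAEReport:
    """Per-patient MAE (HU) for all masked voxels and per tissue region.

    Voxel counts are per region; an empty region carries count 0 and MAE
    ``nan`` (undefined, never reported as 0).  Counts may be ``None`` for
    externally reported rows where they are unknown.
    """

    patient: str
    mae_all: float
    mae_air: float
    mae_tissue: float
    mae_bone: float
    n_all: int | None = None
    n_air: int | None = None
    n_tissue: int | None = None
    n_bone: int | None = None

    def values(self) -> tuple[float, float, float, float]:
        return (self.mae_all, self.mae_air, self.mae_tissue, self.mae_bone)


@dataclass
class CohortSummary:
    """Cohort-level statistics: one row each of Mean / Standard deviation /
    Minimum / Maximum, columns as in a per-patient report table.  The
    standard deviation is the population form (divisor n)."""

    stats: pd.DataFrame

    def __getitem__(self, key: tuple[str, str]) -> float:
        row, col = key
        return float(self.stats.loc[row, col])


def make_head_mask(
    mr: np.ndarray,
    closing_radius: int = 3,
    threshold: float | None = None,
) -> np.ndarray:
    """Automatic head mask from MR intensity.

    Otsu threshold (unless ``threshold`` is given) -> morphological closing
    -> largest connected component -> hole filling, applied per 2-D slice.
    Dark interior structures (bone, sinus air) are recovered by the hole
    filling as long as the scalp forms a closed bright rim.
    """
    mr = np.asarray(mr)
    if not np.any(mr > 0):
        raise ValueError("cannot build a head mask from an all-zero MR image")
    if mr.ndim == 2:
        return _mask_slice(mr, closing_radius, threshold)
    if mr.ndim == 3:
        return np.stack([_mask_slice(s, closing_radius, threshold) for s in mr])
    raise ValueError(f"expected a 2-D or 3-D MR array, got ndim={mr.ndim}")


def _mask_slice(mr: np.ndarray, closing_radius: int, threshold: float | None) -> np.ndarray:
    thr = filters.threshold_otsu(mr) if threshold is None else threshold
    fg = mr > thr
    if not fg.any():
        raise ValueError("head mask is empty after thresholding")
    fg = morphology.closing(fg, morphology.disk(closing_radius))
    lab = measure.label(fg)
    if lab.max() == 0:
        raise ValueError("head mask is empty after morphology")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(lab == largest)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


def evaluate_patient(
    mrct: np.ndarray,
    ct: np.ndarray,
    mask: np.ndarray,
    windows: TissueWindows = TissueWindows(),
    patient: str = "patient",
) -> PatientMAEReport:
    """MAE between synthetic and true CT within the head mask, per region.

    Regions are the ground-truth CT's window memberships restricted to the
    mask.  Region voxel counts always sum to the mask size.
    """
    mrct, ct, mask = np.asarray(mrct), np.asarray(ct), np.asarray(mask, dtype=bool)
    if not (mrct.shape == ct.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: mrct {mrct.shape}, ct {ct.shape}, mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("head mask is empty")
    err = np.abs(mrct.astype(np.float64) - ct.astype(np.float64))
    region_masks = [m & mask for m in windows.masks(ct)]
    maes, counts = [], []
    for rm in region_masks:
        n = int(rm.sum())
        counts.append(n)
        maes.append(float(err[rm].mean()) if n else float("nan"))
    return PatientMAEReport(
        patient=patient,
        mae_all=float(err[mask].mean()),
        mae_air=maes[0], mae_tissue=maes[1], mae_bone=maes[2],
        n_all=int(mask.sum()), n_air=counts[0], n_tissue=counts[1], n_bone=counts[2],
    )


def reports_frame(reports: list[PatientMAEReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.patient, *r.values()] for r in reports],
        columns=["patient", *REPORT_COLUMNS],
    ).set_index("patient")


def summarize_cohort(reports: list[PatientMAEReport]) -> CohortSummary:
    """Column-wise Mean / population Std / Min / Max over patient reports."""
    if not reports:
        raise ValueError("cannot summarize an empty list of reports")
    df = reports_frame(reports)
    stats = pd.DataFrame(
        [df.mean(), df.std(ddof=0), df.min(), df.max()],
        index=list(SUMMARY_ROWS),
    )
    return CohortSummary(stats=stats)


def write_report(
    summary: CohortSummary, reports: list[PatientMAEReport], path: str | Path
) -> None:
    """Write per-patient rows plus the four summary rows as CSV, and a JSON
    sidecar with the same content plus voxel counts."""
    path = Path(path)
    df = reports_frame(reports)
    out = pd.concat([df, summary.stats])
    out.index.name = "patient"
    try:
        out.to_csv(path, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    sidecar = {
        "patients": [r.__dict__ for r in reports],
        "summary": {row: summary.stats.loc[row].to_dict() for row in SUMMARY_ROWS},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_report(path: str | Path) -> tuple[list[PatientMAEReport], CohortSummary | None]:
    """Read back a CSV written by :func:`write_report` (or any CSV with a
    patient column plus the four MAE columns)."""
    df = pd.read_csv(path, index_col=0)
    summary_rows = df.index.intersection(SUMMARY_ROWS)
    patients = df.drop(index=summary_rows)
    reports = [
        PatientMAEReport(patient=str(idx), **{c: float(row[c]) for c in REPORT_COLUMNS})
        for idx, row in patients.iterrows()
    ]
    summary = None
    if len(summary_rows) == len(SUMMARY_ROWS):
        summary = CohortSummary(stats=df.loc[list(SUMMARY_ROWS), list(REPORT_COLUMNS)])
    return reports, summary
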