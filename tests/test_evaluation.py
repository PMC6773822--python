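"""Per-tissue MAE evaluation, cohort summaries against the published table,
head masking, and report round trips."""

import numpy as np
import pandas as pd
import pytest

from mrct.evaluation import (
    PatientMAEReport,
    dice,
    evaluate_patient,
    make_head_mask,
    read_report,
    reports_frame,
    summarize_cohort,
    write_report,
)
from mrct.hu_windows import TissueWindows
from mrct.reference import PUBLISHED_SUMMARY, clinical_test_reports

WINDOWS = TissueWindows()


def _random_case(rng, shape=(20, 20)):
    ct = rng.uniform(-1024, 2000, shape)
    mrct = ct + rng.normal(0, 100, shape)
    mask = rng.random(shape) < 0.7
    mask[0, 0] = True  # never empty
    return mrct, ct, mask


def test_identical_and_shifted_inputs(rng):
    _, ct, mask = _random_case(rng)
    r = evaluate_patient(ct, ct, mask, WINDOWS)
    assert r.values() == (0, 0, 0, 0) or all(
        v == 0 or np.isnan(v) for v in r.values()
    )
    r10 = evaluate_patient(ct + 10.0, ct, mask, WINDOWS)
    for v in r10.values():
        assert np.isnan(v) or v == pytest.approx(10.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_region_mae_matches_voxel_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    mrct, ct, mask = _random_case(rng, (15, 15))
    r = evaluate_patient(mrct, ct, mask, WINDOWS)
    sums = {"all": [0.0, 0], "air": [0.0, 0], "tissue": [0.0, 0], "bone": [0.0, 0]}
    for i in range(15):
        for j in range(15):
            if not mask[i, j]:
                continue
            err = abs(mrct[i, j] - ct[i, j])
            sums["all"][0] += err
            sums["all"][1] += 1
            region = WINDOWS.region_of(ct[i, j])
            sums[region][0] += err
            sums[region][1] += 1
    for region in sums:
        expect = sums[region][0] / sums[region][1] if sums[region][1] else np.nan
        got = getattr(r, f"mae_{region}")
        n_got = getattr(r, f"n_{region}")
        assert n_got == sums[region][1]
        if sums[region][1]:
            assert got == pytest.approx(expect, abs=1e-9)
        else:
            assert np.isnan(got)


def test_region_decomposition_identity(rng):
    """Counts partition the mask and the all-voxel MAE is exactly the
    count-weighted mean of the regional MAEs."""
    mrct, ct, mask = _random_case(rng)
    r = evaluate_patient(mrct, ct, mask, WINDOWS)
    assert r.n_air + r.n_tissue + r.n_bone == r.n_all == mask.sum()
    parts = [(r.n_air, r.mae_air), (r.n_tissue, r.mae_tissue), (r.n_bone, r.mae_bone)]
    weighted = sum(n * m for n, m in parts if n) / r.n_all
    assert r.mae_all == pytest.approx(weighted, rel=1e-12)


def test_empty_region_reports_nan_not_zero():
    ct = np.full((5, 5), 50.0)  # all soft tissue
    r = evaluate_patient(ct + 5, ct, np.ones_like(ct, dtype=bool), WINDOWS)
    assert np.isnan(r.mae_air) and r.n_air == 0
    assert np.isnan(r.mae_bone) and r.n_bone == 0
    assert r.mae_tissue == pytest.approx(5.0)


def test_degenerate_inputs_rejected():
    ct = np.zeros((4, 4))
    with pytest.raises(ValueError, match="empty"):
        evaluate_patient(ct, ct, np.zeros_like(ct, dtype=bool), WINDOWS)
    with pytest.raises(ValueError, match="shape mismatch"):
        evaluate_patient(ct, ct[:2], np.ones_like(ct, dtype=bool), WINDOWS)
    with pytest.raises(ValueError):
        summarize_cohort([])


def test_published_cohort_summary_reproduced():
    """Feeding the 13 published per-patient rows to summarize_cohort
    reproduces the published Mean/Std/Min/Max rows to 2 decimals (std in
    population, divisor-n form)."""
    summary = summarize_cohort(clinical_test_reports())
    cols = ("mae_all", "mae_air", "mae_tissue", "mae_bone")
    for row, expected in PUBLISHED_SUMMARY.items():
        for col, val in zip(cols, expected):
            assert summary[row, col] == pytest.approx(val, abs=0.005), (row, col)


def test_single_report_summary():
    r = PatientMAEReport("p", 10.0, 20.0, 5.0, 30.0)
    s = summarize_cohort([r])
    assert s["Mean", "mae_all"] == s["Minimum", "mae_all"] == s["Maximum", "mae_all"] == 10.0
    assert s["Standard deviation", "mae_all"] == 0.0


def test_report_roundtrip_and_schema(tmp_path):
    reports = clinical_test_reports()
    summary = summarize_cohort(reports)
    path = tmp_path / "report.csv"
    write_report(summary, reports, path)
    df = pd.read_csv(path, index_col=0)
    assert list(df.columns) == ["mae_all", "mae_air", "mae_tissue", "mae_bone"]
    assert list(df.index[-4:]) == ["Mean", "Standard deviation", "Minimum", "Maximum"]
    back, back_summary = read_report(path)
    for a, b in zip(reports, back):
        assert a.values() == pytest.approx(b.values())
    assert back_summary is not None
    assert back_summary["Mean", "mae_tissue"] == pytest.approx(
        summary["Mean", "mae_tissue"]
    )
    assert (tmp_path / "report.json").exists()


def test_head_mask_recovers_analytic_mask(noiseless_patient):
    p = noiseless_patient
    s = p.n_slices // 2
    computed = make_head_mask(p.mr[s])
    assert dice(computed, p.mask[s]) > 0.95
    # idempotent on the already-masked image
    again = make_head_mask(p.mr[s] * computed)
    assert np.array_equal(again, computed)


def test_head_mask_noisy_volume(noisy_patient):
    p = noisy_patient
    masks = make_head_mask(np.clip(p.mr, 0, None))
    assert masks.shape == p.mr.shape
    d = np.mean([dice(masks[i], p.mask[i]) for i in range(p.n_slices)])
    assert d > 0.9


def test_head_mask_rejects_empty_image():
    with pytest.raises(ValueError, match="all-zero"):
        make_head_mask(np.zeros((10, 10)))


def test_reports_frame_columns():
    df = reports_frame(clinical_test_reports())
    assert df.shape == (13, 4)
    assert df.index[0] == "Patient 1"
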