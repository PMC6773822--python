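"""Folds, augmentation alignment, fraction arithmetic, the training loop's
bookkeeping, and prediction plumbing."""

from dataclasses import replace

import numpy as np
import pytest

from mrct.hu_windows import NormalizationSpec
from mrct.phantom import PhantomSpec, generate_cohort
from mrct.training import (
    DESK_TRAIN,
    SlicePairs,
    TrainConfig,
    augment,
    constant_baseline_mae,
    make_folds,
    predict,
    predict_volume,
    train,
)
from mrct.unet import NetworkConfig, build_network, initialize

IDS_47 = [f"pat{i:02d}" for i in range(47)]


def test_fold_sizes_for_47_patients():
    """47 patients into 5 folds gives sizes {10,10,9,9,9}."""
    folds = make_folds(IDS_47, 5, seed=0)
    assert sorted(len(f) for f in folds) == [9, 9, 9, 10, 10]


@pytest.mark.parametrize("k", [2, 3, 5])
def test_folds_partition_patients_exactly_once(k):
    folds = make_folds(IDS_47, k, seed=3)
    seen = [p for f in folds for p in f]
    assert sorted(seen) == sorted(IDS_47)


def test_folds_deterministic_and_validated():
    assert make_folds(IDS_47, 5, seed=9) == make_folds(IDS_47, 5, seed=9)
    assert make_folds(IDS_47, 5, seed=9) != make_folds(IDS_47, 5, seed=10)
    with pytest.raises(ValueError, match="cannot make"):
        make_folds(IDS_47[:3], 5, seed=0)


def _pair(rng, n=32):
    mr = rng.uniform(0, 100, (n, n)).astype(np.float32)
    ct = rng.uniform(-1000, 1500, (n, n)).astype(np.float32)
    return mr, ct


def test_augment_identity_when_disabled(rng):
    mr, ct = _pair(rng)
    cfg = TrainConfig(rot90_prob=0.0, crop_range=(1.0, 1.0))
    mr2, ct2 = augment(mr, ct, rng, cfg)
    assert np.array_equal(mr2, mr) and np.array_equal(ct2, ct)


def test_augment_rotation_is_shared_lossless_grid_rotation(rng):
    """With rotation forced and cropping off, the result is np.rot90 by the
    same k for MR, CT and a co-transformed label map; per-label pixel counts
    are unchanged (rotation is a permutation)."""
    mr, ct = _pair(rng)
    labels = (rng.integers(0, 5, mr.shape)).astype(np.int8)
    cfg = TrainConfig(rot90_prob=1.0, crop_range=(1.0, 1.0))
    mr2, ct2, lab2 = augment(mr, ct, rng, cfg, labels=labels)
    ks = [k for k in (1, 2, 3) if np.array_equal(mr2, np.rot90(mr, k))]
    assert len(ks) == 1
    k = ks[0]
    assert np.array_equal(ct2, np.rot90(ct, k))
    assert np.array_equal(lab2, np.rot90(labels, k))
    assert np.array_equal(np.bincount(lab2.ravel()), np.bincount(labels.ravel()))
    # four quarter turns compose to the identity
    assert np.array_equal(np.rot90(mr, 4), mr)


def test_augment_crop_preserves_shape_and_alignment(rng):
    mr, ct = _pair(rng)
    labels = np.zeros(mr.shape, dtype=np.int8)
    labels[8:24, 8:24] = 1
    cfg = TrainConfig(rot90_prob=0.0, crop_range=(0.6, 0.6))
    mr2, ct2, lab2 = augment(mr, ct, rng, cfg, labels=labels)
    assert mr2.shape == mr.shape and ct2.shape == ct.shape and lab2.shape == labels.shape
    assert set(np.unique(lab2)) <= {0, 1}  # nearest resampling invents no labels


def test_take_fraction_floor_arithmetic(rng):
    pairs = SlicePairs(
        mr=np.zeros((57, 4, 4), dtype=np.float32),
        ct=np.zeros((57, 4, 4), dtype=np.float32),
        patient_index=np.zeros(57, dtype=np.int64),
        patient_ids=["a"],
    )
    assert len(pairs.take_fraction(0.1, rng)) == 5
    assert len(pairs.take_fraction(1.0, rng)) == 57
    with pytest.raises(ValueError):
        pairs.take_fraction(0.001, rng)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(folds=1)
    with pytest.raises(ValueError):
        TrainConfig(fraction=0.0)


@pytest.fixture(scope="module")
def tiny_run(tmp_path_factory):
    spec = PhantomSpec(slices_per_patient=4).noiseless()
    cohort = generate_cohort(spec, 3, master_seed=5)
    net = initialize(build_network(NetworkConfig(depth=2, base_filters=4)), seed=0)
    cfg = replace(DESK_TRAIN, epochs=3, batch_size=4)
    run_dir = tmp_path_factory.mktemp("run")
    rec = train(
        net,
        SlicePairs.from_cohort(cohort[:2]),
        SlicePairs.from_cohort(cohort[2:]),
        cfg,
        run_dir=run_dir,
    )
    return net, rec, run_dir, cohort


def test_train_records_and_checkpoints(tiny_run):
    net, rec, run_dir, _ = tiny_run
    assert len(rec.epochs) == 3
    assert {"epoch", "train_loss", "val_loss"} <= set(rec.epochs[0])
    assert 0 <= rec.best_epoch < 3
    assert (run_dir / "loss.csv").exists()
    assert (run_dir / "final.npz").exists() and (run_dir / "best.npz").exists()
    assert rec.loss_curve().shape == (3, 3)


def test_train_loss_decreases(tiny_run):
    _, rec, _, _ = tiny_run
    assert rec.epochs[-1]["train_loss"] < rec.epochs[0]["train_loss"]


def test_predict_shapes_and_channel_sum(tiny_run):
    net, _, _, cohort = tiny_run
    p = cohort[2]
    # non-grid-divisible input exercises the pad/crop round trip
    mr = p.mr[0][:50, :50]
    hu, stack = predict(net, mr)
    assert hu.shape == mr.shape == stack.shape
    assert not stack.normalized
    assert np.allclose(hu, stack.air + stack.tissue + stack.bone, atol=1e-5)
    vol = predict_volume(net, p.mr)
    assert vol.shape == p.mr.shape


@pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
def test_nan_loss_aborts_with_diagnostic(tiny_run):
    _, _, _, cohort = tiny_run
    net = initialize(build_network(NetworkConfig(depth=1, base_filters=2)), seed=0)
    cfg = replace(DESK_TRAIN, epochs=4, batch_size=4, lr=1e12)
    with pytest.raises(FloatingPointError, match="epoch"):
        train(
            net,
            SlicePairs.from_cohort(cohort[:2]),
            SlicePairs.from_cohort(cohort[2:]),
            cfg,
        )


def test_cross_validate_partitions_patients():
    """Every patient validates exactly once across folds; one record per
    fold is returned."""
    from mrct.training import cross_validate

    spec = PhantomSpec(slices_per_patient=3).noiseless()
    cohort = generate_cohort(spec, 4, master_seed=2)
    cfg = replace(DESK_TRAIN, epochs=1, batch_size=4, folds=2)
    results = cross_validate(
        cohort, lambda: build_network(NetworkConfig(depth=2, base_filters=2)), cfg
    )
    assert len(results) == 2
    val_ids = sorted(pid for ids, _ in results for pid in ids)
    assert val_ids == sorted(p.patient_id for p in cohort)
    assert all(len(rec.epochs) == 1 for _, rec in results)


def test_training_is_reproducible_from_seed():
    """Same config and seed give identical per-epoch losses (up to exact
    floating-point reproduction on one device)."""
    spec = PhantomSpec(slices_per_patient=4).noiseless()
    cohort = generate_cohort(spec, 3, master_seed=5)
    cfg = replace(DESK_TRAIN, epochs=2, batch_size=4, seed=9)

    def one_run():
        net = initialize(build_network(NetworkConfig(depth=2, base_filters=4)), seed=1)
        return train(
            net,
            SlicePairs.from_cohort(cohort[:2]),
            SlicePairs.from_cohort(cohort[2:]),
            cfg,
        )

    a, b = one_run(), one_run()
    for ea, eb in zip(a.epochs, b.epochs):
        assert ea["train_loss"] == pytest.approx(eb["train_loss"], abs=1e-6)
        assert ea["val_loss"] == pytest.approx(eb["val_loss"], abs=1e-6)


def test_constant_baseline_is_median_mae():
    spec = PhantomSpec(slices_per_patient=2).noiseless()
    cohort = generate_cohort(spec, 2, master_seed=1)
    base = constant_baseline_mae(cohort, region="tissue")
    vals = []
    for p in cohort:
        from mrct.hu_windows import TissueWindows

        rm = TissueWindows().masks(p.ct)[1] & p.mask
        vals.append(p.ct[rm])
    vals = np.concatenate(vals)
    assert base == pytest.approx(np.abs(vals - np.median(vals)).mean())
    assert base > 0
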