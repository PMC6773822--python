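"""Canonical desk-scale studies: small, CPU-friendly end-to-end runs.

The clinical study conditions (60 patients, 256-grade sagittal grids, 150
epochs) are far beyond a single-CPU test budget, so the package defines one
fixed desk-scale counterpart and uses it everywhere results are quoted: a
10-patient noiseless phantom cohort of 48x48 sagittal slices (20 per
patient, about 200 in total), the 3-level / 8-filter network profile, and a
short Adam schedule.  Keeping the study definition in one place means the
test suite and the reproduction script exercise exactly the same
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hu_windows import NormalizationSpec, TissueWindows
from .phantom import PhantomSpec, generate_cohort
from .training import (
    DESK_TRAIN,
    SlicePairs,
    TrainConfig,
    channel_mae,
    constant_baseline_mae,
    constant_channel_baseline_mae,
    evaluate_model,
    subsampling_experiment,
    train,
)
from .unet import DESK_PROFILE, build_network, initialize

#: Phantom conditions for desk-scale studies: 48x48 noiseless slices.
DESK_PHANTOM = PhantomSpec(size=48, slices_per_patient=20).noiseless()
DESK_COHORT_PATIENTS = 10
DESK_VAL_PATIENTS = 2


def _seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass
class DeskLearningResult:
    """Held-out desk-study metrics, all in HU within the head mask.

    ``tissue_mae_hu`` is the recombined-image MAE over soft-tissue-region
    voxels; ``tissue_channel_mae_hu`` is the MAE of the predicted tissue
    channel against the split ground-truth channel over all masked voxels.
    Each comes with the best-constant-prediction baseline for the same
    quantity (the analytic median-constant floor a useful model must beat).
    """

    tissue_mae_hu: float
    tissue_baseline_mae_hu: float
    tissue_channel_mae_hu: float
    tissue_channel_baseline_mae_hu: float
    mae_all_hu: float
    best_val_loss: float
    n_train_slices: int


def desk_learning_study(
    seed: int,
    epochs: int | None = None,
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
) -> DeskLearningResult:
    """Train the desk profile on the canonical noiseless cohort and report
    held-out per-tissue MAE against the best-constant baseline.

    The cohort, network initialization and batch order all derive from
    ``seed``; two patients are held out for validation/evaluation.
    """
    cohort_seed, init_seed, batch_seed, _ = _seeds(seed)
    cohort = generate_cohort(DESK_PHANTOM, DESK_COHORT_PATIENTS, cohort_seed)
    train_p = cohort[:-DESK_VAL_PATIENTS]
    val_p = cohort[-DESK_VAL_PATIENTS:]
    cfg = replace(DESK_TRAIN, seed=batch_seed)
    if epochs is not None:
        cfg = replace(cfg, epochs=epochs)
    net = initialize(build_network(DESK_PROFILE), seed=init_seed)
    rec = train(
        net, SlicePairs.from_cohort(train_p), SlicePairs.from_cohort(val_p),
        cfg, norm, windows,
    )
    reports = evaluate_model(net, val_p, norm, windows)
    return DeskLearningResult(
        tissue_mae_hu=float(np.mean([r.mae_tissue for r in reports])),
        tissue_baseline_mae_hu=constant_baseline_mae(val_p, windows, "tissue"),
        tissue_channel_mae_hu=channel_mae(net, val_p, norm, windows, "tissue"),
        tissue_channel_baseline_mae_hu=constant_channel_baseline_mae(
            val_p, windows, "tissue"
        ),
        mae_all_hu=float(np.mean([r.mae_all for r in reports])),
        best_val_loss=rec.best_val_loss,
        n_train_slices=sum(p.n_slices for p in train_p),
    )


def desk_subsampling_study(
    seed: int,
    fractions: tuple[float, ...] = (0.1, 1.0),
    epochs: int | None = None,
    norm: NormalizationSpec = NormalizationSpec(),
):
    """Desk-scale analogue of the training-data-volume experiment.

    Trains one desk model per training fraction from the same
    initialization and evaluates each on the same two held-out test
    patients; returns the tidy per-(fraction, region) MAE table.
    """
    cohort_seed, init_seed, batch_seed, _ = _seeds(seed)
    cohort = generate_cohort(DESK_PHANTOM, DESK_COHORT_PATIENTS, cohort_seed)
    train_p = cohort[:-DESK_VAL_PATIENTS]
    test_p = cohort[-DESK_VAL_PATIENTS:]
    cfg = replace(DESK_TRAIN, seed=batch_seed)
    if epochs is not None:
        cfg = replace(cfg, epochs=epochs)
    return subsampling_experiment(
        train_p, test_p, fractions, lambda: build_network(DESK_PROFILE),
        cfg, norm, init_seed=init_seed,
    )
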