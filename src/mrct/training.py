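"""Training loop, augmentation, cross-validation folds and the
data-subsampling experiment.

Training minimizes the channel-summed MAE+MSE objective with Adam on
mini-batches of aligned (MR, CT) sagittal slices.  Augmentation (optional
90-degree grid rotations and random crops resized back to the grid) is
applied to the raw MR/CT pair *before* the CT is split into tissue
channels, so interpolation can never create out-of-window channel values.
Cross-validation folds are split by patient, never by slice, to avoid
leaking near-duplicate neighboring slices into validation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from . import hu_windows as hw
from .hu_windows import ChannelStack, NormalizationSpec, TissueWindows, split_channels
from .objective import batch_loss_and_grad
from .phantom import PhantomPatient
from .unet import UNet, initialize, pad_to_grid, save_checkpoint
from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and augmentation settings.

    ``fraction`` subsamples the training slices (for the data-volume
    experiment); ``rot90_prob`` is the probability of a random 90-degree
    grid rotation; ``crop_range`` bounds the per-axis random crop fraction
    (``(1.0, 1.0)`` disables cropping).
    """

    batch_size: int = 32
    epochs: int = 150
    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    rot90_prob: float = 0.5
    crop_range: tuple[float, float] = (0.8, 1.0)
    folds: int = 5
    fraction: float = 1.0
    seed: int = 0
    channel_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # one-step learning-rate decay: multiply lr by decay_factor after
    # decay_at_frac of the epochs (factor 1.0 disables it)
    decay_at_frac: float = 0.75
    decay_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


#: Full-scale settings (mini-batches of 32, 150 epochs, 5 folds).
FULL_TRAIN = TrainConfig()
#: Small CPU-friendly settings used by the test suite: no augmentation,
#: short schedule with one lr step-down, smaller batches and a higher
#: learning rate suited to the small network.
DESK_TRAIN = TrainConfig(
    batch_size=8, epochs=60, lr=1e-2, rot90_prob=0.0, crop_range=(1.0, 1.0),
    decay_factor=0.2,
)


# -- folds -----------------------------------------------------------------


def make_folds(patient_ids: list[str], k: int, seed: int) -> list[list[str]]:
    """Patient-level partition into k validation folds of near-equal size
    (sizes differ by at most 1), deterministic given ``seed``."""
    if k > len(patient_ids):
        raise ValueError(f"cannot make {k} folds from {len(patient_ids)} patients")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patient_ids))
    shuffled = [patient_ids[i] for i in order]
    return [list(chunk) for chunk in np.array_split(shuffled, k)]


# -- datasets --------------------------------------------------------------


@dataclass
class SlicePairs:
    """Flat collection of aligned raw (MR, CT) slices with patient indices."""

    mr: np.ndarray        # (N, H, W) raw MR units
    ct: np.ndarray        # (N, H, W) HU
    patient_index: np.ndarray
    patient_ids: list[str]

    def __len__(self) -> int:
        return self.mr.shape[0]

    @classmethod
    def from_cohort(cls, patients: list[PhantomPatient]) -> "SlicePairs":
        mr = np.concatenate([p.mr for p in patients])
        ct = np.concatenate([p.ct for p in patients])
        idx = np.concatenate(
            [np.full(p.n_slices, i, dtype=np.int64) for i, p in enumerate(patients)]
        )
        return cls(mr=mr, ct=ct, patient_index=idx,
                   patient_ids=[p.patient_id for p in patients])

    def take_fraction(self, fraction: float, rng: np.random.Generator) -> "SlicePairs":
        """Random subset of floor(fraction * n) slices."""
        n_keep = int(np.floor(fraction * len(self)))
        if n_keep < 1:
            raise ValueError(f"fraction {fraction} keeps no slices")
        keep = np.sort(rng.choice(len(self), size=n_keep, replace=False))
        return SlicePairs(self.mr[keep], self.ct[keep], self.patient_index[keep],
                          self.patient_ids)


# -- augmentation ----------------------------------------------------------


def augment(
    mr: np.ndarray,
    ct: np.ndarray,
    rng: np.random.Generator,
    config: TrainConfig,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one identical random geometric transform to an aligned pair.

    With probability ``rot90_prob`` the pair is rotated by a random multiple
    of 90 degrees (lossless grid rotation); then a random sub-window of
    per-axis fraction drawn from ``crop_range`` is cropped and resized back
    to the original grid (bilinear for images, nearest for an optional label
    map).  The same transform is applied to every array, so spatial
    correspondence is preserved.
    """
    h, w = mr.shape
    arrays = [mr, ct] + ([labels] if labels is not None else [])
    if config.rot90_prob > 0 and rng.random() < config.rot90_prob:
        k = int(rng.integers(1, 4))
        arrays = [np.rot90(a, k) for a in arrays]
    f_h = rng.uniform(*config.crop_range)
    f_w = rng.uniform(*config.crop_range)
    ch, cw = max(int(round(f_h * h)), 8), max(int(round(f_w * w)), 8)
    if (ch, cw) != (h, w):
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        resized = []
        for i, a in enumerate(arrays):
            crop = a[r0 : r0 + ch, c0 : c0 + cw]
            order = 0 if (labels is not None and i == len(arrays) - 1) else 1
            out = sktransform.resize(
                crop.astype(np.float32), (h, w), order=order,
                preserve_range=True, anti_aliasing=False,
            )
            resized.append(out.astype(a.dtype) if order == 0 else out.astype(np.float32))
        arrays = resized
    arrays = [np.ascontiguousarray(a) for a in arrays]
    return tuple(arrays)


# -- batch assembly --------------------------------------------------------


def _assemble_batch(
    mr_slices: list[np.ndarray],
    ct_slices: list[np.ndarray],
    norm: NormalizationSpec,
    windows: TissueWindows,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize MR and split+normalize CT into (N,1,H,W) / (N,3,H,W)."""
    x = np.stack([norm.normalize_mr(m) for m in mr_slices])[:, None].astype(np.float32)
    targets = []
    for ct in ct_slices:
        stack = hw.normalize(split_channels(ct, windows), norm)
        targets.append(stack.stacked())
    y = np.stack(targets).astype(np.float32)
    return x, y


# -- training --------------------------------------------------------------


@dataclass
class TrainRecord:
    """Per-epoch loss history and checkpoint bookkeeping for one run."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    wall_time_s: float = 0.0
    final_checkpoint: str | None = None
    best_checkpoint: str | None = None

    def loss_curve(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path: str | Path) -> None:
        self.loss_curve().to_csv(path, index=False)


def _snapshot(net: UNet) -> list[np.ndarray]:
    arrays = [p.value.copy() for p in net.params()]
    for layer in net._leaf_layers():
        if isinstance(layer, BatchNorm2d):
            arrays.append(layer.running_mean.copy())
            arrays.append(layer.running_var.copy())
    return arrays


def _restore(net: UNet, state: list[np.ndarray]) -> None:
    it = iter(state)
    for p in net.params():
        p.value[...] = next(it)
    for layer in net._leaf_layers():
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)


def _validation_loss(
    net: UNet, pairs: SlicePairs, cfg: TrainConfig,
    norm: NormalizationSpec, windows: TissueWindows,
) -> float:
    total, n = 0.0, 0
    for start in range(0, len(pairs), cfg.batch_size):
        sl = slice(start, start + cfg.batch_size)
        x, y = _assemble_batch(list(pairs.mr[sl]), list(pairs.ct[sl]), norm, windows)
        pred = net.forward(x, training=False)
        loss, _ = batch_loss_and_grad(pred, y, cfg.channel_weights)
        total += loss * x.shape[0]
        n += x.shape[0]
    return total / n


def train(
    net: UNet,
    train_pairs: SlicePairs,
    val_pairs: SlicePairs,
    config: TrainConfig,
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
    run_dir: str | Path | None = None,
    log=None,
) -> TrainRecord:
    """Train ``net`` on raw slice pairs, minimizing the channel-summed
    MAE+MSE objective with Adam.

    Augmentation, batching and the optional training-fraction subsample all
    draw from a generator seeded by ``config.seed``, so a run is
    deterministic up to floating-point reduction order.  The epoch with the
    lowest validation loss is restored into ``net`` on return; if
    ``run_dir`` is given, loss CSV plus final and best checkpoints are
    written there.
    """
    rng = np.random.default_rng(config.seed)
    if config.fraction < 1.0:
        train_pairs = train_pairs.take_fraction(config.fraction, rng)
    opt = Adam(net.params(), lr=config.lr, betas=config.betas)
    record = TrainRecord()
    best_state = None
    t0 = time.perf_counter()
    augmenting = config.rot90_prob > 0 or config.crop_range != (1.0, 1.0)
    decay_epoch = int(config.decay_at_frac * config.epochs)
    for epoch in range(config.epochs):
        if config.decay_factor != 1.0 and epoch == decay_epoch:
            opt.lr *= config.decay_factor
        perm = rng.permutation(len(train_pairs))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            mr_b, ct_b = [], []
            for i in idx:
                m, c = train_pairs.mr[i], train_pairs.ct[i]
                if augmenting:
                    m, c = augment(m, c, rng, config)
                mr_b.append(m)
                ct_b.append(c)
            x, y = _assemble_batch(mr_b, ct_b, norm, windows)
            opt.zero_grad()
            pred = net.forward(x, training=True)
            loss, grad = batch_loss_and_grad(pred, y, config.channel_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"loss={loss}"
                )
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = _validation_loss(net, val_pairs, config, norm, windows)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n_seen, "val_loss": val_loss}
        record.epochs.append(entry)
        if log is not None:
            log(f"epoch {epoch:3d}  train {entry['train_loss']:.5f}  val {val_loss:.5f}")
        if val_loss < record.best_val_loss:
            record.best_val_loss = val_loss
            record.best_epoch = epoch
            best_state = _snapshot(net)
    record.wall_time_s = time.perf_counter() - t0
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        final = run_dir / "final.npz"
        save_checkpoint(final, net, norm)
        record.final_checkpoint = str(final)
    if best_state is not None:
        _restore(net, best_state)
    if run_dir is not None:
        best = Path(run_dir) / "best.npz"
        save_checkpoint(best, net, norm)
        record.best_checkpoint = str(best)
        record.to_csv(Path(run_dir) / "loss.csv")
    return record


# -- prediction ------------------------------------------------------------


def predict(
    net: UNet, mr: np.ndarray, norm: NormalizationSpec = NormalizationSpec()
) -> tuple[np.ndarray, ChannelStack]:
    """Translate one MR slice into (HU image, HU channel stack).

    The MR slice is padded to the network grid, normalized, passed through
    the network in inference mode, denormalized per channel, and the
    channels summed; padding margins are cropped off.  The sum is raw —
    no clamping or re-masking.
    """
    padded, rec = pad_to_grid(np.asarray(mr, dtype=np.float32), net.config.depth)
    x = norm.normalize_mr(padded)[None, None].astype(np.float32)
    out = net.forward(x, training=False)[0]
    stack = hw.denormalize(ChannelStack.from_array(out, normalized=True), norm)
    cropped = ChannelStack(
        rec.crop(stack.air), rec.crop(stack.tissue), rec.crop(stack.bone)
    )
    return hw.recombine(cropped), cropped


def predict_volume(
    net: UNet, mr: np.ndarray, norm: NormalizationSpec = NormalizationSpec()
) -> np.ndarray:
    """Slicewise prediction over a (n_slices, H, W) MR stack."""
    return np.stack([predict(net, s, norm)[0] for s in mr])


# -- evaluation helpers ----------------------------------------------------


def evaluate_model(
    net: UNet,
    patients: list[PhantomPatient],
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
):
    """Per-patient MAE reports for model predictions on phantom patients,
    using each phantom's analytic head mask."""
    from .evaluation import evaluate_patient

    reports = []
    for p in patients:
        mrct = predict_volume(net, p.mr, norm)
        reports.append(
            evaluate_patient(mrct, p.ct, p.mask, windows, patient=p.patient_id)
        )
    return reports


def constant_baseline_mae(
    patients: list[PhantomPatient],
    windows: TissueWindows = TissueWindows(),
    region: str = "tissue",
) -> float:
    """MAE of the best constant predictor for one region.

    The constant minimizing mean absolute error is the median of the
    region's ground-truth HU values over the given patients (within the
    head mask); returns the resulting MAE.  This is the floor any useful
    model must beat.
    """
    idx = {"air": 0, "tissue": 1, "bone": 2}[region]
    vals = []
    for p in patients:
        rm = windows.masks(p.ct)[idx] & p.mask
        vals.append(p.ct[rm])
    vals = np.concatenate(vals).astype(np.float64)
    return float(np.abs(vals - np.median(vals)).mean())


def channel_mae(
    net: UNet,
    patients: list[PhantomPatient],
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
    channel: str = "tissue",
) -> float:
    """MAE (HU) of one predicted channel against the split ground truth,
    over all masked voxels of the given patients."""
    errs = []
    for p in patients:
        for s in range(p.n_slices):
            _, stack = predict(net, p.mr[s], norm)
            truth = split_channels(p.ct[s], windows)
            diff = np.abs(getattr(stack, channel) - getattr(truth, channel))
            errs.append(diff[p.mask[s]])
    return float(np.concatenate(errs).mean())


def constant_channel_baseline_mae(
    patients: list[PhantomPatient],
    windows: TissueWindows = TissueWindows(),
    channel: str = "tissue",
) -> float:
    """MAE of the best constant prediction for one split channel.

    The channel is 0 outside its window, so the optimal constant is the
    median over all masked voxels including those zeros.
    """
    vals = []
    for p in patients:
        ch = getattr(split_channels(p.ct, windows), channel)
        vals.append(ch[p.mask])
    vals = np.concatenate(vals).astype(np.float64)
    return float(np.abs(vals - np.median(vals)).mean())


# -- experiments -----------------------------------------------------------


def cross_validate(
    cohort: list[PhantomPatient],
    build_net,
    train_cfg: TrainConfig,
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
    init_seed: int = 0,
) -> list[tuple[list[str], TrainRecord]]:
    """k-fold cross-validation with patient-level folds.

    ``build_net`` is a zero-argument factory returning a fresh network.
    Returns (validation patient ids, record) per fold.
    """
    ids = [p.patient_id for p in cohort]
    folds = make_folds(ids, train_cfg.folds, train_cfg.seed)
    results = []
    for fold_i, val_ids in enumerate(folds):
        train_p = [p for p in cohort if p.patient_id not in val_ids]
        val_p = [p for p in cohort if p.patient_id in val_ids]
        net = initialize(build_net(), seed=init_seed + fold_i)
        rec = train(
            net,
            SlicePairs.from_cohort(train_p),
            SlicePairs.from_cohort(val_p),
            replace(train_cfg, seed=train_cfg.seed + fold_i),
            norm, windows,
        )
        results.append((val_ids, rec))
    return results


def subsampling_experiment(
    train_patients: list[PhantomPatient],
    test_patients: list[PhantomPatient],
    fractions: tuple[float, ...],
    build_net,
    train_cfg: TrainConfig,
    norm: NormalizationSpec = NormalizationSpec(),
    windows: TissueWindows = TissueWindows(),
    init_seed: int = 0,
) -> pd.DataFrame:
    """Train one model per training-data fraction and evaluate on a fixed
    held-out test set.

    Every fraction starts from the identical initialization seed; only the
    random subset of training slices differs.  The last training patient is
    held out as the validation monitor (never the test set, which stays
    untouched until final evaluation).  Returns a tidy frame with one row
    per (fraction, region) giving mean/min/max test MAE.
    """
    from .evaluation import reports_frame

    fractions = tuple(sorted(fractions))
    fit_patients, monitor = train_patients[:-1], train_patients[-1:]
    val_pairs = SlicePairs.from_cohort(monitor)
    rows = []
    for frac in fractions:
        net = initialize(build_net(), seed=init_seed)
        cfg = replace(train_cfg, fraction=frac)
        train(net, SlicePairs.from_cohort(fit_patients), val_pairs, cfg, norm, windows)
        df = reports_frame(evaluate_model(net, test_patients, norm, windows))
        for region in ("all", "air", "tissue", "bone"):
            col = df[f"mae_{region}"]
            rows.append({
                "fraction": frac, "region": region,
                "mae_mean": float(col.mean()),
                "mae_min": float(col.min()),
                "mae_max": float(col.max()),
            })
    return pd.DataFrame(rows)
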