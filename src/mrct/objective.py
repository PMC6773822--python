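"""Training objective: combined MAE + MSE loss, summed over tissue channels.

For a pair of images X, Y with n pixels,

    MAE(X, Y) = (1/n) sum_i |X_i - Y_i|
    MSE(X, Y) = (1/n) sum_i (X_i - Y_i)^2
    L(X, Y)   = MAE(X, Y) + MSE(X, Y)

and the total objective is the equally weighted sum of L over the air,
tissue and bone channels:

    L_tot = L(X_air, Y_air) + L(X_tissue, Y_tissue) + L(X_bone, Y_bone).

The MAE term keeps gradients informative for small residuals (sharp
boundaries), the MSE term penalizes large excursions; computing the loss per
channel prevents the wide air/bone dynamic range from drowning out soft
tissue.  During training the loss is evaluated on normalized channel values;
evaluation-time MAE (``mrct.evaluation``) is computed in HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hu_windows import CHANNEL_NAMES, ChannelStack


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mae(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute pixelwise difference between two equal-shape grids."""
    x, y = _check_shapes(x, y)
    return float(np.mean(np.abs(x - y)))


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared pixelwise difference between two equal-shape grids."""
    x, y = _check_shapes(x, y)
    d = x - y
    return float(np.mean(d * d))


def combined_loss(x: np.ndarray, y: np.ndarray) -> float:
    """MAE + MSE between two equal-shape grids."""
    return mae(x, y) + mse(x, y)


@dataclass(frozen=True)
class LossBreakdown:
    """Per-channel and total loss components for one prediction/target pair."""

    mae_air: float
    mae_tissue: float
    mae_bone: float
    mse_air: float
    mse_tissue: float
    mse_bone: float

    @property
    def channel_losses(self) -> tuple[float, float, float]:
        return (
            self.mae_air + self.mse_air,
            self.mae_tissue + self.mse_tissue,
            self.mae_bone + self.mse_bone,
        )

    @property
    def total(self) -> float:
        return float(sum(self.channel_losses))

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, l in zip(CHANNEL_NAMES, self.channel_losses):
            out[f"loss_{name}"] = l
        out["loss_total"] = self.total
        return out


def total_loss(
    pred: ChannelStack,
    target: ChannelStack,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LossBreakdown:
    """Channel-summed combined loss between a predicted and a target stack.

    Both stacks must share shape and normalization state (the loss is
    normally computed in normalized space during training).  ``weights``
    scales the per-channel MAE and MSE terms; the default is the equally
    weighted objective.
    """
    if pred.normalized != target.normalized:
        raise ValueError(
            "mixed normalization states: "
            f"pred normalized={pred.normalized}, target normalized={target.normalized}"
        )
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    maes = [w * mae(p, t) for w, p, t in zip(weights, pred.channels, target.channels)]
    mses = [w * mse(p, t) for w, p, t in zip(weights, pred.channels, target.channels)]
    return LossBreakdown(
        mae_air=maes[0], mae_tissue=maes[1], mae_bone=maes[2],
        mse_air=mses[0], mse_tissue=mses[1], mse_bone=mses[2],
    )


def batch_loss_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, np.ndarray]:
    """Differentiable batch form of the total loss for the training loop.

    ``pred`` and ``target`` are (N, 3, H, W) arrays of normalized channel
    values.  Returns the batch-mean total loss and its gradient with respect
    to ``pred``.  Per image and channel the loss uses n = H*W; the subgradient
    of |d| at d == 0 is taken as 0.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.ndim != 4 or pred.shape[1] != 3:
        raise ValueError(f"expected (N, 3, H, W) arrays, got {pred.shape}")
    n_img, _, h, w = pred.shape
    n_pix = h * w
    d = pred - target
    wvec = np.asarray(weights, dtype=d.dtype).reshape(1, 3, 1, 1)
    per_term = wvec * (np.abs(d) + d * d)
    loss = float(per_term.sum()) / (n_img * n_pix)
    grad = wvec * (np.sign(d) + 2.0 * d) / (n_img * n_pix)
    return loss, grad.astype(pred.dtype, copy=False)
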