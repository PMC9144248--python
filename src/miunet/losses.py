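"""Composite segmentation objective.

The total training loss for the joint model is

    L = sum over branches of [ lam1 * L_DSC + (1 - lam1) * L_BCE ]
        + lam_tv * ( TV(p_cine) + TV(p_lge) )
        + lam_sp * L_BCE(p_cine, p_lge)

where L_DSC is the soft Dice loss with squared sums in the denominator,
L_BCE is the pixel-mean binary cross-entropy, TV is the L1 total
variation of the predicted foreground probability maps (1/N * sum |dx|),
and the last term is a cross-contrast spatial-consistency BCE between the
two branches' probability maps (soft targets, gradients to both sides).

Every function accepts either plain numpy arrays (returns a float) or
autodiff :class:`~miunet.nn.Tensor` inputs (returns a Tensor on the
tape), so the same code path is used for training, for oracle tests, and
for finite-difference gradient checks.

Multi-class extension: probability maps are (C, H, W) or (N, C, H, W)
with C = 4 softmax channels. Dice is evaluated one-vs-rest per channel
and averaged over the three foreground classes (a background-dominated
Dice would saturate); BCE and the consistency term average over all four
channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigurationError, DimensionError
from .nn import Tensor

__all__ = [
    "LossWeights",
    "EPS",
    "dsc_loss",
    "bce_loss",
    "seg_loss",
    "tv_penalty",
    "spatial_consistency",
    "joint_loss",
]

EPS = 1e-7  # probability clip before any logarithm

FOREGROUND_CHANNELS = (1, 2, 3)


@dataclass(frozen=True)
class LossWeights:
    """lambda1 balances Dice vs BCE; lambda_tv and lambda_sp weight the
    smoothness and cross-contrast consistency constraints."""

    lambda1: float = 0.5
    lambda_tv: float = 0.0
    lambda_sp: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lambda1 <= 1.0:
            raise ConfigurationError("lambda1 must be in [0, 1]")
        if self.lambda_tv < 0 or self.lambda_sp < 0:
            raise ConfigurationError("lambda_tv and lambda_sp must be >= 0")


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_same_shape(a: Tensor, b: Tensor):
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")


def _maybe_item(out: Tensor, tensor_mode: bool):
    return out if tensor_mode else out.item()


def dsc_loss(pred, target):
    """Soft Dice loss, 1 - 2*sum(x*xhat) / (sum(x^2) + sum(xhat^2)).

    Single-channel / flat-vector primitive. Both-empty inputs (all-zero
    pred and target) are defined as 0 — perfect agreement on absence.
    """
    tensor_mode = _is_tensor(pred, target)
    x, t = _wrap(pred), _wrap(target)
    _check_same_shape(x, t)
    denom_val = float((x.data ** 2).sum() + (t.data ** 2).sum())
    if denom_val == 0.0:
        return _maybe_item(x.sum() * 0.0, tensor_mode)
    inter = (x * t).sum()
    denom = (x ** 2.0).sum() + (t ** 2.0).sum()
    out = 1.0 - 2.0 * inter / denom
    return _maybe_item(out, tensor_mode)


def bce_loss(pred, target):
    """Binary cross-entropy, mean over all elements; predictions are
    clipped to [EPS, 1 - EPS] before the logarithms. Soft targets allowed."""
    tensor_mode = _is_tensor(pred, target)
    p, t = _wrap(pred), _wrap(target)
    _check_same_shape(p, t)
    pc = p.clip(EPS, 1.0 - EPS)
    out = -(t * pc.log() + (1.0 - t) * (1.0 - pc).log()).mean()
    return _maybe_item(out, tensor_mode)


def _multiclass_dsc(prob: Tensor, onehot: Tensor):
    """Per-channel one-vs-rest soft Dice averaged over foreground classes."""
    terms = [
        dsc_loss(prob[..., c, :, :], onehot[..., c, :, :])
        for c in FOREGROUND_CHANNELS
    ]
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def _is_probmap(x) -> bool:
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    return data.ndim >= 3


def seg_loss(pred, target, lambda1: float = 0.5):
    """Per-branch loss: lambda1 * Dice + (1 - lambda1) * BCE.

    With flat/2D inputs both terms act on the given vectors directly;
    with (.., C, H, W) probability maps the multi-class aggregation
    applies (foreground-averaged Dice, all-channel BCE).
    """
    if not 0.0 <= lambda1 <= 1.0:
        raise ConfigurationError("lambda1 must be in [0, 1]")
    tensor_mode = _is_tensor(pred, target)
    p, t = _wrap(pred), _wrap(target)
    _check_same_shape(p, t)
    if _is_probmap(p):
        dice = _multiclass_dsc(p, t)
    else:
        dice = dsc_loss(p, t)
    bce = bce_loss(p, t)
    out = lambda1 * _wrap(dice) + (1.0 - lambda1) * _wrap(bce)
    return _maybe_item(out, tensor_mode)


def tv_penalty(prob_map):
    """L1 total variation of a 2D map: (1/N) * sum of |forward differences|
    along both axes, with replicated edges (zero difference at the last
    row/column). Constant maps score 0."""
    tensor_mode = _is_tensor(prob_map)
    x = _wrap(prob_map)
    if x.ndim != 2:
        raise DimensionError("tv_penalty expects a single-channel 2D array")
    n = float(x.data.size)
    dv = (x[1:, :] - x[:-1, :]).abs().sum()
    dh = (x[:, 1:] - x[:, :-1]).abs().sum()
    out = (dv + dh) * (1.0 / n)
    return _maybe_item(out, tensor_mode)


def _tv_foreground(prob: Tensor):
    """Mean per-map TV over the foreground channels (and any batch dim).

    Evaluated on the full array at once; since every map has the same
    pixel count this equals the average of per-channel `tv_penalty` calls.
    """
    if prob.ndim == 3:
        fg = prob[FOREGROUND_CHANNELS[0] : FOREGROUND_CHANNELS[-1] + 1]
        n_maps = len(FOREGROUND_CHANNELS)
    elif prob.ndim == 4:
        fg = prob[:, FOREGROUND_CHANNELS[0] : FOREGROUND_CHANNELS[-1] + 1]
        n_maps = prob.shape[0] * len(FOREGROUND_CHANNELS)
    else:
        raise DimensionError("expected (C,H,W) or (N,C,H,W) probability map")
    h, w = fg.shape[-2], fg.shape[-1]
    dv = (fg[..., 1:, :] - fg[..., :-1, :]).abs().sum()
    dh = (fg[..., :, 1:] - fg[..., :, :-1]).abs().sum()
    return (dv + dh) * (1.0 / float(n_maps * h * w))


def spatial_consistency(pred_cine, pred_lge, stop_gradient: str = "none"):
    """Cross-contrast consistency: BCE with the cine probabilities as the
    prediction and the LGE probabilities as a *soft* target, averaged over
    all channels and pixels.

    By default gradients flow to both branches; `stop_gradient` can detach
    either side (the high-SNR contrast acting as a fixed prior is the
    `stop_gradient="cine"` reading).
    """
    if stop_gradient not in ("none", "lge", "cine"):
        raise ConfigurationError(f"unknown stop_gradient mode {stop_gradient!r}")
    tensor_mode = _is_tensor(pred_cine, pred_lge)
    p, t = _wrap(pred_cine), _wrap(pred_lge)
    _check_same_shape(p, t)
    if stop_gradient == "lge":
        t = t.detach()
    elif stop_gradient == "cine":
        p = p.detach()
    return _maybe_item(_wrap(bce_loss(p, t)), tensor_mode)


def joint_loss(
    pred_cine,
    pred_lge,
    target_cine,
    target_lge,
    weights: LossWeights,
    stop_gradient: str = "none",
):
    """Full two-branch objective; returns (total, per-term breakdown).

    With lambda_tv = lambda_sp = 0 this reduces exactly to the sum of the
    two branch segmentation losses.
    """
    tensor_mode = _is_tensor(pred_cine, pred_lge)
    pc, pl = _wrap(pred_cine), _wrap(pred_lge)
    tc, tl = _wrap(target_cine), _wrap(target_lge)
    terms = {
        "seg_cine": _wrap(seg_loss(pc, tc, weights.lambda1)),
        "seg_lge": _wrap(seg_loss(pl, tl, weights.lambda1)),
        "tv_cine": _tv_foreground(pc),
        "tv_lge": _tv_foreground(pl),
        "spatial": _wrap(spatial_consistency(pc, pl, stop_gradient)),
    }
    total = (
        terms["seg_cine"]
        + terms["seg_lge"]
        + weights.lambda_tv * (terms["tv_cine"] + terms["tv_lge"])
        + weights.lambda_sp * terms["spatial"]
    )
    if tensor_mode:
        return total, terms
    return total.item(), {k: v.item() for k, v in terms.items()}
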