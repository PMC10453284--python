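"""Composite training losses and pixel-wise evaluation metrics.

Losses accept either plain numpy arrays (returning floats) or autograd
tensors (returning tensors, for training graphs).  The vessel loss is
``L_v = L_bce + 0.1 * L_dice``; the A/V loss is a masked cross-entropy over
{background, artery, vein} that excludes UNCERTAIN ground-truth pixels; the
total is ``L_v + L_a``.

Metric conventions: VESSEL counts treat vessel pixels as positives over all
evaluated pixels; AV counts treat artery as positive and vein as negative,
restricted to ground-truth artery/vein pixels, with predictions taken as the
argmax over the artery/vein channels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._nn import Tensor, softmax
from .io_datasets import AVLabel

EPSILON = 1e-6       # dice smoothing
PROB_CLAMP = 1e-7    # log stability


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _ret(t: Tensor, was_tensor: bool):
    return t if was_tensor else float(t.data)


def bce_loss(p, y, reduction: str = "mean"):
    """Binary cross-entropy of probabilities ``p`` against binary ``y``."""
    pt, tensor_in = _as_tensor(p)
    # match the prediction dtype so float32 training graphs stay float32
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=pt.dtype)
    if pt.shape != y.shape:
        raise ValueError(f"shape mismatch: p {pt.shape} vs y {y.shape}")
    pc = pt.clamp(PROB_CLAMP, 1.0 - PROB_CLAMP)
    terms = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log())
    out = terms.mean() if reduction == "mean" else terms.sum()
    return _ret(out, tensor_in)


def dice_loss(p, y):
    """1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps), eps = 1e-6."""
    pt, tensor_in = _as_tensor(p)
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=pt.dtype)
    if pt.shape != y.shape:
        raise ValueError(f"shape mismatch: p {pt.shape} vs y {y.shape}")
    yt = Tensor(y)
    inter = (pt * yt).sum()
    denom = pt.sum() + Tensor(y.sum())
    out = 1.0 - (2.0 * inter + EPSILON) / (denom + EPSILON)
    return _ret(out, tensor_in)


def av_ce_loss(logits, av, reduction: str = "mean"):
    """Masked 3-class cross-entropy; UNCERTAIN ground truth is excluded.

    ``logits`` has channel order (background, artery, vein) with channels on
    axis -3 (supports both (C, H, W) and (N, C, H, W)).
    """
    lt, tensor_in = _as_tensor(logits)
    av = np.asarray(av.data if isinstance(av, Tensor) else av)
    if lt.shape[-2:] != av.shape[-2:] or lt.shape[-3] != 3:
        raise ValueError(f"shape mismatch: logits {lt.shape} vs labels {av.shape}")
    mask = (av != int(AVLabel.UNCERTAIN)).astype(lt.dtype)
    n_eval = mask.sum()
    if n_eval == 0:
        raise ValueError("all pixels are UNCERTAIN: empty A/V loss")
    onehot_cls = np.clip(av, 0, 2)  # uncertain pixels masked anyway
    axis = lt.ndim - 3
    oh = np.moveaxis(np.eye(3, dtype=lt.dtype)[onehot_cls], -1, axis)
    logp = softmax(lt, axis=axis).clamp(PROB_CLAMP, 1.0).log()
    if lt.ndim == 4 and mask.ndim == 2:
        mask = np.broadcast_to(mask, (lt.shape[0],) + mask.shape)
        n_eval = mask.sum()
    per_px = -(Tensor(oh) * logp).sum(axis=axis) * Tensor(mask)
    total = per_px.sum()
    out = total / n_eval if reduction == "mean" else total
    return _ret(out, tensor_in)


@dataclass
class LossTerms:
    l_bce: float
    l_dice: float
    l_v: float
    l_a: float
    total: float
    epsilon: float = EPSILON


def total_loss(vessel_prob, vessel_gt, final_logits, av_gt,
               reduction: str = "mean"):
    """Composite loss; returns (LossTerms, total) where total matches the
    input type (tensor in -> tensor out, for backprop)."""
    lb = bce_loss(vessel_prob, vessel_gt, reduction=reduction)
    ld = dice_loss(vessel_prob, vessel_gt)
    la = av_ce_loss(final_logits, av_gt, reduction=reduction)
    lv = lb + 0.1 * ld
    tot = lv + la

    def f(x):
        return float(x.data) if isinstance(x, Tensor) else float(x)

    terms = LossTerms(l_bce=f(lb), l_dice=f(ld), l_v=f(lv), l_a=f(la),
                      total=f(tot))
    return terms, tot


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    convention: str = "VESSEL"   # VESSEL | AV
    eval_mask: str = "all pixels"

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.convention != other.convention:
            raise ValueError("cannot pool counts across conventions")
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn,
                               self.convention, self.eval_mask)


def confusion(pred, gt, convention: str) -> ConfusionCounts:
    """Tally TP/TN/FP/FN under the given convention.

    VESSEL: ``pred`` and ``gt`` are binary maps; positives are vessel pixels;
    every pixel is evaluated.

    AV: ``gt`` is an AVLabel map; evaluation is restricted to ground-truth
    artery/vein pixels.  ``pred`` is either 3-channel logits/probabilities
    (argmax is taken over the artery and vein channels only) or a categorical
    map that must be artery/vein at every evaluated pixel.
    """
    gt = np.asarray(gt)
    if convention == "VESSEL":
        pred = np.asarray(pred)
        if pred.ndim == 3 and pred.shape[0] == 1:
            pred = pred[0]
        if pred.dtype.kind == "f":
            pred = pred >= 0.5
        pred = pred.astype(bool)
        gtb = gt.astype(bool)
        if pred.shape != gtb.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {gtb.shape}")
        return ConfusionCounts(
            tp=int((pred & gtb).sum()), tn=int((~pred & ~gtb).sum()),
            fp=int((pred & ~gtb).sum()), fn=int((~pred & gtb).sum()),
            convention="VESSEL", eval_mask="all pixels")

    if convention != "AV":
        raise ValueError(f"unknown convention {convention!r}")
    sel = (gt == int(AVLabel.ARTERY)) | (gt == int(AVLabel.VEIN))
    if not sel.any():
        raise ValueError("empty A/V evaluation mask: no artery/vein ground truth")
    pred = np.asarray(pred)
    if pred.ndim == 3 and pred.shape[0] == 3:
        # argmax over artery/vein channels only
        pred_art = pred[1] > pred[2]
    else:
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
        vals = pred[sel]
        bad = ~np.isin(vals, (int(AVLabel.ARTERY), int(AVLabel.VEIN)))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} evaluated pixels are neither artery nor "
                "vein; pass 3-channel scores or an artery/vein-restricted map"
            )
        pred_art = np.zeros_like(sel)
        pred_art[sel] = vals == int(AVLabel.ARTERY)
    gt_art = gt == int(AVLabel.ARTERY)
    pa, ga = pred_art[sel], gt_art[sel]
    return ConfusionCounts(
        tp=int((pa & ga).sum()), tn=int((~pa & ~ga).sum()),
        fp=int((pa & ~ga).sum()), fn=int((~pa & ga).sum()),
        convention="AV", eval_mask="ground-truth artery/vein pixels")


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sen, Spe, Acc, F1 from pooled counts; undefined ratios become NaN."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          stacklevel=2)
            return float("nan")
        return num / den

    return {
        "sen": ratio(tp, tp + fn, "sensitivity"),
        "spe": ratio(tn, tn + fp, "specificity"),
        "acc": ratio(tp + tn, counts.total, "accuracy"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    }


__all__ = [
    "EPSILON", "PROB_CLAMP", "LossTerms", "ConfusionCounts",
    "bce_loss", "dice_loss", "av_ce_loss", "total_loss", "confusion",
    "metrics",
]
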