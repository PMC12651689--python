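"""Segmentation training objectives and the Hausdorff boundary distance.

Six losses, each usable standalone or in a weighted combination:

    dice      1 - 2*sum(p*m) / (sum(p^2) + sum(m^2) + eps)
    focal     cross-entropy with a (1-p)^gamma modulating factor (gamma=2)
    hausdorff symmetric max-min boundary distance (evaluation; its
              differentiable training surrogate is separate, see below)
    jaccard   1 - (|intersection| + eps) / (|union| + eps)
    tversky   asymmetric Jaccard: alpha weights false positives (0.7),
              beta false negatives (0.3)
    dicebce   dice + mean binary cross-entropy, unit weights

All ratio losses carry a smoothing eps (default 1e-6, settable to 0) so
empty masks do not divide by zero.  The functions accept plain numpy
arrays or autodiff tensors and reduce over the last axis, so a leading
batch axis broadcasts through.

The Hausdorff distance itself is not differentiable in the predicted
probabilities; `hausdorff_surrogate` is this package's differentiable
stand-in (squared error weighted by squared distance transforms), NOT
the max-min boundary formula, and is documented as such.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .nn import Tensor

CLIP_EPS = 1e-7
SMOOTH_EPS = 1e-6

LOSS_NAMES = ("dice", "focal", "hausdorff", "jaccard", "tversky", "dicebce")


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _sum(x):
    return x.sum(axis=-1) if _is_tensor(x) else np.sum(x, axis=-1)


def _log(x):
    return x.log() if _is_tensor(x) else np.log(x)


def _clip(x, lo, hi):
    return x.clip(lo, hi) if _is_tensor(x) else np.clip(x, lo, hi)


def _mean_last(x):
    return x.mean(axis=-1) if _is_tensor(x) else np.mean(x, axis=-1)


def _check_lengths(pred, target):
    ps = pred.shape if hasattr(pred, "shape") else np.shape(pred)
    ts = np.shape(target.data if _is_tensor(target) else target)
    if ps[-1] != ts[-1]:
        raise ValueError(f"prediction length {ps[-1]} != target length {ts[-1]}")


def dice_loss(pred, target, smooth_eps: float = SMOOTH_EPS):
    """Soft Dice loss with squared-term denominator."""
    _check_lengths(pred, target)
    inter = _sum(pred * target)
    denom = _sum(pred * pred) + _sum(target * target) + smooth_eps
    return 1.0 - 2.0 * inter / denom


def focal_loss(pred, target, gamma: float = 2.0):
    """Focal loss; pred is clipped away from {0,1} for log stability."""
    _check_lengths(pred, target)
    p = _clip(pred, CLIP_EPS, 1.0 - CLIP_EPS)
    pos = (1.0 - p) ** gamma * _log(p) * target
    neg = p ** gamma * _log(1.0 - p) * (1.0 - target)
    return -_mean_last(pos + neg)


def bce_loss(pred, target):
    """Mean binary cross-entropy with the same clipping as focal_loss."""
    _check_lengths(pred, target)
    p = _clip(pred, CLIP_EPS, 1.0 - CLIP_EPS)
    return -_mean_last(_log(p) * target + _log(1.0 - p) * (1.0 - target))


def jaccard_loss(pred, target, smooth_eps: float = SMOOTH_EPS):
    """1 - IoU on soft predictions."""
    _check_lengths(pred, target)
    inter = _sum(pred * target)
    union = _sum(pred) + _sum(target) - inter
    return 1.0 - (inter + smooth_eps) / (union + smooth_eps)


def tversky_loss(pred, target, alpha: float = 0.7, beta: float = 0.3,
                 smooth_eps: float = SMOOTH_EPS):
    """Tversky loss: alpha weights false positives, beta false negatives."""
    if alpha + beta <= 0:
        raise ValueError("alpha + beta must be positive")
    _check_lengths(pred, target)
    tp = _sum(pred * target)
    fp = _sum(pred * (1.0 - target))
    fn = _sum((1.0 - pred) * target)
    return 1.0 - (tp + smooth_eps) / (tp + alpha * fp + beta * fn + smooth_eps)


def dicebce_loss(pred, target, smooth_eps: float = SMOOTH_EPS):
    """Hybrid Dice + binary cross-entropy, unit weights."""
    return dice_loss(pred, target, smooth_eps) + bce_loss(pred, target)


# ---------------------------------------------------------------------------
# Hausdorff distance (evaluation) and its differentiable surrogate (training)
# ---------------------------------------------------------------------------

def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-connected background neighbour or on the
    image border; returned as an (n, 2) array of (row, col) coordinates."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("boundary extraction expects a 2D mask")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two binary masks, in pixels.

    max over both directions of the largest nearest-boundary distance.
    If exactly one mask is empty the image diagonal is returned as a
    documented sentinel; if both are empty the distance is 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    pa = boundary_points(a)
    pb = boundary_points(b)
    if len(pa) == 0 and len(pb) == 0:
        return 0.0
    if len(pa) == 0 or len(pb) == 0:
        return float(np.hypot(*a.shape))
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa)[0].max()
    d_ba = ta.query(pb)[0].max()
    return float(max(d_ab, d_ba))


def _edt_weights(mask: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance from each pixel to the mask's foreground."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.full(m.shape, float(np.hypot(*m.shape)) ** 2)
    return ndimage.distance_transform_edt(~m) ** 2


def hausdorff_surrogate(pred, target, threshold: float = 0.5):
    """Differentiable boundary-error surrogate for training.

    mean over pixels of (p - m)^2 weighted by the squared distance
    transforms of prediction and target (distances taken to each mask's
    foreground, i.e. computed on the complements), so wrong pixels far
    from the correct region dominate.  Zero on a perfect binary match,
    finite gradient everywhere.  This is NOT the max-min Hausdorff
    formula — that one is non-differentiable in the probabilities.
    """
    pred_np = pred.data if _is_tensor(pred) else np.asarray(pred, dtype=float)
    target_np = target.data if _is_tensor(target) else np.asarray(target, dtype=float)
    if pred_np.shape != target_np.shape:
        raise ValueError("prediction/target shapes differ")
    shape = pred_np.shape
    if pred_np.ndim == 2:
        pred_np, target_np = pred_np[None], target_np[None]
    else:
        pred_np = pred_np.reshape(-1, *shape[-2:])
        target_np = target_np.reshape(-1, *shape[-2:])
    weights = np.empty_like(pred_np)
    for i in range(pred_np.shape[0]):
        w_gt = _edt_weights(target_np[i])
        w_pr = _edt_weights(pred_np[i] >= threshold)
        weights[i] = w_gt + w_pr
    weights = weights.reshape(shape)   # constants w.r.t. the gradient
    if _is_tensor(pred):
        weighted = (pred - target) ** 2 * weights
        return weighted.mean(axis=(-2, -1))
    diff2 = (np.asarray(pred, float) - np.asarray(target, float)) ** 2
    return np.mean(diff2 * weights, axis=(-2, -1))


def make_loss(name: str, *, focal_gamma: float = 2.0, tversky_alpha: float = 0.7,
              tversky_beta: float = 0.3, smooth_eps: float = SMOOTH_EPS):
    """Return a (pred, target) -> scalar-per-sample loss closure by name.

    For training, `hausdorff` maps to the differentiable surrogate.
    """
    name = name.lower()
    if name == "dice":
        return lambda p, m: dice_loss(p, m, smooth_eps)
    if name == "focal":
        return lambda p, m: focal_loss(p, m, focal_gamma)
    if name == "jaccard":
        return lambda p, m: jaccard_loss(p, m, smooth_eps)
    if name == "tversky":
        return lambda p, m: tversky_loss(p, m, tversky_alpha, tversky_beta,
                                         smooth_eps)
    if name == "dicebce":
        return lambda p, m: dicebce_loss(p, m, smooth_eps)
    if name == "hausdorff":
        return hausdorff_surrogate
    raise ValueError(f"unknown loss {name!r}; valid names: {', '.join(LOSS_NAMES)}")


def combined_loss(weights: dict[str, float], **kwargs):
    """Weighted sum of named losses, for the composite-objective reading."""
    parts = [(make_loss(name, **kwargs), w) for name, w in weights.items()]

    def loss(p, m):
        total = None
        for fn, w in parts:
            term = fn(p, m) * w
            total = term if total is None else total + term
        return total

    return loss
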