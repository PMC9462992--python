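"""Training objectives for the three tasks.

All losses accept either NumPy arrays (returning a float) or autodiff
tensors for the predictions (returning a scalar :class:`~aopmeter.autodiff.Tensor`
through which gradients flow).  Ground truth is always plain NumPy.

The shape-constrained loss (SLF) penalizes non-convex segmentations: for
triplets (p, q, r) with r on the segment between two foreground pixels p and
q, a convex prediction should be at least as confident at r as at the pair.
Its exhaustive sum is O(N^2 L) in the number of foreground pixels, so the
training path uses a seeded Monte-Carlo estimate over uniformly drawn
(pair, collinear point) triplets; the loss value is the expectation over
that triplet space, which the exhaustive mode computes exactly.  Each
triplet term is clamped at zero — only concavity violations (the collinear
point predicted below the pair) are penalized; an unclamped term would
reward overshooting at interior points without bound.  The loss vanishes at
the perfect prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossWeights", "cross_entropy", "dice_loss", "dice_loss_masks",
    "shape_constrained_loss", "mse_heatmap_loss", "total_loss",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Fixed loss weights: ``w1`` balances the Task2 pair against the heatmap
    MSE; ``delta`` weights the (right, left, midpoint) heatmaps."""

    w1: float = 0.5
    delta: tuple[float, float, float] = (1.0, 0.8, 0.6)

    def __post_init__(self):
        if not (0.0 <= self.w1 <= 1.0):
            raise ValueError("w1 must be in [0, 1]")
        if any(d <= 0 for d in self.delta):
            raise ValueError("delta weights must be positive")


def _lift(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _maybe_item(t: Tensor, want_float: bool):
    return t.item() if want_float else t


# ---------------------------------------------------------------------------

def cross_entropy(y, yhat):
    """Binary cross-entropy, batch-averaged.

    ``y`` in {0, 1}; ``yhat`` the predicted probability of class 1, clamped
    to [1e-7, 1 - 1e-7].
    """
    want_float = not isinstance(yhat, Tensor)
    y = np.asarray(y, dtype=np.float32)
    p = _lift(yhat).clamp(EPS, 1.0 - EPS)
    one = Tensor(np.float32(1.0))
    loss = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (one - p).log()).mean()
    return _maybe_item(loss, want_float)


def dice_loss(y, p):
    """Pooled Dice loss ``1 - 2 sum(y p) / (sum y + sum p)``.

    ``y`` is the one-hot (or binary) ground truth and ``p`` the matching
    probabilities, any shape, sums pooled over everything (pixels and
    foreground classes).  Empty ground truth with empty prediction is 0.
    """
    want_float = not isinstance(p, Tensor)
    y = np.asarray(y, dtype=np.float32)
    p = _lift(p)
    denom = float(y.sum() + p.data.sum())
    if denom == 0.0:
        return 0.0 if want_float else Tensor(np.float32(0.0))
    numer = (Tensor(y) * p).sum()
    loss = Tensor(np.float32(1.0)) - Tensor(np.float32(2.0)) * numer * (
        Tensor(y.sum()) + p.sum()).pow(-1.0)
    return _maybe_item(loss, want_float)


def dice_loss_masks(labels: np.ndarray, probs, foreground_classes=(1, 2)):
    """Dice loss from an integer label mask and per-class probability maps.

    ``labels``: (N, H, W) ints; ``probs``: (N, C, H, W) with channel c the
    probability of class c.  Foreground classes are pooled as in
    :func:`dice_loss`.
    """
    labels = np.asarray(labels)
    onehot = np.stack([(labels == c) for c in foreground_classes],
                      axis=1).astype(np.float32)
    if isinstance(probs, Tensor):
        lo = min(foreground_classes)
        assert tuple(foreground_classes) == tuple(range(lo, lo + len(foreground_classes)))
        fg = probs.narrow(1, lo, len(foreground_classes))
    else:
        fg = np.stack([np.asarray(probs)[:, c] for c in foreground_classes], axis=1)
    return dice_loss(onehot, fg)


# ---------------------------------------------------------------------------

def _segment_points(p, q):
    """Pixels on the segment p-q, rounded from m+1 uniform parameters where
    m is the Chebyshev distance (endpoints included)."""
    m = int(max(abs(q[0] - p[0]), abs(q[1] - p[1])))
    t = np.arange(m + 1) / max(m, 1)
    ys = np.rint(p[0] + t * (q[0] - p[0])).astype(int)
    xs = np.rint(p[1] + t * (q[1] - p[1])).astype(int)
    return ys, xs


def shape_constrained_loss(y: np.ndarray, p, class_id: int = 2,
                           n_triplets: int = 1000,
                           rng: np.random.Generator | None = None,
                           exhaustive: bool = False):
    """Convexity penalty for one image.

    ``y``: (H, W) integer labels; ``p``: (H, W) predicted probability of
    ``class_id``.  The value is the expectation over (uniform unordered
    foreground pair, uniform collinear pixel) of

        B * (y_p - p_p)(y_q - p_q)(p_p + p_q - 2 p_r)

    where B = 1 iff the ground-truth label at r is also foreground.  With
    ``exhaustive=True`` the expectation is computed exactly (use only on
    small masks); otherwise ``n_triplets`` seeded Monte-Carlo draws are used.
    """
    want_float = not isinstance(p, Tensor)
    y = np.asarray(y)
    fg = np.argwhere(y == class_id)
    if len(fg) < 2:
        return 0.0 if want_float else Tensor(np.float32(0.0))
    pt = _lift(p)

    if exhaustive:
        ridx_y, ridx_x, pidx, qidx, weights = [], [], [], [], []
        n_pairs = len(fg) * (len(fg) - 1) // 2
        for i in range(len(fg)):
            for j in range(i + 1, len(fg)):
                ys, xs = _segment_points(fg[i], fg[j])
                keep = y[ys, xs] == class_id
                w = 1.0 / (len(ys) * n_pairs)
                ridx_y.append(ys[keep])
                ridx_x.append(xs[keep])
                pidx.append(np.repeat(i, keep.sum()))
                qidx.append(np.repeat(j, keep.sum()))
                weights.append(np.repeat(w, keep.sum()))
        ry = np.concatenate(ridx_y)
        rx = np.concatenate(ridx_x)
        pi = np.concatenate(pidx)
        qi = np.concatenate(qidx)
        w = np.concatenate(weights)
    else:
        if rng is None:
            raise ValueError("Monte-Carlo mode needs an rng")
        i = rng.integers(0, len(fg), size=n_triplets)
        j = rng.integers(0, len(fg) - 1, size=n_triplets)
        j = np.where(j >= i, j + 1, j)  # uniform over distinct pairs
        pyx, qyx = fg[i], fg[j]
        m = np.maximum(np.abs(qyx - pyx).max(axis=1), 1)
        t = rng.integers(0, m + 1) / m
        ry = np.rint(pyx[:, 0] + t * (qyx[:, 0] - pyx[:, 0])).astype(int)
        rx = np.rint(pyx[:, 1] + t * (qyx[:, 1] - pyx[:, 1])).astype(int)
        keep = y[ry, rx] == class_id
        ry, rx, pi, qi = ry[keep], rx[keep], i[keep], j[keep]
        w = np.full(len(ry), 1.0 / n_triplets)

    if len(ry) == 0:
        return 0.0 if want_float else Tensor(np.float32(0.0))
    width = y.shape[1]
    if want_float:  # float64 array path (the tensor graph is float32)
        arr = np.asarray(p, dtype=np.float64).reshape(-1)
        pp = arr[fg[pi, 0] * width + fg[pi, 1]]
        pq = arr[fg[qi, 0] * width + fg[qi, 1]]
        pr = arr[ry * width + rx]
        terms = np.maximum((1.0 - pp) * (1.0 - pq) * (pp + pq - 2.0 * pr), 0.0)
        return float(np.sum(terms * w))
    flat = pt.reshape(-1)
    pp = _gather1d(flat, fg[pi, 0] * width + fg[pi, 1])
    pq = _gather1d(flat, fg[qi, 0] * width + fg[qi, 1])
    pr = _gather1d(flat, ry * width + rx)
    one = Tensor(np.float32(1.0))
    two = Tensor(np.float32(2.0))
    # only concavity violations (r predicted below the pair) are penalized;
    # rewarding overshoot at r would make the loss unbounded below
    terms = ((one - pp) * (one - pq) * (pp + pq - two * pr)).relu()
    loss = (terms * Tensor(w)).sum()
    return _maybe_item(loss, want_float)


def _gather1d(flat: Tensor, idx):
    idx = np.asarray(idx)
    out = Tensor(flat.data[idx], _prev=(flat,))

    def _bw():
        if flat.requires_grad:
            g = np.zeros_like(flat.data)
            np.add.at(g, idx, out.grad)
            flat._accum(g)
    out._backward = _bw
    return out


# ---------------------------------------------------------------------------

def mse_heatmap_loss(pred, true, delta=(1.0, 0.8, 0.6)):
    """Importance-weighted heatmap MSE: sum_k delta_k * mean_ij (H_k - Ĥ_k)^2.

    ``pred``/``true`` are (..., K, H, W) with K = len(delta); the mean is per
    pixel (and per batch element) so the magnitude is resolution-independent.
    """
    want_float = not isinstance(pred, Tensor)
    p = _lift(pred)
    t = np.asarray(true, dtype=np.float32)
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.shape}")
    k_axis = p.data.ndim - 3
    axes = tuple(i for i in range(p.data.ndim) if i != k_axis)
    per_map = (p - Tensor(t)).pow(2.0).mean(axis=axes)
    loss = (per_map * Tensor(np.asarray(delta, dtype=np.float32))).sum()
    return _maybe_item(loss, want_float)


def total_loss(l_d, l_sc, l_mse, weights: LossWeights = LossWeights(),
               s1=None, s2=None):
    """Uncertainty-weighted combination
    ``w1 (θ1 L_D + θ2 L_SC) + (1 - w1) L_MSE`` with θ_i = exp(-s_i) and a
    ``+ s_i / 2`` regularizer per learnable log-variance; s_i = None freezes
    θ_i = 1 with no regularizer."""
    want_float = all(not isinstance(v, Tensor) for v in (l_d, l_sc, l_mse, s1, s2))
    l_d, l_sc, l_mse = _lift(l_d), _lift(l_sc), _lift(l_mse)
    half = Tensor(np.float32(0.5))
    task2 = Tensor(np.float32(0.0))
    for l, s in ((l_d, s1), (l_sc, s2)):
        if s is None:
            task2 = task2 + l
        else:
            s = _lift(s)
            task2 = task2 + (-s).exp() * l
    loss = Tensor(np.float32(weights.w1)) * task2 + \
        Tensor(np.float32(1.0 - weights.w1)) * l_mse
    for s in (s1, s2):
        if s is not None:
            loss = loss + half * _lift(s)
    return _maybe_item(loss, want_float)
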