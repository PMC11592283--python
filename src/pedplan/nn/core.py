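"""Reverse-mode autodiff core: Tensor graph + the ops the networks use.

All activations are single-sample ``(C, X, Y, Z)`` float32 arrays.  Each op
builds one graph node whose ``_backward`` closure scatters the upstream
gradient into its parents; ``Tensor.backward()`` runs them in reverse
topological order.  Gradients only flow into tensors with
``requires_grad=True`` (parameters) or with parents of their own.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from pedplan.errors import ValidationError

__all__ = [
    "Tensor", "conv3d", "conv_transpose2x", "maxpool2", "relu", "add",
    "concat", "gate", "batch_norm", "softmax_channels", "seg_loss",
    "heatmap_mse_loss", "heatmap_ce_loss", "spatial_softmax",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad or p._parents for p in parents
        )
        self._parents = tuple(parents)
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValidationError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _needs(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, X, Y, Z) -> (X*Y*Z, C*k^3) with 'same' zero padding."""
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k, k), axis=(1, 2, 3))  # (C, X,Y,Z, k,k,k)
    c = x.shape[0]
    n = win.shape[1] * win.shape[2] * win.shape[3]
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(n, c * k**3)


def _conv_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    """Plain 'same' convolution; w is (Cout, Cin, k, k, k)."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    col = _im2col(x, k)
    out = col @ w.reshape(cout, cin * k**3).T
    if b is not None:
        out += b
    spatial = x.shape[1:]
    return np.ascontiguousarray(out.T.reshape(cout, *spatial)), col


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded 3D convolution, kernel 1 or 3 cubed."""
    k = w.data.shape[2]
    if x.data.shape[0] != w.data.shape[1]:
        raise ValidationError(
            f"conv3d channel mismatch: input {x.data.shape[0]}, weight expects {w.data.shape[1]}"
        )
    out_data, col = _conv_raw(x.data, w.data, None if b is None else b.data)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def _backward(g: np.ndarray) -> None:
        cout = w.data.shape[0]
        g2 = g.reshape(cout, -1)
        if w.requires_grad or w._parents:
            w._accum((g2 @ col).reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g2.sum(axis=1))
        if _needs(x):
            wt = np.ascontiguousarray(
                w.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
            )
            gx, _ = _conv_raw(g, wt, None)
            x._accum(gx)

    out._backward = _backward
    return out


def conv_transpose2x(x: Tensor, w: Tensor) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (doubles each spatial dim).

    ``w`` is (Cin, Cout, 2, 2, 2).
    """
    cin, cout = w.data.shape[0], w.data.shape[1]
    if x.data.shape[0] != cin:
        raise ValidationError(f"deconv channel mismatch: {x.data.shape[0]} vs {cin}")
    d, h, wd = x.data.shape[1:]
    tmp = np.tensordot(x.data, w.data, axes=([0], [0]))  # (D,H,W, Cout,2,2,2)
    out_data = np.ascontiguousarray(
        tmp.transpose(3, 0, 4, 1, 5, 2, 6)
    ).reshape(cout, 2 * d, 2 * h, 2 * wd)
    out = Tensor(out_data, parents=(x, w))

    def _backward(g: np.ndarray) -> None:
        gt = g.reshape(cout, d, 2, h, 2, wd, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        if w.requires_grad or w._parents:
            w._accum(np.tensordot(x.data, gt, axes=([1, 2, 3], [0, 1, 2])))
        if _needs(x):
            gx = np.tensordot(gt, w.data, axes=([3, 4, 5, 6], [1, 2, 3, 4]))
            x._accum(np.ascontiguousarray(gx.transpose(3, 0, 1, 2)))

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# pooling / pointwise
# ---------------------------------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValidationError(f"maxpool2 needs even extents, got {x.data.shape}")
    blocks = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    blocks = np.ascontiguousarray(blocks.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
        c, d // 2, h // 2, w // 2, 8
    )
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if not _needs(x):
            return
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        x._accum(gb.reshape(c, d, h, w))

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if _needs(x):
            x._accum(g * mask)

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValidationError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    out = Tensor(a.data + b.data, parents=(a, b))

    def _backward(g: np.ndarray) -> None:
        if _needs(a):
            a._accum(g)
        if _needs(b):
            b._accum(g)

    out._backward = _backward
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    if a.data.shape[1:] != b.data.shape[1:]:
        raise ValidationError(f"concat grid mismatch: {a.data.shape} vs {b.data.shape}")
    ca = a.data.shape[0]
    out = Tensor(np.concatenate([a.data, b.data], axis=0), parents=(a, b))

    def _backward(g: np.ndarray) -> None:
        if _needs(a):
            a._accum(g[:ca])
        if _needs(b):
            b._accum(g[ca:])

    out._backward = _backward
    return out


def gate(x: Tensor, factor: np.ndarray) -> Tensor:
    """Multiply by a constant per-voxel factor broadcast over channels."""
    f = np.asarray(factor, dtype=np.float32)
    if f.shape != x.data.shape[1:]:
        raise ValidationError(f"gate grid mismatch: {f.shape} vs {x.data.shape[1:]}")
    out = Tensor(x.data * f[None], parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if _needs(x):
            x._accum(g * f[None])

    out._backward = _backward
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalization over the spatial axes (single sample)."""
    axes = (1, 2, 3)
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        running_mean *= 1 - momentum
        running_mean += momentum * mu[:, 0, 0, 0]
        running_var *= 1 - momentum
        running_var += momentum * var[:, 0, 0, 0]
    else:
        mu = running_mean[:, None, None, None]
        var = running_var[:, None, None, None]
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    out = Tensor(gamma.data[:, None, None, None] * xhat + beta.data[:, None, None, None],
                 parents=(x, gamma, beta))

    def _backward(g: np.ndarray) -> None:
        if gamma.requires_grad or gamma._parents:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents:
            beta._accum(g.sum(axis=axes))
        if _needs(x):
            gam = gamma.data[:, None, None, None]
            if training:
                gm = g.mean(axis=axes, keepdims=True)
                gxm = (g * xhat).mean(axis=axes, keepdims=True)
                x._accum(gam / std * (g - gm - xhat * gxm))
            else:
                x._accum(gam / std * g)

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# heads and losses
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_channels(x: Tensor) -> Tensor:
    """Per-voxel probability over the channel (class) axis."""
    p = _softmax(x.data)
    out = Tensor(p, parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if _needs(x):
            dot = (g * p).sum(axis=0, keepdims=True)
            x._accum(p * (g - dot))

    out._backward = _backward
    return out


def seg_loss(
    logits: Tensor, labels: np.ndarray, w_dice: float = 0.5, w_ce: float = 0.5
) -> Tensor:
    """Composite soft-Dice + cross-entropy loss (fused op, gradient wrt logits).

    ``labels`` are integer class ids on the same grid; every id must be a
    valid class index.
    """
    n_classes = logits.data.shape[0]
    lab = np.asarray(labels)
    if lab.shape != logits.data.shape[1:]:
        raise ValidationError(f"label grid {lab.shape} != logits grid {logits.data.shape[1:]}")
    if lab.min() < 0 or lab.max() >= n_classes:
        raise ValidationError(
            f"label ids span {lab.min()}..{lab.max()}, outside [0, {n_classes})"
        )
    p = _softmax(logits.data)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, lab[None].astype(np.int64), 1.0, axis=0)
    n_vox = lab.size
    eps = 1e-6

    # cross-entropy
    p_t = np.take_along_axis(p, lab[None].astype(np.int64), axis=0)[0]
    ce = float(-np.log(np.maximum(p_t, 1e-12)).mean())

    # soft Dice per class
    flat_p = p.reshape(n_classes, -1)
    flat_g = onehot.reshape(n_classes, -1)
    inter = (flat_p * flat_g).sum(axis=1)
    sums = flat_p.sum(axis=1) + flat_g.sum(axis=1)
    dice_c = (2 * inter + eps) / (sums + eps)
    dice_loss = float(1.0 - dice_c.mean())

    out = Tensor(np.float32(w_ce * ce + w_dice * dice_loss), parents=(logits,))

    def _backward(g: np.ndarray) -> None:
        if not _needs(logits):
            return
        gs = float(g)
        # d(ce)/d logits
        g_logits = (p - onehot) / n_vox * (w_ce * gs)
        # d(dice)/d p_c, then chain through softmax
        dD_dp = (2 * flat_g * (sums + eps)[:, None] - (2 * inter + eps)[:, None]) / (
            (sums + eps) ** 2
        )[:, None]
        g_p = (-(w_dice * gs) / n_classes) * dD_dp.reshape(p.shape)
        dot = (g_p * p).sum(axis=0, keepdims=True)
        g_logits += p * (g_p - dot)
        logits._accum(g_logits)

    out._backward = _backward
    return out


def spatial_softmax(z: np.ndarray) -> np.ndarray:
    """Per-channel softmax over the spatial voxels of a (K, X, Y, Z) array."""
    k = z.shape[0]
    flat = z.reshape(k, -1)
    flat = flat - flat.max(axis=1, keepdims=True)
    e = np.exp(flat)
    return (e / e.sum(axis=1, keepdims=True)).reshape(z.shape)


def heatmap_ce_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Cross-entropy between per-channel spatial softmax and a normalized
    target heatmap.

    Each keypoint channel is treated as a distribution over voxels; the
    Gaussian target is normalized to unit mass per channel.  Unlike a plain
    MSE on sparse heatmaps, the normalization makes every spurious peak
    compete directly with the true one, so the argmax read-out is stable
    even with very few training volumes.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != logits.data.shape:
        raise ValidationError(f"target shape {t.shape} != prediction {logits.data.shape}")
    k = t.shape[0]
    t_flat = t.reshape(k, -1)
    mass = t_flat.sum(axis=1, keepdims=True)
    t_hat = np.where(mass > 0, t_flat / np.maximum(mass, 1e-12), 0.0)
    p = spatial_softmax(logits.data).reshape(k, -1)
    ce = -(t_hat * np.log(np.maximum(p, 1e-12))).sum(axis=1)
    out = Tensor(np.float32(ce.mean()), parents=(logits,))

    def _backward(g: np.ndarray) -> None:
        if _needs(logits):
            grad = (p * t_hat.sum(axis=1, keepdims=True) - t_hat) / k * float(g)
            logits._accum(grad.reshape(logits.data.shape))

    out._backward = _backward
    return out


def heatmap_mse_loss(pred: Tensor, target: np.ndarray, pos_weight: float = 0.0) -> Tensor:
    """(Weighted) mean squared error against fixed target heatmaps.

    ``pos_weight`` > 0 up-weights voxels by
    ``1 + pos_weight * max(target, prediction)`` (the weight itself is
    treated as constant).  Weighting by the target keeps sparse Gaussian
    peaks from being dominated by the all-zero background (the trivial
    minimum); including the prediction makes spurious peaks far from the
    target just as expensive as missed ones, which protects the argmax
    read-out.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.data.shape:
        raise ValidationError(f"target shape {t.shape} != prediction {pred.data.shape}")
    diff = pred.data - t
    w = 1.0 + pos_weight * np.maximum(t, pred.data) if pos_weight else None
    sq = diff**2 if w is None else w * diff**2
    out = Tensor(np.float32(sq.mean()), parents=(pred,))

    def _backward(g: np.ndarray) -> None:
        if _needs(pred):
            gd = (2.0 / diff.size) * diff * float(g)
            pred._accum(gd if w is None else gd * w)

    out._backward = _backward
    return out
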