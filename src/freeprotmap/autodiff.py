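"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the distance-map network needs:
broadcast arithmetic, (batched) matmul, 3x3 "same" convolution, 2x2/stride-2
transposed convolution, 2x2 max pooling with implicit right/bottom zero
padding, softmax, sigmoid, relu, abs and reductions.  Everything runs in
float64; there is no device abstraction and no batching beyond what numpy
broadcasting provides (the training batch size is one protein).

Graph construction is skipped for subtrees in which no tensor requires a
gradient, so freezing a network stage prunes its backward pass automatically.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            )

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
                gb = (a.data * g[..., None]).reshape(-1, b.data.shape[0]).sum(0) \
                    if a.data.ndim > 1 else a.data * g
                return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
            if a.data.ndim == 1:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.multiply.outer(a.data, g) if g.ndim == 1 else \
                    np.einsum("i,...j->...ij", a.data, g)
                return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        shape = self.shape

        def backward(g):
            gx = np.zeros(shape)
            gx[idx] = g
            return (gx,)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad(self, pad_width):
        """Zero-pad; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple(tuple(p) for p in pad_width)
        slices = tuple(
            slice(p[0], p[0] + s) for p, s in zip(pw, self.shape)
        )
        return Tensor._make(
            np.pad(self.data, pw), (self,), lambda g: (g[slices],)
        )

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return Tensor._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def exp(self):
        y = np.exp(self.data)
        return Tensor._make(y, (self,), lambda g: (g * y,))

    def abs(self):
        s = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * s,))

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._make(y, (self,), backward)

    # -- spatial ops on (C, H, W) maps --------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None):
        """Stride-1 'same' 2-D convolution; self is (C_in, H, W)."""
        x, w = self, weight
        c_in, h, wd = x.shape
        c_out, c_in_w, kh, kw = w.shape
        if c_in != c_in_w:
            raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # (C, H, W, kh, kw) -> (C*kh*kw, H*W)
        colmat = win.transpose(0, 3, 4, 1, 2).reshape(c_in * kh * kw, h * wd)
        w2 = w.data.reshape(c_out, c_in * kh * kw)
        out = (w2 @ colmat).reshape(c_out, h, wd)
        if bias is not None:
            out = out + bias.data.reshape(c_out, 1, 1)

        def backward(g):
            g2 = g.reshape(c_out, h * wd)
            gw = (g2 @ colmat.T).reshape(w.shape)
            gcol = (w2.T @ g2).reshape(c_in, kh, kw, h, wd)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for b in range(kw):
                    gxp[:, a:a + h, b:b + wd] += gcol[:, a, b]
            gx = gxp[:, ph:ph + h, pw:pw + wd]
            if bias is not None:
                return (gx, gw, g.sum(axis=(1, 2)))
            return (gx, gw)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._make(out, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor" = None):
        """2x2 kernel, stride-2 transposed convolution; self is (C_in, h, w).

        weight is (C_in, C_out, 2, 2); output is (C_out, 2h, 2w).
        """
        x, w = self, weight
        c_in, h, wd = x.shape
        c_in_w, c_out = w.shape[0], w.shape[1]
        if c_in != c_in_w:
            raise ValueError(f"channel mismatch: input {c_in}, weight {c_in_w}")
        out5 = np.einsum("chw,cdab->dhawb", x.data, w.data)
        out = out5.reshape(c_out, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(c_out, 1, 1)

        def backward(g):
            gr = g.reshape(c_out, h, 2, wd, 2)
            gx = np.einsum("cdab,dhawb->chw", w.data, gr)
            gw = np.einsum("chw,dhawb->cdab", x.data, gr)
            if bias is not None:
                return (gx, gw, g.sum(axis=(1, 2)))
            return (gx, gw)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._make(out, parents, backward)

    def maxpool2d(self):
        """2x2/stride-2 max pooling, padding odd sides with -inf (never chosen
        unless a window is pure padding, which a 1-pixel pad cannot produce)."""
        c, h, w = self.shape
        ph, pw = h % 2, w % 2
        xp = np.pad(
            self.data, ((0, 0), (0, ph), (0, pw)), constant_values=-np.inf
        )
        h2, w2 = (h + ph) // 2, (w + pw) // 2
        win = xp.reshape(c, h2, 2, w2, 2).transpose(0, 1, 3, 2, 4).reshape(
            c, h2, w2, 4
        )
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gwin = np.zeros((c, h2, w2, 4))
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gxp = gwin.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(
                c, h + ph, w + pw
            )
            return (gxp[:, :h, :w],)

        return Tensor._make(out, (self,), backward)

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf with requires_grad
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )
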