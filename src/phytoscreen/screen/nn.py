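"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based Tensor with exactly the operators the drug-target model
needs: broadcast add/mul, (batched) matmul, ReLU, sigmoid, softmax,
axis reductions, reshape/transpose, embedding gather, 1-D convolution,
and a numerically stable binary cross-entropy on logits.  Gradients are
accumulated by topological sort; correctness is pinned down by central
finite-difference checks in the test suite.

Everything is float64-or-float32 deterministic on one device; there is
no graph optimisation and no GPU path — problem sizes here are desk
scale by design.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo, visited = [], set()

        def build(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # closures reference their output tensor: break the cycles so the
        # tape is freed by reference counting, not delayed gc
        for t in topo:
            t._backward = None
            t._parents = ()

    def clear_graph(self):
        """Drop the tape below this tensor (for forward-only evaluation)."""
        stack, visited = [self], set()
        while stack:
            t = stack.pop()
            if id(t) in visited:
                continue
            visited.add(id(t))
            stack.extend(t._parents)
            t._backward = None
            t._parents = ()

    # -- elementwise ---------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    # -- linear algebra ------------------------------------------------
    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # stacked @ matrix: one large GEMM instead of per-slice calls
            k = a.shape[-1]
            y = (a.reshape(-1, k) @ b).reshape(a.shape[:-1] + (b.shape[1],))
            out = Tensor(y, self.requires_grad or other.requires_grad, (self, other))

            def bw():
                g2 = out.grad.reshape(-1, b.shape[1])
                if self.requires_grad:
                    self._accum((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accum(a.reshape(-1, k).T @ g2)

            out._backward = bw
            return out

        out = Tensor(a @ b, self.requires_grad or other.requires_grad, (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape))

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self):
        s = np.empty_like(self.data)
        pos = self.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        s[~pos] = e / (1.0 + e)
        out = Tensor(s, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1 - s))

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = bw
        return out

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out._backward = bw
        return out

    # -- lookup / convolution --------------------------------------------
    def gather_rows(self, idx: np.ndarray):
        """out[..., :] = self[idx[...], :] — embedding lookup."""
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx.ravel(), out.grad.reshape(-1, self.data.shape[-1]))
                self._accum(g)

        out._backward = bw
        return out

    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """'Same'-padded 1-D convolution.

        self: (B, L, Cin); weight: (K, Cin, Cout); bias: (Cout,).
        """
        B, L, Cin = self.data.shape
        K, _, Cout = weight.data.shape
        left = (K - 1) // 2
        xp = np.pad(self.data, ((0, 0), (left, K - 1 - left), (0, 0)))
        # im2col: one large matmul instead of K small ones
        windows = np.lib.stride_tricks.sliding_window_view(xp, L, axis=1)
        # windows: (B, K, Cin, L) -> xcol (B, L, K*Cin)
        xcol = np.ascontiguousarray(windows.transpose(0, 3, 1, 2)).reshape(B * L, K * Cin)
        wr = weight.data.reshape(K * Cin, Cout)
        y = (xcol @ wr).reshape(B, L, Cout) + bias.data
        out = Tensor(
            y,
            self.requires_grad or weight.requires_grad or bias.requires_grad,
            (self, weight, bias),
        )

        def bw():
            g = out.grad
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = xcol.T @ g.reshape(-1, Cout)
                weight._accum(gw.reshape(K, Cin, Cout))
            if self.requires_grad:
                gxcol = (g.reshape(-1, Cout) @ wr.T).reshape(B, L, K, Cin)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, k : k + L, :] += gxcol[:, :, k, :]
                self._accum(gxp[:, left : left + L, :])

        out._backward = bw
        return out

    # -- losses -----------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray):
        """Mean binary cross-entropy on raw logits (stable softplus form)."""
        z, y = self.data, np.asarray(targets, dtype=self.data.dtype)
        softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
        loss = (softplus - y * z).mean()
        out = Tensor(np.asarray(loss), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
                self._accum(out.grad * (p - y) / z.size)

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def constant(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
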