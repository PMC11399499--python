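"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Implements exactly the operations the GCN link predictor needs: dense and
constant-left matmul, row gather, batched outer products, 3×3 same-padding
convolution (im2col), global average pooling, relu, dropout, and a
numerically stable binary cross-entropy on logits.  Parameters are updated
with Adam plus L2 weight decay (decay added to the gradient, the classic
Adam-with-weight-decay formulation).

Deliberately minimal: single-threaded, no broadcasting rules
beyond what the model uses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "bce_with_logits", "DTYPE"]

#: Compute precision of the engine.  Single precision is plenty for SGD
#: training and halves memory traffic; flip to float64 when checking
#: gradients against finite differences.
DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._backward = lambda: None
        self._prev = tuple(prev)
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # -- ops ----------------------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _backward
        return out

    def left_matmul(self, const: np.ndarray) -> "Tensor":
        """A @ self with A a constant matrix (e.g. normalized adjacency)."""
        out = Tensor(const @ self.data, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(const.T @ out.grad)

        out._backward = _backward
        return out

    def add(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (out.data > 0))

        out._backward = _backward
        return out

    def mul_mask(self, mask: np.ndarray) -> "Tensor":
        """Elementwise product with a constant array (dropout masks)."""
        out = Tensor(self.data * mask, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out._backward = _backward
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        out = Tensor(self.data[idx], (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    # -- graph-specific composites ------------------------------------------

    @staticmethod
    def outer_batch(src: "Tensor", dst: "Tensor") -> "Tensor":
        """Batched outer product: (B×d, B×d) → B×d×d."""
        out = Tensor(
            np.einsum("bi,bj->bij", src.data, dst.data), (src, dst)
        )

        def _backward():
            if src.requires_grad:
                src._accum(np.einsum("bij,bj->bi", out.grad, dst.data))
            if dst.requires_grad:
                dst._accum(np.einsum("bij,bi->bj", out.grad, src.data))

        out._backward = _backward
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """3×3 (or k×k) same-padding stride-1 convolution, B×C×H×W."""
        B, C, H, W = self.data.shape
        O, Cw, kh, kw = weight.data.shape
        assert C == Cw
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = _im2col(xp, kh, kw, H, W)  # B, C*kh*kw, H*W
        wmat = weight.data.reshape(O, C * kh * kw)
        y = np.matmul(wmat, cols).reshape(B, O, H, W)
        y += bias.data[None, :, None, None]
        out = Tensor(y, (self, weight, bias))

        def _backward():
            go = out.grad.reshape(B, O, H * W)
            if bias.requires_grad:
                bias._accum(go.sum(axis=(0, 2)))
            if weight.requires_grad:
                gw = go.transpose(1, 0, 2).reshape(O, -1) @ \
                    cols.transpose(0, 2, 1).reshape(-1, C * kh * kw)
                weight._accum(gw.reshape(weight.data.shape))
            if self.requires_grad:
                gcols = np.matmul(wmat.T, go)
                gx = _col2im(gcols, (B, C, H + 2 * ph, W + 2 * pw), kh, kw, H, W)
                self._accum(gx[:, :, ph : ph + H, pw : pw + W])

        out._backward = _backward
        return out

    def global_avg_pool(self) -> "Tensor":
        """Mean over the two trailing spatial axes: B×C×H×W → B×C."""
        B, C, H, W = self.data.shape
        out = Tensor(self.data.mean(axis=(2, 3)), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(
                    np.broadcast_to(
                        out.grad[:, :, None, None] / (H * W), self.data.shape
                    )
                )

        out._backward = _backward
        return out

    # -- autodiff ------------------------------------------------------------

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        seen.add(id(self))
        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _im2col(xp: np.ndarray, kh: int, kw: int, H: int, W: int) -> np.ndarray:
    B, C = xp.shape[:2]
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (B, C, kh, kw, H, W), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return view.reshape(B, C * kh * kw, H * W)


def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int, H: int, W: int):
    B, C, Hp, Wp = xshape
    gx = np.zeros(xshape, dtype=cols.dtype)
    cols = cols.reshape(B, C, kh, kw, H, W)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + H, j : j + W] += cols[:, :, i, j]
    return gx


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (log-sum-exp stabilized)."""
    z = logits.data
    y = np.asarray(targets, dtype=float)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), (logits,))

    def _backward():
        if logits.requires_grad:
            p = _sigmoid(z)
            logits._accum(out.grad * (p - y) / y.size)

    out._backward = _backward
    return out


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 0.005,
                 weight_decay: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
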