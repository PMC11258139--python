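"""Minimal 3D neural-network layers with explicit forward/backward passes.

All layers operate on single samples shaped ``(channels, z, y, x)`` in
float32; mini-batching is realized by gradient accumulation in the training
loop. 3x3x3 convolutions are evaluated as one im2col GEMM whose column
matrix is assembled from *contiguous* slices of the flattened padded volume
(see :func:`_flat_conv3`), keeping both the arithmetic and the memory
traffic efficient on a single BLAS thread; large scratch buffers are pooled
per layer because faulting fresh pages in dominates otherwise.

Normalization follows batch-norm semantics at batch size one: per-sample
spatial statistics during training, running statistics at evaluation. Using
running statistics at inference keeps the network a fixed function of its
input, which the overlap-tile stitching relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv3d", "ConvTranspose3d", "Norm3d", "ELU", "MaxPool2",
    "avg_downsample", "AdamW",
]

_OFFSETS3 = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]
_OFFSETS2 = [(dz, dy, dx) for dz in range(2) for dy in range(2) for dx in range(2)]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data.astype(np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class _BufferPool:
    """Reusable named scratch arrays (large buffers are expensive to fault in)."""

    def __init__(self) -> None:
        self._bufs: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...]) -> np.ndarray:
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._bufs[name] = buf
        return buf


def _flat_conv3(x: np.ndarray, wmat: np.ndarray, bias: np.ndarray | None,
                keep_col: bool, pool: _BufferPool, tag: str
                ) -> tuple[np.ndarray, np.ndarray | None]:
    """'Same' 3x3x3 convolution of a (c, d, h, w) volume as one GEMM.

    The padded volume is flattened; each of the 27 neighborhood offsets is
    then a *contiguous* slice of the flat array, so the im2col matrix is
    assembled with plain memcpys. The GEMM is evaluated over the contiguous
    base range (which includes some out-of-frame positions) and the valid
    (d, h, w) block is cropped out afterwards.

    ``wmat`` has shape (cout, 27*c) in offset-major layout. Returns the
    output and, if ``keep_col``, the column matrix (27*c, L) whose first
    ``base(z,y,x) = z*Hp*Wp + y*Wp + x`` entries align with flat padded
    positions (needed for the weight gradient).
    """
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    dp, hp, wp = d + 2, h + 2, w + 2
    vp = dp * hp * wp
    max_off = 2 * hp * wp + 2 * wp + 2
    ell = vp - max_off
    xf = xp.reshape(c, vp)
    col3 = pool.get(f"{tag}.col", (27, c, ell))
    for o, (dz, dy, dx) in enumerate(_OFFSETS3):
        off = dz * hp * wp + dy * wp + dx
        col3[o] = xf[:, off:off + ell]
    col = col3.reshape(27 * c, ell)
    cout = wmat.shape[0]
    out_flat = np.matmul(wmat, col, out=pool.get(f"{tag}.of", (cout, ell)))
    if bias is not None:
        out_flat += bias[:, None]
    out_buf = pool.get(f"{tag}.ob", (cout, vp))
    out_buf[:, :ell] = out_flat
    out = np.ascontiguousarray(out_buf.reshape(cout, dp, hp, wp)[:, :d, :h, :w])
    return out, (col if keep_col else None)


class Conv3d:
    """3x3x3 (or 1x1x1) convolution, stride 1, zero padding 'same'.

    Evaluated as a single flat-shift im2col GEMM; the input gradient is the
    'same' correlation with the flipped kernel, evaluated the same way.
    """

    def __init__(self, name: str, cin: int, cout: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        if k not in (1, 3):
            raise ValueError("only 1x1x1 and 3x3x3 kernels are supported")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, size=(k ** 3, cout, cin)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._col: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self._pool = _BufferPool()
        self.need_input_grad = True

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _wmat(self) -> np.ndarray:
        return np.ascontiguousarray(
            self.w.data.transpose(1, 0, 2).reshape(self.cout, 27 * self.cin))

    def _wback(self) -> np.ndarray:
        return np.ascontiguousarray(
            self.w.data[::-1].transpose(2, 0, 1).reshape(self.cin, 27 * self.cout))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, d, h, w = x.shape
        if self.k == 1:
            out = (self.w.data[0] @ x.reshape(c, -1)) + self.b.data[:, None]
            if train:
                self._x = x
            return out.reshape(self.cout, d, h, w)
        out, col = _flat_conv3(x, self._wmat(), self.b.data, keep_col=train,
                               pool=self._pool, tag="fwd")
        if train:
            self._col = col
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        cout, d, h, w = g.shape
        if self.k == 1:
            gf = g.reshape(cout, -1)
            self.b.grad += gf.sum(axis=1)
            x = self._x
            self.w.grad[0] += gf @ x.reshape(self.cin, -1).T
            gx = self.w.data[0].T @ gf
            self._x = None
            return gx.reshape(self.cin, d, h, w)
        self.b.grad += g.sum(axis=(1, 2, 3))
        # place g at the valid positions of the flat base range, zeros elsewhere
        dp, hp, wp = d + 2, h + 2, w + 2
        vp = dp * hp * wp
        ell = self._col.shape[1]
        gbuf = self._pool.get("gb", (cout, vp))
        gbuf.fill(0.0)
        gbuf.reshape(cout, dp, hp, wp)[:, :d, :h, :w] = g
        gw = gbuf[:, :ell] @ self._col.T  # (cout, 27*cin)
        self.w.grad += gw.reshape(cout, 27, self.cin).transpose(1, 0, 2)
        self._col = None
        if not self.need_input_grad:
            return np.zeros((self.cin, d, h, w), dtype=np.float32)
        gx, _ = _flat_conv3(np.ascontiguousarray(g), self._wback(), None,
                            keep_col=False, pool=self._pool, tag="bwd")
        return gx


class ConvTranspose3d:
    """2x2x2 transpose convolution with stride 2 (doubles each spatial axis)."""

    def __init__(self, name: str, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        scale = np.sqrt(2.0 / cin)
        self.w = Param(f"{name}.w", rng.normal(0.0, scale, size=(8, cout, cin)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, d, h, w = x.shape
        v = d * h * w
        xf = x.reshape(c, v)
        out = np.empty((self.cout, 2 * d, 2 * h, 2 * w), dtype=np.float32)
        for o, (dz, dy, dx) in enumerate(_OFFSETS2):
            piece = self.w.data[o] @ xf + self.b.data[:, None]
            out[:, dz::2, dy::2, dx::2] = piece.reshape(self.cout, d, h, w)
        if train:
            self._x = xf
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        d2, h2, w2 = g.shape[1:]
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        gx = np.zeros((self.cin, d * h * w), dtype=np.float32)
        for o, (dz, dy, dx) in enumerate(_OFFSETS2):
            go = np.ascontiguousarray(g[:, dz::2, dy::2, dx::2]).reshape(self.cout, -1)
            self.b.grad += go.sum(axis=1)
            self.w.grad[o] += go @ self._x.T
            gx += self.w.data[o].T @ go
        self._x = None
        return gx.reshape(self.cin, d, h, w)


class Norm3d:
    """Channel-wise normalization over spatial dimensions.

    Training uses the current sample's statistics and updates running
    estimates (momentum 0.1); evaluation uses the running estimates, so the
    layer is affine and input-independent at inference time.
    """

    def __init__(self, name: str, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, d, h, w = x.shape
        xf = x.reshape(c, -1)
        if train:
            mean = xf.mean(axis=1)
            var = xf.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mean[:, None]) * inv_std[:, None]
        out = self.gamma.data[:, None] * xhat + self.beta.data[:, None]
        if train:
            self._cache = (xhat, inv_std.astype(np.float32))
        return np.asarray(out.reshape(c, d, h, w), dtype=np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = g.shape
        gf = g.reshape(c, -1)
        xhat, inv_std = self._cache
        self._cache = None
        self.beta.grad += gf.sum(axis=1)
        self.gamma.grad += (gf * xhat).sum(axis=1)
        n = gf.shape[1]
        gm = gf.mean(axis=1, keepdims=True)
        gxm = (gf * xhat).mean(axis=1, keepdims=True)
        gx = (self.gamma.data[:, None] * inv_std[:, None]) * (gf - gm - xhat * gxm)
        return gx.reshape(c, d, h, w).astype(np.float32)


class ELU:
    """Exponential linear unit, alpha = 1."""

    def __init__(self) -> None:
        self._y: np.ndarray | None = None
        self._pos: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, np.expm1(np.minimum(x, 0.0))).astype(np.float32)
        if train:
            self._y, self._pos = y, pos
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = np.where(self._pos, g, g * (self._y + 1.0)).astype(np.float32)
        self._y = self._pos = None
        return gx


class MaxPool2:
    """2x2x2 max pooling (stride 2); spatial sizes must be even."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        return (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
                .transpose(0, 1, 3, 5, 2, 4, 6)
                .reshape(c, d // 2, h // 2, w // 2, 8))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        blocks = self._blocks(x)
        if train:
            self._idx = blocks.argmax(axis=-1)
            self._shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        blocks = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(blocks, self._idx[..., None], g[..., None], axis=-1)
        out = (blocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
               .transpose(0, 1, 4, 2, 5, 3, 6)
               .reshape(c, d, h, w))
        self._idx = self._shape = None
        return out


def avg_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool a (c, z, y, x) volume by an integer factor per axis."""
    c, d, h, w = x.shape
    f = factor
    if d % f or h % f or w % f:
        raise ValueError(f"shape {x.shape[1:]} not divisible by factor {f}")
    return x.reshape(c, d // f, f, h // f, f, w // f, f).mean(axis=(2, 4, 6))


class AdamW:
    """AdamW optimizer with decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
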