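"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the reconstruction and segmentation
networks need: elementwise arithmetic, ReLU/sigmoid, 2D convolution
(im2col + GEMM), 2x average pooling / nearest upsampling, concatenation,
reductions, and a differentiable hard k-space data-consistency layer.
All tensors are float32 in channels-last (B, H, W, C) layout; im2col
patch matrices are rebuilt during backward rather than cached, keeping
peak memory flat across long unrolled graphs.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import sgemm

_ALLOCATOR_TUNED = False


def tune_allocator() -> None:
    """Raise glibc's mmap/trim thresholds for large-buffer recycling.

    The unrolled training graphs allocate and free many multi-megabyte
    arrays; with default thresholds glibc returns them to the kernel on
    every free and each reallocation pays the page-fault cost again.
    No-op on non-glibc platforms.
    """
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 512 * 1024 * 1024)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 512 * 1024 * 1024)  # M_TRIM_THRESHOLD
        _ALLOCATOR_TUNED = True
    except Exception:
        pass


__all__ = ["Tensor", "conv2d", "avg_pool2", "upsample2", "concat", "stack",
           "sep_filter2d_valid", "kspace_consistency", "sense_consistency",
           "no_grad", "tune_allocator"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev_state = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev_state
        return False


class Tensor:
    """Array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        if not _grad_enabled:
            _prev = ()
            requires_grad = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _register(self, fn) -> None:
        # only wire the closure into the graph when a grad path exists;
        # otherwise the closure would pin every intermediate in memory
        if self.requires_grad:
            self._backward = fn

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        # ``own=True`` promises g is a freshly allocated float32 array the
        # caller will not reuse, so it can be adopted without a copy
        if self.grad is None:
            if own and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; recursion would overflow on long recurrent graphs
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()
            if node._prev:
                # interior node: its grad is fully consumed and the closure
                # cycle (node -> closure -> node) would defer collection of
                # multi-megabyte buffers to the cyclic GC; break it now
                node.grad = None
                node._backward = None
                node._prev = ()

    # -- elementwise arithmetic -------------------------------------------
    def _as_tensor(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._register(_bw)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape), own=True)

        out._register(_bw)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._as_tensor(other))

    def __rsub__(self, other):
        return self._as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = self._as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0), own=True)

        out._register(_bw)
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0), own=True)

        out._register(_bw)
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(s, _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s), own=True)

        out._register(_bw)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data, own=True)

        out._register(_bw)
        return out

    # -- reductions & shaping ----------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(np.broadcast_to(out.grad, self.data.shape))

        out._register(_bw)
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._register(_bw)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[idx] = out.grad
                self._accum(g, own=True)

        out._register(_bw)
        return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the shape of its source."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Convolution (channels-last: B, H, W, C)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad the two spatial axes of a (B, H, W, C) array."""
    if p == 0:
        return np.ascontiguousarray(x)
    b, h, w, c = x.shape
    out = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
    out[:, p:-p, p:-p, :] = x
    return out


def _shift_gemm(xp: np.ndarray, wm: np.ndarray, ho: int, wo: int,
                bias: np.ndarray | None = None) -> np.ndarray:
    """Correlation of padded (B, Hp, Wp, Cin) input with (k, k, Cin, Cout)
    weights as k*k shifted GEMMs accumulated in place (BLAS beta=1)."""
    k = wm.shape[0]
    c_in, c_out = wm.shape[2], wm.shape[3]
    bs = xp.shape[0]
    m = bs * ho * wo
    y = np.empty((m, c_out), dtype=np.float32)
    if bias is None:
        y[:] = 0.0
    else:
        y[:] = bias
    scratch = np.empty((bs, ho, wo, c_in), dtype=np.float32)
    flat = scratch.reshape(m, c_in)
    for di in range(k):
        for dj in range(k):
            np.copyto(scratch, xp[:, di:di + ho, dj:dj + wo, :])
            # y.T (F-contiguous view) <- wm.T @ scratch.T + y.T, in place
            sgemm(1.0, wm[di, dj].T, flat.T, beta=1.0, c=y.T, overwrite_c=1)
    return y.reshape(bs, ho, wo, c_out)


def _shift_gemm_dw(xp: np.ndarray, dmat: np.ndarray, k: int, ho: int,
                   wo: int) -> np.ndarray:
    """Weight gradient of the shifted-GEMM correlation."""
    bs, _, _, c_in = xp.shape
    c_out = dmat.shape[1]
    m = bs * ho * wo
    dw = np.zeros((k, k, c_in, c_out), dtype=np.float32)
    scratch = np.empty((bs, ho, wo, c_in), dtype=np.float32)
    flat = scratch.reshape(m, c_in)
    for di in range(k):
        for dj in range(k):
            np.copyto(scratch, xp[:, di:di + ho, dj:dj + wo, :])
            # dw[di,dj].T <- dmat.T @ scratch (trans_b resolves layouts)
            sgemm(1.0, dmat.T, flat.T, beta=1.0, c=dw[di, dj].T,
                  trans_b=1, overwrite_c=1)
    return dw


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           pad: int | None = None) -> Tensor:
    """2D cross-correlation on (B, H, W, C) input with (k, k, C, O) weights.

    ``pad=None`` means 'same' padding for odd kernels; ``pad=0`` is valid
    correlation.  The input gradient is a full correlation with the
    spatially flipped, channel-transposed kernel.
    """
    k, _, c_in, c_out = w.data.shape
    if pad is None:
        pad = (k - 1) // 2
    bs, h, ww = x.data.shape[:3]
    ho, wo = h + 2 * pad - k + 1, ww + 2 * pad - k + 1
    xp = _pad_hw(x.data, pad)
    y = _shift_gemm(xp, w.data, ho, wo,
                    bias=None if b is None else b.data)
    out = Tensor(y, _prev=(x, w) if b is None else (x, w, b))

    def _bw():
        dout = out.grad
        dmat = dout.reshape(-1, c_out)
        if b is not None and b.requires_grad:
            b._accum(dmat.sum(axis=0))
        if w.requires_grad:
            w._accum(_shift_gemm_dw(xp, dmat, k, ho, wo), own=True)
        if x.requires_grad:
            wflip = np.ascontiguousarray(
                w.data[::-1, ::-1].transpose(0, 1, 3, 2))
            dop = _pad_hw(dout, k - 1)
            dxp = _shift_gemm(dop, wflip, h + 2 * pad, ww + 2 * pad)
            if pad:
                dxp = np.ascontiguousarray(dxp[:, pad:-pad, pad:-pad, :])
            x._accum(dxp, own=True)

    out._register(_bw)
    return out


def sep_filter2d_valid(x: Tensor, g: np.ndarray) -> Tensor:
    """Valid-region separable symmetric filtering of a (B, H, W, 1) batch.

    Used for the Gaussian-window statistics of the SSIM loss; the kernel
    is fixed (no kernel gradient).  With a symmetric tap vector the
    adjoint is the same filter applied to the zero-embedded gradient.
    """
    from scipy.ndimage import correlate1d

    g = np.asarray(g, dtype=np.float32)
    r = len(g) // 2

    def filt(a: np.ndarray) -> np.ndarray:
        y = correlate1d(a, g, axis=1, mode="constant")
        y = correlate1d(y, g, axis=2, mode="constant")
        return y[:, r:-r, r:-r, :]

    out = Tensor(filt(x.data), _prev=(x,))

    def _bw():
        if x.requires_grad:
            bs, ho, wo, c = out.grad.shape
            emb = np.zeros((bs, ho + 2 * r, wo + 2 * r, c), dtype=np.float32)
            emb[:, r:-r, r:-r, :] = out.grad
            x._accum(filt(_pad_hw(emb, r)), own=True)

    out._register(_bw)
    return out


# ---------------------------------------------------------------------------
# Pooling / resampling / concatenation
# ---------------------------------------------------------------------------

def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 on (B, H, W, C) input."""
    b, h, w, c = x.data.shape
    y = x.data.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    out = Tensor(y, _prev=(x,))

    def _bw():
        if x.requires_grad:
            g = np.repeat(np.repeat(out.grad, 2, axis=1), 2, axis=2) * 0.25
            x._accum(g)

    out._register(_bw)
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling on (B, H, W, C) input."""
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out = Tensor(y, _prev=(x,))

    def _bw():
        if x.requires_grad:
            b, h, w, c = out.grad.shape
            g = out.grad.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
            x._accum(g)

    out._register(_bw)
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw():
        offset = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(offset, offset + n)
                t._accum(out.grad[tuple(sl)])
            offset += n

    out._register(_bw)
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def _bw():
        grads = np.moveaxis(out.grad, axis, 0)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accum(g)

    out._register(_bw)
    return out


# ---------------------------------------------------------------------------
# Hard data consistency (differentiable)
# ---------------------------------------------------------------------------

def _to_complex(two_channel: np.ndarray) -> np.ndarray:
    return two_channel[..., 0] + 1j * two_channel[..., 1]


def _cfft2(z: np.ndarray) -> np.ndarray:
    """Centered orthonormal FFT in single precision (trailing two axes)."""
    from scipy import fft as sfft
    return np.fft.fftshift(
        sfft.fft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho",
                  workers=1), axes=(-2, -1))


def _cifft2(z: np.ndarray) -> np.ndarray:
    from scipy import fft as sfft
    return np.fft.fftshift(
        sfft.ifft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho",
                   workers=1), axes=(-2, -1))


def kspace_consistency(x: Tensor, sampled_kspace: np.ndarray,
                       row_mask: np.ndarray) -> Tensor:
    """Hard k-space data consistency on a 2-channel (real, imag) image batch.

    The predicted image is transformed to k-space (centered, orthonormal),
    the acquired phase lines are overwritten with the measured data, and
    the result is transformed back.  The map is complex-linear and unitary
    off the sampled lines, so the adjoint used in backward is the same
    projection with the measured data replaced by zero.

    Parameters
    ----------
    x:
        (B, H, W, 2) tensor, last axis = (real, imag).
    sampled_kspace:
        (B, H, W) complex measured k-space (values off retained lines are
        ignored).
    row_mask:
        Boolean retained-line indicator, shape (H,) or per-item (B, H).
    """
    m = np.asarray(row_mask, dtype=bool)[..., None]  # (H,1) or (B,H,1)
    z = _to_complex(x.data).astype(np.complex64)
    k = _cfft2(z)
    k = np.where(m, sampled_kspace.astype(np.complex64), k)
    img = _cifft2(k)
    out = Tensor(np.stack([img.real, img.imag], axis=-1), _prev=(x,))

    def _bw():
        if x.requires_grad:
            gz = _to_complex(out.grad).astype(np.complex64)
            gk = _cfft2(gz)
            gk = np.where(m, 0.0, gk)
            gi = _cifft2(gk)
            x._accum(np.ascontiguousarray(
                np.stack([gi.real, gi.imag], axis=-1), dtype=np.float32),
                own=True)

    out._register(_bw)
    return out


def sense_consistency(x: Tensor, sampled_kspace: np.ndarray,
                      row_mask: np.ndarray, sens: np.ndarray) -> Tensor:
    """Per-coil hard data consistency through known coil sensitivities.

    The 2-channel (B, H, W, 2) prediction is a coil-combined image ``z``;
    each coil's
    predicted k-space ``F(S_c z)`` has its acquired lines overwritten with
    the measured per-coil data, and the result is recombined as
    ``sum_c conj(S_c) * F^-1(...)``.  With RSS-normalized sensitivities
    this is an affine self-adjoint map, so backward applies the same
    operator with the measured data zeroed.

    ``sampled_kspace`` has shape (B, C, H, W) and ``sens`` (C, H, W).
    """
    m = np.asarray(row_mask, dtype=bool)[..., None]

    def project(z: np.ndarray, measured: np.ndarray) -> np.ndarray:
        k = _cfft2((z[:, None, :, :] * sens[None]).astype(np.complex64))
        k = np.where(m, measured.astype(np.complex64), k)
        return np.sum(np.conj(sens)[None] * _cifft2(k), axis=1)

    z = _to_complex(x.data)
    img = project(z, sampled_kspace)
    out = Tensor(np.stack([img.real, img.imag], axis=-1), _prev=(x,))

    def _bw():
        if x.requires_grad:
            gz = _to_complex(out.grad)
            gi = project(gz, np.zeros_like(sampled_kspace))
            x._accum(np.ascontiguousarray(
                np.stack([gi.real, gi.imag], axis=-1), dtype=np.float32),
                own=True)

    out._register(_bw)
    return out
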