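"""Cross-shaped kernel masks for multilead ECG convolution.

A 12-lead ECG laid out as a leads x time grid has a 4-neighbourhood
dependence structure: a sample correlates with adjacent samples on the same
lead (different times) and with other leads at the same time, but not with
different leads at different times.  Restricting each k x k convolution
kernel to the cross through its centre (centre row = same lead across time,
centre column = same time across leads) encodes exactly this structure and
removes the diagonal weights a dense kernel would learn.

Two readings of the cross are provided:

``full_cross``
    all positions on the centre row and centre column (2k - 1 weights for a
    k x k kernel).  This is the default — it keeps kernel sizes above 3
    meaningful.
``strict_n4``
    only the centre and its four orthogonal neighbours (5 weights for any
    k >= 3), the literal 4-neighbourhood.

The two coincide at k = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("full_cross", "strict_n4")


@dataclass
class CrossKernelMask:
    kernel_size: tuple
    mode: str = "full_cross"
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        kh, kw = self.kernel_size
        if self.mask is None:
            self.mask = _make_mask(kh, kw, self.mode)
        self.mask = np.asarray(self.mask, dtype=np.float64)

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())


def _make_mask(kh: int, kw: int, mode: str) -> np.ndarray:
    if kh < 1 or kw < 1 or kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(
            f"kernel dims must be odd positive integers, got ({kh}, {kw})")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ch, cw = kh // 2, kw // 2
    mask = np.zeros((kh, kw))
    if mode == "full_cross":
        mask[ch, :] = 1.0
        mask[:, cw] = 1.0
    else:  # strict_n4: centre + 4 orthogonal neighbours
        mask[ch, cw] = 1.0
        for dh, dw in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            h, w = ch + dh, cw + dw
            if 0 <= h < kh and 0 <= w < kw:
                mask[h, w] = 1.0
    return mask


def build_mask(kernel_size, mode: str = "full_cross") -> CrossKernelMask:
    """Build the binary trainability mask for a k_h x k_w kernel."""
    kh, kw = kernel_size
    return CrossKernelMask(kernel_size=(kh, kw), mode=mode,
                           mask=_make_mask(kh, kw, mode))


def effective_weight_count(kernel_size, mode: str, in_channels: int,
                           out_channels: int) -> int:
    """Trainable kernel-weight count: active mask positions x in x out."""
    return build_mask(kernel_size, mode).n_active * in_channels * out_channels


def conv2d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   stride: int = 1, padding: int = 0,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """2-D cross-correlation of ``x`` (n, C, H, W) with ``weight``
    (O, C, kh, kw), optionally restricted to the mask's active positions.

    Implemented as a sum of shifted tensor contractions over the active
    kernel offsets only — numerically identical to a dense convolution with
    ``weight * mask`` but touching just the cross positions.
    """
    n, c, h, w = x.shape
    o, c2, kh, kw = weight.shape
    if c != c2:
        raise ValueError(f"input has {c} channels but weight expects {c2}")
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"kernel ({kh}, {kw}) larger than padded input ({h + 2 * padding},"
            f" {w + 2 * padding})")
    out = np.zeros((n, o, ho, wo))
    offsets = _active_offsets(kh, kw, mask)
    for di, dj in offsets:
        xs = xp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride]
        out += np.einsum("ncij,oc->noij", xs, weight[:, :, di, dj],
                         optimize=True)
    if bias is not None:
        out += bias[None, :, None, None]
    return out


def conv2d_backward(x: np.ndarray, weight: np.ndarray, dout: np.ndarray,
                    stride: int = 1, padding: int = 0,
                    mask: np.ndarray | None = None):
    """Gradients (dx, dweight, dbias) of :func:`conv2d_forward`."""
    n, c, h, w = x.shape
    o, _, kh, kw = weight.shape
    _, _, ho, wo = dout.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(weight)
    for di, dj in _active_offsets(kh, kw, mask):
        xs = xp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride]
        dw[:, :, di, dj] = np.einsum("noij,ncij->oc", dout, xs, optimize=True)
        dxp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride] += \
            np.einsum("noij,oc->ncij", dout, weight[:, :, di, dj],
                      optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    if padding:
        dx = dxp[:, :, padding:padding + h, padding:padding + w]
    else:
        dx = dxp
    return dx, dw, db


def _active_offsets(kh: int, kw: int, mask: np.ndarray | None):
    if mask is None:
        return [(i, j) for i in range(kh) for j in range(kw)]
    ii, jj = np.nonzero(np.asarray(mask))
    return list(zip(ii.tolist(), jj.tolist()))


def masked_conv2d(x: np.ndarray, weight: np.ndarray, mask: CrossKernelMask,
                  bias: np.ndarray | None = None, stride: int = 1,
                  padding: int = 0) -> np.ndarray:
    """Functional masked convolution: weights outside the cross are ignored
    (equivalently, multiplied by zero) before a standard convolution."""
    return conv2d_forward(x, weight, bias, stride=stride, padding=padding,
                          mask=mask.mask)
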