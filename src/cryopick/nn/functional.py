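"""Pure-numpy convolution kernels used by the autodiff ops.

All routines work on NCHW float arrays. Forward convolution is im2col +
batched matmul; the input gradient is computed as a zero-stuffed
convolution with the spatially flipped, channel-swapped kernel, which is
also what the transposed-convolution forward pass uses.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _im2col(xp, kh, kw, stride, dil):
    """Sliding patches of an already padded array. Returns a view."""
    b, c, h, w = xp.shape
    sh, sw = _pair(stride)
    dh, dw = _pair(dil)
    oh = (h - dh * (kh - 1) - 1) // sh + 1
    ow = (w - dw * (kw - 1) - 1) // sw + 1
    s0, s1, s2, s3 = xp.strides
    shape = (b, c, kh, kw, oh, ow)
    strides = (s0, s1, s2 * dh, s3 * dw, s2 * sh, s3 * sw)
    return as_strided(xp, shape=shape, strides=strides), oh, ow


def _shift_views(xp, kh, kw, stride, dil, oh, ow):
    sh, sw = _pair(stride)
    dh, dw = _pair(dil)
    for i in range(kh):
        for j in range(kw):
            yield i, j, xp[
                :, :,
                i * dh : i * dh + (oh - 1) * sh + 1 : sh,
                j * dw : j * dw + (ow - 1) * sw + 1 : sw,
            ]


def conv2d_forward(x, w, stride=1, padding=0, dilation=1, groups=1):
    b, cin, _, _ = x.shape
    cout, cg, kh, kw = w.shape
    if cin != cg * groups:
        raise ValueError(f"channel mismatch: x has {cin}, kernel expects {cg * groups}")
    ph, pw = _pair(padding)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    dh, dw = _pair(dilation)
    sh, sw = _pair(stride)
    oh = (xp.shape[2] - dh * (kh - 1) - 1) // sh + 1
    ow = (xp.shape[3] - dw * (kw - 1) - 1) // sw + 1
    if groups == cin and cg == 1 and cout == cin:
        # depthwise: per-channel broadcast multiply, no contraction
        out = np.zeros((b, cout, oh, ow), dtype=x.dtype)
        for i, j, xv in _shift_views(xp, kh, kw, stride, dilation, oh, ow):
            out += w[None, :, 0, i, j, None, None] * xv
        return out
    if groups == 1:
        # shift-and-accumulate: avoids the large im2col copy
        out = np.zeros((b, cout, oh, ow), dtype=x.dtype)
        for i, j, xv in _shift_views(xp, kh, kw, stride, dilation, oh, ow):
            # (o,c) x (b,c,h,w) -> (o,b,h,w), accumulated as (b,o,h,w)
            out += np.tensordot(w[:, :, i, j], xv, axes=([1], [1])).transpose(
                1, 0, 2, 3
            )
        return out
    cols, oh, ow = _im2col(xp, kh, kw, stride, dilation)
    # (b, g, cg*kh*kw, oh*ow)
    cols = np.ascontiguousarray(cols).reshape(b, groups, cg * kh * kw, oh * ow)
    wg = w.reshape(groups, cout // groups, cg * kh * kw)
    out = np.matmul(wg, cols)  # (b, g, cout/g, oh*ow)
    return out.reshape(b, cout, oh, ow)


def conv2d_weight_grad(gout, x, wshape, stride=1, padding=0, dilation=1, groups=1):
    b = x.shape[0]
    cout, cg, kh, kw = wshape
    ph, pw = _pair(padding)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    oh, ow = gout.shape[2], gout.shape[3]
    if groups == cout and cg == 1 and cout == x.shape[1]:
        gw = np.empty(wshape, dtype=x.dtype)
        for i, j, xv in _shift_views(xp, kh, kw, stride, dilation, oh, ow):
            gw[:, 0, i, j] = np.einsum("bchw,bchw->c", gout, xv, optimize=True)
        return gw
    if groups == 1:
        gw = np.empty(wshape, dtype=x.dtype)
        for i, j, xv in _shift_views(xp, kh, kw, stride, dilation, oh, ow):
            gw[:, :, i, j] = np.tensordot(
                gout, xv, axes=([0, 2, 3], [0, 2, 3])
            )
        return gw
    cols, oh, ow = _im2col(xp, kh, kw, stride, dilation)
    cols = np.ascontiguousarray(cols).reshape(b, groups, cg * kh * kw, oh * ow)
    gg = gout.reshape(b, groups, cout // groups, oh * ow)
    # sum over batch and spatial positions
    gw = np.einsum("bgon,bgkn->gok", gg, cols)
    return gw.reshape(wshape).astype(x.dtype, copy=False)


def _stuff_and_pad(g, stride, pad_t, pad_b, pad_l, pad_r):
    """Insert stride-1 zeros between grad elements and pad the borders."""
    b, c, h, w = g.shape
    sh, sw = _pair(stride)
    out = np.zeros(
        (b, c, (h - 1) * sh + 1 + pad_t + pad_b, (w - 1) * sw + 1 + pad_l + pad_r),
        dtype=g.dtype,
    )
    out[:, :, pad_t : pad_t + (h - 1) * sh + 1 : sh,
        pad_l : pad_l + (w - 1) * sw + 1 : sw] = g
    return out


def _flip_swap(w, groups):
    """Spatially flip the kernel and swap in/out channels within each group."""
    cout, cg, kh, kw = w.shape
    wg = w.reshape(groups, cout // groups, cg, kh, kw)
    wf = wg[:, :, :, ::-1, ::-1].transpose(0, 2, 1, 3, 4)
    return np.ascontiguousarray(wf).reshape(groups * cg, cout // groups, kh, kw)


def conv2d_input_grad(gout, w, xshape, stride=1, padding=0, dilation=1, groups=1):
    _, _, h, wdt = xshape
    _, _, kh, kw = w.shape
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    sh, sw = _pair(stride)
    oh, ow = gout.shape[2], gout.shape[3]
    # residual rows/cols the forward stride skipped at the bottom/right
    extra_h = (h + 2 * ph - dh * (kh - 1) - 1) - (oh - 1) * sh
    extra_w = (wdt + 2 * pw - dw * (kw - 1) - 1) - (ow - 1) * sw
    pt = dh * (kh - 1) - ph
    pl = dw * (kw - 1) - pw
    if pt < 0 or pl < 0:
        raise ValueError("padding larger than receptive field is unsupported")
    stuffed = _stuff_and_pad(gout, stride, pt, pt + extra_h, pl, pl + extra_w)
    wf = _flip_swap(w, groups)
    gx = conv2d_forward(stuffed, wf, stride=1, padding=0, dilation=dilation,
                        groups=groups)
    return gx[:, :, :h, :wdt]


def conv_transpose2d_forward(x, w, stride=1, padding=0, dilation=1, groups=1,
                             out_hw=None):
    """Transposed convolution: the adjoint of conv2d_forward.

    ``w`` uses conv2d layout (cout, cin/groups, kh, kw) mapping the
    *output* of the corresponding forward conv back to its input; here x
    plays the role of that output.
    """
    _, _, kh, kw = w.shape
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    sh, sw = _pair(stride)
    h_in, w_in = x.shape[2], x.shape[3]
    if out_hw is None:
        out_hw = (
            (h_in - 1) * sh - 2 * ph + dh * (kh - 1) + 1,
            (w_in - 1) * sw - 2 * pw + dw * (kw - 1) + 1,
        )
    cg = w.shape[1]
    xshape = (x.shape[0], cg * groups, out_hw[0], out_hw[1])
    return conv2d_input_grad(x, w, xshape, stride, padding, dilation, groups)
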