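"""Depthwise / pointwise convolution primitives.

The depthwise stage convolves each channel with its own kernel and never
mixes channels:

    DepthConv(V_c, X[:, :, c])(i, j) = sum_{k, l} V_c(k, l) * X(i+k, j+l, c)

(valid positions only). The pointwise stage stacks the per-channel outputs
at every spatial location and applies a learned 1x1 cross-channel mix —
the factorization underlying ConvNeXt blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def depthwise_conv(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid depthwise convolution.

    Parameters
    ----------
    x : (H, W, C) array
    kernels : (C, K, L) array, one kernel per channel

    Returns
    -------
    (H-K+1, W-L+1, C) array; channels never mix.
    """
    if x.ndim != 3 or kernels.ndim != 3:
        raise ValueError("x must be (H, W, C) and kernels (C, K, L)")
    C, K, L = kernels.shape
    if x.shape[2] != C:
        raise ValueError(f"channel mismatch: input has {x.shape[2]}, kernels have {C}")
    if K > x.shape[0] or L > x.shape[1]:
        raise ValueError(f"kernel {K}x{L} larger than input {x.shape[0]}x{x.shape[1]}")
    win = sliding_window_view(x, (K, L), axis=(0, 1))  # (Ho, Wo, C, K, L)
    return np.einsum("ijckl,ckl->ijc", win, kernels, optimize=True)


def pointwise_stack(
    x: np.ndarray, kernels: np.ndarray, mix: np.ndarray | None = None
) -> np.ndarray:
    """Depthwise outputs stacked per location, then a 1x1 cross-channel mix.

    With ``mix=None`` the identity mix is used, i.e. the result is just the
    channel-stacked depthwise output.
    """
    stacked = depthwise_conv(x, kernels)
    if mix is None:
        return stacked
    mix = np.asarray(mix, dtype=float)
    if mix.shape[0] != stacked.shape[2]:
        raise ValueError(f"mix matrix rows {mix.shape[0]} != channels {stacked.shape[2]}")
    return stacked @ mix
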