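"""Pluggable denoisers for regularization by denoising (RED).

A denoiser maps a complex length-N vector to a denoised vector of the same
length.  The vector is reshaped to a small two-channel (real, imaginary)
image on a configured ``rows x cols`` layout, denoised per channel, and
flattened back.  RED is denoiser-agnostic, so anything with roughly
symmetric Jacobian and local homogeneity works here; the package ships
``identity``, ``median`` and ``total_variation``, plus an ``external``
hook for a user-supplied network.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle

__all__ = ["get_denoiser", "DENOISERS"]


def _to_image(h: np.ndarray, layout: tuple) -> np.ndarray:
    rows, cols = layout
    return np.stack(
        [h.real.reshape(rows, cols), h.imag.reshape(rows, cols)], axis=-1
    )


def _from_image(img: np.ndarray) -> np.ndarray:
    return (img[..., 0] + 1j * img[..., 1]).ravel()


def identity(h: np.ndarray, layout: tuple, strength: float) -> np.ndarray:
    return np.asarray(h, dtype=complex).copy()


def median(h: np.ndarray, layout: tuple, strength: float) -> np.ndarray:
    img = _to_image(np.asarray(h, dtype=complex), layout)
    size = max(2, int(round(strength))) if strength >= 2 else 3
    out = np.empty_like(img)
    for c in range(2):
        out[..., c] = ndimage.median_filter(img[..., c], size=size, mode="reflect")
    return _from_image(out)


def total_variation(h: np.ndarray, layout: tuple, strength: float) -> np.ndarray:
    """Channel-coupled TV (Chambolle) on the scale-normalized image."""
    h = np.asarray(h, dtype=complex)
    scale = np.sqrt(np.mean(np.abs(h) ** 2))
    if scale == 0:
        return h.copy()
    img = _to_image(h / scale, layout)
    out = denoise_tv_chambolle(img, weight=strength, channel_axis=-1)
    return _from_image(out) * scale


DENOISERS = {
    "identity": identity,
    "median": median,
    "total_variation": total_variation,
}


def get_denoiser(name_or_fn):
    """Resolve a denoiser name (or pass a callable through)."""
    if callable(name_or_fn):
        return name_or_fn
    try:
        return DENOISERS[name_or_fn]
    except KeyError:
        raise ValueError(
            f"unknown denoiser {name_or_fn!r}; choose from {sorted(DENOISERS)} "
            "or pass a callable(h, layout, strength)"
        ) from None
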