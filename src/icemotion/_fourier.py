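"""Shared DFT frequency-grid helpers (cycles/pixel, unshifted layout)."""

from __future__ import annotations

import numpy as np


def freq_grid(shape: tuple[int, int]):
    """Return (fy, fx) meshgrids in cycles/pixel for an unshifted 2D DFT."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.broadcast_to(fy, shape), np.broadcast_to(fx, shape)


def freq_radius(shape: tuple[int, int]) -> np.ndarray:
    """|u| in cycles/pixel on the unshifted 2D DFT grid."""
    fy, fx = freq_grid(shape)
    return np.hypot(fy, fx)


def freq_azimuth(shape: tuple[int, int]) -> np.ndarray:
    """Azimuth angle of each DFT sample, radians in (-pi, pi]."""
    fy, fx = freq_grid(shape)
    return np.arctan2(fy, fx)


def hermitian_white(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """FFT of a unit white real field, scaled to unit per-mode variance.

    The result is Hermitian-symmetric, so any real, elementwise filtering of
    it inverse-transforms to a real image.
    """
    w = np.fft.fft2(rng.standard_normal(shape))
    return w / np.sqrt(w.size)
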