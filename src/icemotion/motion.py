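"""Gaussian-Markov model of beam-induced molecular motion.

Radiolysis randomly rearranges water molecules: after a fluence of n e-/A^2
each molecule's displacement is an isotropic 3D Gaussian with per-axis
variance n * sigma0^2, accumulating independently over successive fluence
increments (a Markov process in fluence, not time).  A Fourier component of
the projected structure at spatial frequency u then decorrelates
exponentially with fluence at rate

    alpha_u = 2 pi^2 sigma0^2 u^2      (per e-/A^2),

which yields closed forms for the expected power spectrum of any frame sum
and for the growth of the block-summed ring signal,

    g(z) = (z + exp(-z) - 1)/z,   z = alpha_u * (block fluence).

All fluences entering this module are in e-/A^2 (pixel doses are converted
by pixel area beforehand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionModel",
    "SpectralParams",
    "alpha_u",
    "displace",
    "frame_correlation",
    "spectrum_discrete",
    "spectrum_continuous",
    "g_of_z",
    "block_curve_model",
]


@dataclass(frozen=True)
class MotionModel:
    """Per-axis mean-squared displacement per unit fluence, A^2/(e-/A^2)."""

    sigma0_sq: float

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0:
            raise ValueError("sigma0_sq must be >= 0")


@dataclass(frozen=True)
class SpectralParams:
    """Decorrelation rate and per-frame structure power at one frequency."""

    alpha_u: float
    F0_sq: float

    def __post_init__(self) -> None:
        if self.alpha_u < 0 or self.F0_sq < 0:
            raise ValueError("alpha_u and F0_sq must be >= 0")


def alpha_u(u, sigma0_sq: float):
    """Spectral decorrelation rate 2 pi^2 sigma0^2 u^2 per unit fluence."""
    return 2.0 * np.pi**2 * sigma0_sq * np.asarray(u, dtype=float) ** 2


def displace(
    positions: np.ndarray,
    fluence: float,
    model: MotionModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random-walk step: add i.i.d. Gaussian increments per axis.

    Per-axis variance is ``fluence * sigma0_sq``; successive calls add
    independent increments (the Markov property), so two steps of D/2 are
    distributed like one step of D.
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    positions = np.asarray(positions, dtype=float)
    if fluence == 0 or model.sigma0_sq == 0:
        return positions.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd = np.sqrt(fluence * model.sigma0_sq)
    return positions + rng.normal(0.0, sd, size=positions.shape)


def frame_correlation(u, i: int, j: int, d: float, model: MotionModel):
    """Expected Fourier correlation exp(-alpha_u |i-j| d) between frames.

    ``d`` is the fluence per frame in e-/A^2; frames are 1-indexed.
    """
    if i < 1 or j < 1:
        raise ValueError("frame indices are 1-based")
    if d <= 0:
        raise ValueError("fluence per frame must be positive")
    return np.exp(-alpha_u(u, model.sigma0_sq) * abs(i - j) * d)


def _sum_factor(a, M: int):
    """sum_{i,j=1..M} exp(-a |i-j|) evaluated stably; a = alpha_u * d.

    Closed form 2 e^-a (1-e^-a)^-2 [(1-e^-a) M + e^-aM - 1] + M, with a
    direct O(M) summation when a is small enough for the closed form to
    lose precision to cancellation.
    """
    a = np.asarray(a, dtype=float)
    small = a < 1e-6
    out = np.empty_like(a)
    if np.any(small):
        k = np.arange(1, M)
        ak = np.multiply.outer(a[small], k)
        out[small] = M + 2.0 * np.sum((M - k) * np.exp(-ak), axis=-1)
    if np.any(~small):
        ab = a[~small]
        e = np.exp(-ab)
        em1 = -np.expm1(-ab)  # 1 - e^-a
        out[~small] = 2.0 * e / em1**2 * (em1 * M + np.expm1(-ab * M)) + M
    return out


def spectrum_discrete(u, M: int, d: float, model: MotionModel, F0_sq: float):
    """Expected power spectrum of an M-frame sum under frame-to-frame motion.

    Each frame contributes power d^2 F0(u)^2 and frames i, j correlate as
    exp(-alpha_u |i-j| d); summing the M x M covariance gives

        S(u) = d^2 F0^2 [ 2 e^-ad (1-e^-ad)^-2 {(1-e^-ad) M + e^-adM - 1} + M ]

    with the limits M^2 d^2 F0^2 (no motion) and M d^2 F0^2 (uncorrelated
    frames).  A single frame (M=1) carries its full power regardless of
    sigma0^2.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if d <= 0:
        raise ValueError("fluence per frame must be positive")
    a = alpha_u(u, model.sigma0_sq) * d
    scalar = np.isscalar(u) or np.ndim(u) == 0
    fac = _sum_factor(np.atleast_1d(a), M)
    out = d * d * F0_sq * fac
    return float(out[0]) if scalar else out.reshape(np.shape(a))


def spectrum_continuous(u, D_total: float, model: MotionModel, F0_sq: float):
    """Continuous-exposure limit: S(u) = 2 F0^2 [aD + e^-aD - 1] / a^2.

    The M -> infinity, Md = D limit of :func:`spectrum_discrete`; behaves
    as D^2 F0^2 for aD << 1 and 2 D F0^2 / alpha_u for aD >> 1.
    """
    if D_total < 0:
        raise ValueError("total fluence must be >= 0")
    a = alpha_u(u, model.sigma0_sq)
    z = a * D_total
    # 2(z + e^-z - 1)/z^2 == 2 g(z)/z -> 1 as z -> 0
    return D_total**2 * F0_sq * _two_g_over_z(z)


def _two_g_over_z(z):
    """2 (z + e^-z - 1) / z^2, series-stable near z = 0."""
    z = np.asarray(z, dtype=float)
    small = z < 1e-4
    out = np.empty_like(z)
    zs = z[small]
    out[small] = 1.0 - zs / 3.0 + zs**2 / 12.0
    zb = z[~small]
    out[~small] = 2.0 * (zb + np.expm1(-zb)) / zb**2
    return out if out.ndim else float(out)


def g_of_z(z):
    """Saturation function g(z) = (z + e^-z - 1)/z of the block-sum signal.

    Monotone increasing from 0 (as z/2 for small z) to 1; evaluated by its
    Taylor series below z = 1e-4 to avoid cancellation.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.empty_like(z)
    small = z < 1e-4
    zs = z[small]
    out[small] = zs / 2.0 - zs**2 / 6.0 + zs**3 / 24.0
    zb = z[~small]
    out[~small] = (zb + np.expm1(-zb)) / zb
    return float(out[0]) if scalar else out


def block_curve_model(m, M: int, d: float, alpha: float, scale: float):
    """Expected W_{M,m} ring contribution, scale * g(alpha * m * d).

    ``d`` is fluence per frame (e-/A^2) and ``alpha`` the decorrelation
    rate at the target frequency.  ``scale`` absorbs 2 D_tot/alpha_u, the
    electron optics, thickness envelope and structure amplitude, so the
    shape in m carries all the motion information; M enters only through
    that absorbed total exposure.
    """
    if d <= 0:
        raise ValueError("fluence per frame must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    del M  # absorbed into scale; kept for interface symmetry
    return scale * g_of_z(alpha * np.asarray(m, dtype=float) * d)
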