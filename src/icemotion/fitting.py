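"""Estimation of the motion parameter and its downstream consequences.

The block-sum ring signal W_{M,m} at a chosen frequency u grows with block
fluence as scale * g(alpha_u m d).  A two-parameter weighted fit of that
form recovers alpha_u and hence sigma0^2 = alpha_u / (2 pi^2 u^2).  From
sigma0^2 follow: the block fluence maximising ring signal-to-noise (the
stationary point of g(z)/sqrt(z), since noise grows as sqrt(m)), the
3D mean-squared displacement rate 3 sigma0^2, and the Brownian blurring of
embedded macromolecules via Stokes-Einstein scaling of the diffusion
coefficient with molecular weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, least_squares

from .motion import alpha_u as alpha_of_u
from .motion import g_of_z
from .spectra import BlockSeries

__all__ = [
    "MotionFit",
    "ParticleBlurParams",
    "FitFailure",
    "fit_sigma0",
    "snr_optimum_z",
    "optimal_dose",
    "msd_3d_rate",
    "rms_displacement",
    "particle_rms",
    "blur_bfactor",
]


class FitFailure(RuntimeError):
    """Raised when the motion fit does not converge."""


@dataclass
class MotionFit:
    """Result of the block-sum motion fit.

    ``sigma0_sq`` is in A^2 per e-/A^2 (per axis); ``scale`` in the same
    arbitrary units as the fitted series.  ``covariance`` is the 2x2
    (sigma0_sq, scale) covariance propagated from the weighted Jacobian.
    """

    sigma0_sq: float
    scale: float
    covariance: np.ndarray
    residual_norm: float
    n_points: int
    identifiable: bool = True
    message: str = ""

    @property
    def sigma0_sq_err(self) -> float:
        return float(np.sqrt(max(self.covariance[0, 0], 0.0)))


@dataclass(frozen=True)
class ParticleBlurParams:
    """Inputs for extrapolating water motion to an embedded particle."""

    molecular_weight: float  # Da
    fluence: float = 25.0  # e-/A^2, a typical single-particle exposure
    diffusion_ratio: float | None = None  # D_water/D_particle override

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.fluence < 0:
            raise ValueError("fluence must be >= 0")
        if self.diffusion_ratio is not None and self.diffusion_ratio <= 0:
            raise ValueError("diffusion_ratio must be positive")

    @property
    def ratio(self) -> float:
        """D_water/D_particle; defaults to the (MW/18)^(1/3) size rule."""
        if self.diffusion_ratio is not None:
            return self.diffusion_ratio
        return (self.molecular_weight / 18.0) ** (1.0 / 3.0)


def fit_sigma0(series: BlockSeries, u_target: float | None = None) -> MotionFit:
    """Weighted nonlinear fit of scale * g(2 pi^2 sigma0^2 u^2 m d).

    Weights are 1/error^2 with the series' analytic error bars.  Both
    parameters are fitted in log space (positivity); a coarse log-grid scan
    over sigma0^2 in [1e-3, 10] seeds a local least-squares refinement, so
    the result is deterministic in the inputs.  The covariance comes from
    the Jacobian at the optimum, mapped back to linear parameters.

    A series consistent with zero signal everywhere is flagged
    unidentifiable (warning; ``identifiable=False`` and the grid lower
    bound is reported).
    """
    u = series.u_target if u_target is None else u_target
    y = np.asarray(series.value, dtype=float)
    err = np.asarray(series.error, dtype=float)
    dose = np.asarray(series.block_dose, dtype=float)  # m*d, e-/A^2
    if len(y) < 3:
        raise ValueError("need at least 3 block sizes to fit")

    if np.all(np.abs(y) < 2.0 * err):
        warnings.warn(
            "fit_sigma0: no significant ring signal at any block size; "
            "sigma0_sq is unidentifiable (reporting the scan lower bound)",
            stacklevel=2,
        )
        return MotionFit(
            sigma0_sq=1e-3,
            scale=0.0,
            covariance=np.full((2, 2), np.inf),
            residual_norm=float(np.sum((y / err) ** 2)),
            n_points=len(y),
            identifiable=False,
            message="zero signal",
        )

    w = 1.0 / err**2

    def model_g(s0sq):
        return g_of_z(alpha_of_u(u, s0sq) * dose)

    # Coarse scan with the scale profiled out linearly.
    best = None
    for s0sq in np.geomspace(1e-3, 10.0, 60):
        gv = model_g(s0sq)
        denom = float(np.sum(w * gv * gv))
        if denom <= 0:
            continue
        sc = float(np.sum(w * y * gv)) / denom
        if sc <= 0:
            continue
        chi2 = float(np.sum(w * (y - sc * gv) ** 2))
        if best is None or chi2 < best[0]:
            best = (chi2, s0sq, sc)
    if best is None:
        raise FitFailure("no admissible starting point (non-positive scale)")

    def resid(p):
        s0sq, sc = np.exp(p)
        return (y - sc * model_g(s0sq)) / err

    res = least_squares(
        resid, np.log([best[1], best[2]]), method="lm", max_nfev=5000
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitFailure(
            f"motion fit did not converge (status {res.status}): {res.message}"
        )
    s0sq, sc = np.exp(res.x)
    jtj = res.jac.T @ res.jac
    try:
        cov_log = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov_log = np.full((2, 2), np.inf)
    jac_lin = np.diag([s0sq, sc])  # d(log x) -> dx
    cov = jac_lin @ cov_log @ jac_lin
    identifiable = np.isfinite(cov[0, 0]) and np.sqrt(cov[0, 0]) < 10.0 * s0sq
    if not identifiable:
        warnings.warn(
            "fit_sigma0: sigma0_sq poorly constrained (flat series; only "
            "the product with the scale is identified)",
            stacklevel=2,
        )
    return MotionFit(
        sigma0_sq=float(s0sq),
        scale=float(sc),
        covariance=cov,
        residual_norm=float(np.sum(res.fun**2)),
        n_points=len(y),
        identifiable=bool(identifiable),
    )


@lru_cache(maxsize=1)
def snr_optimum_z() -> float:
    """Block fluence (in units of 1/alpha_u) maximising ring SNR.

    The signal grows as g(z) while the noise grows as sqrt(z), so the SNR
    g(z)/sqrt(z) is stationary where 1.5 - 0.5 z = e^-z (z + 1.5); the
    bracketed root is 2.1491...
    """
    f = lambda z: 1.5 - 0.5 * z - np.exp(-z) * (z + 1.5)
    return float(brentq(f, 0.1, 10.0, xtol=1e-12))


def optimal_dose(sigma0_sq: float, u: float) -> float:
    """Optimal electrons per unit area per image, z* / (2 pi^2 sigma0^2 u^2).

    For sigma0^2 = 0.37 A^2/(e-/A^2) at u = 1/3.7 A^-1 this is 4.0 e-/A^2.
    """
    if sigma0_sq <= 0 or u <= 0:
        raise ValueError("sigma0_sq and u must be positive")
    return snr_optimum_z() / float(alpha_of_u(u, sigma0_sq))


def msd_3d_rate(sigma0_sq: float) -> float:
    """Total 3D mean-squared displacement per unit fluence, 3 sigma0^2."""
    if sigma0_sq < 0:
        raise ValueError("sigma0_sq must be >= 0")
    return 3.0 * sigma0_sq


def rms_displacement(fluence: float, msd_rate: float) -> float:
    """RMS 3D displacement sqrt(fluence * msd_rate) in Angstrom."""
    if fluence < 0 or msd_rate < 0:
        raise ValueError("fluence and msd_rate must be >= 0")
    return float(np.sqrt(fluence * msd_rate))


def particle_rms(water_rms: float, params: ParticleBlurParams) -> float:
    """RMS displacement of an embedded particle from the water RMS.

    Mean-squared displacement scales with the diffusion coefficient, so the
    RMS scales with sqrt(D_particle/D_water) = 1/sqrt(ratio).  The ratio is
    ``params.diffusion_ratio`` when supplied, else the Stokes-Einstein size
    rule (MW/18)^(1/3).
    """
    if water_rms < 0:
        raise ValueError("water_rms must be >= 0")
    return water_rms / np.sqrt(params.ratio)


def blur_bfactor(particle_rms_value: float) -> float:
    """Debye-Waller B-factor of isotropic Gaussian blur, 8 pi^2 <u_x^2>.

    The per-axis positional variance is rms^2/3 (isotropic convention;
    B-factor conventions differ by up to 3x, so this one is stated here
    once and used everywhere).
    """
    if particle_rms_value < 0:
        raise ValueError("particle_rms must be >= 0")
    return 8.0 * np.pi**2 * particle_rms_value**2 / 3.0
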