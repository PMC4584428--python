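"""Electron-optical quantities for Thon-ring work.

Conventions (used consistently across the package):

* Spatial frequencies ``u`` are in 1/Angstrom, lengths in Angstrom.
* Defocus is positive for underfocus.
* The phase-contrast transfer function is ``-[sqrt(1-A^2) sin(gamma)
  + A cos(gamma)]`` with ``gamma = pi*lambda*df(theta)*u^2
  - (pi/2)*Cs*lambda^3*u^4``, so Thon-ring maxima appear as bright rings
  in power spectra of underfocused images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsModel",
    "ThicknessModel",
    "electron_wavelength",
    "ctf",
    "ctf_power_thick",
    "thickness_envelope",
    "first_node_thickness",
    "node_frequency",
    "thickness_from_burnthrough",
]


def electron_wavelength(voltage: float) -> float:
    """Relativistic electron wavelength in Angstrom for ``voltage`` in kV.

    Uses lambda = 12.2643 / sqrt(V (1 + 0.97845e-6 V)) with V in volts.
    300 kV gives 0.019688 A.
    """
    if voltage <= 0:
        raise ValueError(f"voltage must be positive, got {voltage}")
    v = float(voltage) * 1e3
    return 12.2643 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass(frozen=True)
class OpticsModel:
    """Imaging parameters of a defocused bright-field exposure.

    Parameters
    ----------
    voltage
        Accelerating voltage in kV.
    defocus
        Mean defocus in Angstrom, positive for underfocus.
    astig_amplitude
        Astigmatic defocus half-difference in Angstrom (>= 0).
    astig_angle
        Azimuth of the astigmatism major axis in radians.
    spherical_aberration
        Cs in mm.  Defaults to 0: at ~7000 A defocus and u <= 1/2 A^-1 the
        Cs term is secondary.
    amplitude_contrast
        Amplitude-contrast fraction A in [0, 1); 0 for pure ice.
    """

    voltage: float = 300.0
    defocus: float = 7070.0
    astig_amplitude: float = 0.0
    astig_angle: float = 0.0
    spherical_aberration: float = 0.0
    amplitude_contrast: float = 0.0

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if self.astig_amplitude < 0:
            raise ValueError("astig_amplitude must be >= 0")
        if not 0.0 <= self.amplitude_contrast < 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1)")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in Angstrom."""
        return electron_wavelength(self.voltage)


@dataclass(frozen=True)
class ThicknessModel:
    """Sample thickness and the defocus-spread phase parameter it implies."""

    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    def xi(self, u, wavelength: float):
        """Dimensionless xi = pi * lambda * u^2 * t at frequency ``u``."""
        return np.pi * wavelength * np.asarray(u, dtype=float) ** 2 * self.thickness


def _aberration_phase(u, theta, optics: OpticsModel):
    """Wave-aberration phase gamma(u, theta) at the mean defocus."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("spatial frequency must be >= 0")
    theta = np.asarray(theta, dtype=float)
    lam = optics.wavelength
    df = optics.defocus + optics.astig_amplitude * np.cos(
        2.0 * (theta - optics.astig_angle)
    )
    cs = optics.spherical_aberration * 1e7  # mm -> Angstrom
    return np.pi * lam * df * u**2 - 0.5 * np.pi * cs * lam**3 * u**4


def ctf(u, theta, optics: OpticsModel):
    """Phase-contrast transfer function at frequency ``u`` and azimuth ``theta``.

    Astigmatism enters through the azimuthal defocus
    ``df(theta) = defocus + astig_amplitude * cos 2(theta - astig_angle)``.
    Returns values in [-1, 1]; the u=0 limit is ``-A``.
    """
    gamma = _aberration_phase(u, theta, optics)
    a = optics.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(gamma) + a * np.cos(gamma))


def ctf_power_thick(u, theta, optics: OpticsModel, thickness: float | None = None):
    """Squared CTF averaged incoherently over sample height.

    Molecules at height z in a film of thickness t see defocus
    ``defocus + z``; adding their Thon-ring power incoherently averages
    ctf^2 over z, which damps only the oscillatory part:

        <ctf^2> = 1/2 [1 - ((1-2A^2) cos 2gamma - 2A sqrt(1-A^2) sin 2gamma)
                       * sin(xi)/xi],   xi = pi lambda u^2 t.

    ``thickness=None`` is the thin-sample limit (exactly ctf^2).  This is
    the power transfer the simulators use: total ring power survives a
    thick film even when the ring *modulation* is strongly damped.
    """
    gamma = _aberration_phase(u, theta, optics)
    a = optics.amplitude_contrast
    if thickness is None:
        env = 1.0
    else:
        env = thickness_envelope(u, thickness, optics.wavelength)
    osc = (1.0 - 2.0 * a * a) * np.cos(2.0 * gamma) - 2.0 * a * np.sqrt(
        1.0 - a * a
    ) * np.sin(2.0 * gamma)
    return 0.5 * (1.0 - osc * env)


def thickness_envelope(u, t: float, wavelength: float):
    """Defocus-spread damping sin(xi)/xi with xi = pi*lambda*u^2*t.

    Molecules at different heights in a film of thickness ``t`` see
    different defocus, so their Thon-ring oscillations dephase; the
    circularly-averaged modulation is damped by this sinc factor.
    Equals 1 at u = 0 and first crosses zero at xi = pi.
    """
    if t <= 0:
        raise ValueError("thickness must be positive")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("spatial frequency must be >= 0")
    # np.sinc(x) = sin(pi x)/(pi x)
    return np.sinc(wavelength * u**2 * t)


def first_node_thickness(u: float, wavelength: float) -> float:
    """Thickness at which the first sinc node falls at frequency ``u``.

    Inverts xi = pi lambda u^2 t = pi, i.e. t = 1/(lambda u^2).  A film
    showing no node in its Thon-ring modulation out to ``u`` must be
    thinner than this.
    """
    if u <= 0:
        raise ValueError("spatial frequency must be positive")
    return 1.0 / (wavelength * u * u)


def node_frequency(t: float, wavelength: float) -> float:
    """Spatial frequency of the first sinc node for thickness ``t``.

    u = 1/sqrt(lambda t); inverse of :func:`first_node_thickness`.
    """
    if t <= 0:
        raise ValueError("thickness must be positive")
    return 1.0 / np.sqrt(wavelength * t)


def thickness_from_burnthrough(n_images: float, fluence_per_image: float) -> float:
    """Ice thickness estimated from radiolytic burn-through.

    300 keV irradiation removes ~100 A of ice per 170 e-/A^2, so the number
    of images needed to burn through a film times the fluence per image
    gives its thickness as ``total_fluence * 100/170`` Angstrom.
    """
    if n_images <= 0 or fluence_per_image <= 0:
        raise ValueError("n_images and fluence_per_image must be positive")
    return n_images * fluence_per_image * (100.0 / 170.0)
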