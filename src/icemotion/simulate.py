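"""Synthetic dose-fractionated movies of amorphous ice.

Two generators produce movies with the statistical structure the analysis
assumes:

* :func:`simulate_movie_particle` — the physics oracle.  Point scatterers
  with hard-core structure random-walk between (sub-)frames; each frame is
  a weak-contrast bright-field image of the projected density, filtered by
  the thickness-averaged squared CTF, then passed through the stochastic
  detector.
* :func:`simulate_movie_spectral` — the fast generator.  Each Fourier
  component of the structure evolves as a stationary Gauss-Markov
  (Ornstein-Uhlenbeck) process in accumulated fluence with decorrelation
  rate alpha_u = 2 pi^2 sigma0^2 u^2.  By default each frame records the
  exact *window average* of that process over the frame's fluence — the
  continuous-motion situation of a real exposure, for which the block-sum
  saturation model scale*g(alpha_u m d) is exact.  With
  ``frame_integration=False`` frames are instantaneous snapshots, the
  regime described by the discrete frame-sum covariance formula.

Both share :class:`SimConfig`, whose defaults reproduce the source
acquisition geometry (1.04 A pixels, 300 kV, 7070 A underfocus,
2.33 e-/pixel/frame, DQE(0)=0.5) at a desk-scale 256 x 256 field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._fourier import freq_azimuth, freq_radius, hermitian_white
from .detector import DetectorModel, simulate_response
from .motion import MotionModel, _sum_factor, _two_g_over_z, alpha_u, displace
from .optics import OpticsModel, ctf_power_thick
from .spectra import MovieStack, dose_to_fluence

__all__ = [
    "IceStructure",
    "SimConfig",
    "make_ice",
    "render_frame",
    "structure_filter",
    "spectral_structure_frames",
    "simulate_movie_particle",
    "simulate_movie_spectral",
    "noise_movie",
]

# Hard-core diameter as a fraction of the target pair-correlation peak:
# for a rejection-packed fluid the g(r) maximum sits just outside contact.
_HARD_CORE_FRACTION = 0.92


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic movies.

    Geometry and dose defaults follow the source acquisition: 1.04 A
    pixels, 300 kV, 7070 A underfocus, 2.33 e-/pixel/frame, 120 frames,
    and a Falcon II-like detector with DQE(0) = 0.5; ``sigma0_sq = 0.38``
    A^2/(e-/A^2) is the motion rate fitted to the reference exposure.
    ``thickness = 620`` A reproduces the observed single-digit-percent
    Thon-ring modulation through the defocus-spread damping.

    ``ring_strength`` fixes the amplitude of the spectral generator: the
    expected whitened ring signal of the full-sum spectrum (m = M) at the
    band centre, as a fraction of the M d/DQE background.  The absolute
    contrast of ice is not known here, so this is calibrated loosely to
    make rings about as visible as in the printed spectra.
    """

    n_pixels: int = 256
    pixel_size: float = 1.04  # Angstrom
    n_frames: int = 120
    dose_per_frame: float = 2.33  # e-/pixel
    sigma0_sq: float = 0.38  # A^2 per e-/A^2, per axis
    optics: OpticsModel = field(default_factory=OpticsModel)
    detector: DetectorModel = field(default_factory=DetectorModel)
    thickness: float = 620.0  # Angstrom
    seed: int = 0
    # structure model
    ring_center: float = 3.7  # Angstrom spacing of the dominant peak
    ring_width: float = 0.025  # 1/Angstrom, width of the structure bump
    ring_strength: float = 0.5  # whitened full-sum ring peak / background
    ice_density: float = 0.012  # scatterers per A^3 (particle simulator)
    contrast: float = 0.6  # particle-simulator contrast per unit density std
    footprint: float = 0.5  # Angstrom, Gaussian scatterer footprint
    # frame-integration model
    frame_integration: bool = True
    n_substeps: int = 8  # particle simulator sub-exposures per frame
    pre_exposure: float = 0.0  # e-/A^2 applied before the first frame

    def __post_init__(self) -> None:
        if self.n_pixels < 8:
            raise ValueError("n_pixels must be >= 8")
        if min(self.pixel_size, self.dose_per_frame, self.thickness) <= 0:
            raise ValueError("pixel_size, dose_per_frame, thickness must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma0_sq < 0 or self.ice_density < 0 or self.pre_exposure < 0:
            raise ValueError("sigma0_sq, ice_density, pre_exposure must be >= 0")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    @property
    def fluence_per_frame(self) -> float:
        """e-/A^2 per frame."""
        return dose_to_fluence(self.dose_per_frame, self.pixel_size)

    @property
    def field_of_view(self) -> float:
        """Lateral box size in Angstrom."""
        return self.n_pixels * self.pixel_size

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_pixels",
                "pixel_size",
                "n_frames",
                "dose_per_frame",
                "sigma0_sq",
                "thickness",
                "seed",
                "ring_center",
                "ring_width",
                "ring_strength",
                "ice_density",
                "contrast",
                "footprint",
                "frame_integration",
                "n_substeps",
                "pre_exposure",
            )
        }
        d["optics"] = {
            "voltage": self.optics.voltage,
            "defocus": self.optics.defocus,
            "astig_amplitude": self.optics.astig_amplitude,
            "astig_angle": self.optics.astig_angle,
            "spherical_aberration": self.optics.spherical_aberration,
            "amplitude_contrast": self.optics.amplitude_contrast,
        }
        d["detector"] = self.detector.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        optics = OpticsModel(**d.pop("optics", {}))
        det = DetectorModel.from_dict(d.pop("detector", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("optics", "detector")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(optics=optics, detector=det, **d)


@dataclass
class IceStructure:
    """Point-scatterer surrogate for an amorphous ice slab.

    Positions are in Angstrom with x, y in the field of view and z in
    [0, thickness].  A hard-core minimum distance just below
    ``peak_location`` makes the pair correlation peak near the configured
    spacing.
    """

    positions: np.ndarray  # (N, 3)
    box: tuple[float, float, float]
    density: float
    peak_location: float
    min_distance: float

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]


def make_ice(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> IceStructure:
    """Place hard-core scatterers by batched random sequential rejection.

    Candidate points are proposed uniformly in the slab, thinned against
    each other and against the accepted set at the hard-core distance,
    until the target density is reached.  Reproducible given the rng.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    lx = ly = config.field_of_view
    lz = config.thickness
    rmin = _HARD_CORE_FRACTION * config.ring_center
    packing = config.ice_density * (np.pi / 6.0) * rmin**3
    if packing > 0.30:
        raise ValueError(
            f"density {config.ice_density}/A^3 with hard core {rmin:.2f} A "
            f"gives packing fraction {packing:.2f} > 0.30: infeasible for "
            "rejection placement"
        )
    target = int(round(config.ice_density * lx * ly * lz))
    if target == 0:
        return IceStructure(
            positions=np.empty((0, 3)),
            box=(lx, ly, lz),
            density=config.ice_density,
            peak_location=config.ring_center,
            min_distance=rmin,
        )
    accepted: list[np.ndarray] = []
    count = 0
    for _ in range(300):
        need = target - count
        if need <= 0:
            break
        k = min(max(4 * need, 4096), 4_000_000)
        cand = rng.uniform(size=(k, 3)) * np.array([lx, ly, lz])
        pairs = cKDTree(cand).query_pairs(rmin, output_type="ndarray")
        if len(pairs):
            drop = np.zeros(k, dtype=bool)
            drop[pairs.max(axis=1)] = True
            cand = cand[~drop]
        if count:
            dmin, _ = cKDTree(np.concatenate(accepted)).query(cand, k=1)
            cand = cand[dmin >= rmin]
        take = cand[:need]
        if len(take):
            accepted.append(take)
            count += len(take)
    if count < target:
        raise ValueError(
            f"could not place {target} scatterers at density "
            f"{config.ice_density}/A^3 with hard core {rmin:.2f} A "
            f"(reached {count}); reduce the density or the core distance"
        )
    return IceStructure(
        positions=np.concatenate(accepted),
        box=(lx, ly, lz),
        density=config.ice_density,
        peak_location=config.ring_center,
        min_distance=rmin,
    )


def _power_filter(config: SimConfig) -> np.ndarray:
    """Amplitude filter sqrt(<ctf^2>_thickness) * Gaussian footprint.

    Applied to the projected-density DFT so that the *power* carried by
    each frequency matches the incoherent sum over sample heights; the
    phase pattern is immaterial for power-spectrum analysis.
    """
    shape = (config.n_pixels, config.n_pixels)
    r = freq_radius(shape) / config.pixel_size  # 1/Angstrom
    theta = freq_azimuth(shape)
    foot = np.exp(-2.0 * np.pi**2 * config.footprint**2 * r**2)
    filt = foot * np.sqrt(
        ctf_power_thick(r, theta, config.optics, config.thickness)
    )
    filt[0, 0] = 0.0
    return filt


def render_frame(
    ice: IceStructure, config: SimConfig, accumulated_fluence: float = 0.0
) -> np.ndarray:
    """Expected-intensity image (e-/pixel) of the current scatterer field.

    Scatterers are projected onto the pixel grid, mean-subtracted,
    filtered by the Gaussian footprint and the thickness-averaged CTF
    power, normalised to unit density fluctuation, and scaled by
    ``contrast`` on top of the uniform exposure.  ``accumulated_fluence``
    is provenance only; rendering is stateless.
    """
    del accumulated_fluence
    n = config.n_pixels
    lx = config.field_of_view
    d = config.dose_per_frame
    if ice.n_scatterers == 0:
        return np.full((n, n), d)
    hist, _, _ = np.histogram2d(
        ice.positions[:, 0] % lx,
        ice.positions[:, 1] % lx,
        bins=n,
        range=[[0.0, lx], [0.0, lx]],
    )
    lam_proj = ice.n_scatterers / n**2  # mean projected count per pixel
    delta = (hist - hist.mean()) / np.sqrt(lam_proj)
    fluct = np.fft.ifft2(np.fft.fft2(delta) * _power_filter(config)).real
    return np.clip(d * (1.0 + config.contrast * fluct), 0.0, None)


def simulate_movie_particle(config: SimConfig) -> MovieStack:
    """Dose-fractionated movie from the random-walking scatterer field.

    Each frame averages ``n_substeps`` sub-exposures (1 when
    ``frame_integration`` is off), displacing every scatterer by the
    sub-exposure fluence between renders and wrapping periodically, so the
    projected field stays statistically stationary.  ``pre_exposure``
    fluence applied before recording lets the initial pair correlations
    decay to the steady random-walk ensemble first.
    """
    rng = np.random.default_rng(config.seed)
    ice = make_ice(config, rng)
    model = MotionModel(sigma0_sq=config.sigma0_sq)
    box = np.array(ice.box)
    pos = ice.positions.copy()
    if config.pre_exposure > 0 and ice.n_scatterers:
        pos = displace(pos, config.pre_exposure, model, rng) % box
    d_fl = config.fluence_per_frame
    nsub = config.n_substeps if config.frame_integration else 1
    filt = _power_filter(config)
    n = config.n_pixels
    lx = config.field_of_view
    frames = np.empty((config.n_frames, n, n))
    for i in range(config.n_frames):
        if ice.n_scatterers == 0:
            expected = np.full((n, n), config.dose_per_frame)
        else:
            acc = np.zeros((n, n))
            for _ in range(nsub):
                hist, _, _ = np.histogram2d(
                    pos[:, 0], pos[:, 1], bins=n, range=[[0.0, lx], [0.0, lx]]
                )
                acc += hist
                pos = displace(pos, d_fl / nsub, model, rng) % box
            lam_proj = ice.n_scatterers / n**2
            delta = (acc / nsub - acc.mean() / nsub) / np.sqrt(lam_proj)
            fluct = np.fft.ifft2(np.fft.fft2(delta) * filt).real
            expected = np.clip(
                config.dose_per_frame * (1.0 + config.contrast * fluct), 0.0, None
            )
        frames[i] = simulate_response(expected, config.detector, rng)
    return MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        dose_per_frame=config.dose_per_frame,
        voltage=config.optics.voltage,
    )


def _structure_amplitude(config: SimConfig) -> float:
    """Band-centre structure amplitude realising ``ring_strength``.

    Chosen so the expected whitened ring signal of the m = M spectrum at
    the band centre (CTF power averaged to 1/2) equals
    ``ring_strength * M d / DQE(0)``.
    """
    m_frames = config.n_frames
    z1 = float(alpha_u(1.0 / config.ring_center, config.sigma0_sq)) * (
        config.fluence_per_frame
    )
    if config.frame_integration:
        a_m = float(_two_g_over_z(np.asarray(z1 * m_frames)))
    else:
        a_m = float(_sum_factor(np.atleast_1d(z1), m_frames)[0]) / m_frames**2
    gamma_m = m_frames * config.dose_per_frame / config.detector.dqe0
    return np.sqrt(
        config.ring_strength * gamma_m / (m_frames**2 * a_m * 0.5)
    )


def structure_filter(config: SimConfig) -> np.ndarray:
    """Per-mode structure amplitude: bump at 1/ring_center times the
    thickness-averaged CTF power transfer, scaled by the calibrated
    band-centre amplitude."""
    shape = (config.n_pixels, config.n_pixels)
    r = freq_radius(shape) / config.pixel_size
    theta = freq_azimuth(shape)
    u0 = 1.0 / config.ring_center
    profile = np.exp(-((r - u0) ** 2) / (2.0 * config.ring_width**2))
    g_filter = _structure_amplitude(config) * profile * np.sqrt(
        ctf_power_thick(r, theta, config.optics, config.thickness)
    )
    g_filter[0, 0] = 0.0
    return g_filter


def spectral_structure_frames(config: SimConfig, rng: np.random.Generator):
    """Yield the noiseless structure image of each frame.

    Every Fourier mode evolves as a stationary Ornstein-Uhlenbeck process
    in accumulated fluence with rate alpha_u.  With ``frame_integration``
    each frame yields the exact average of the process over the frame's
    fluence window (continuous motion during the frame), sampled jointly
    with the end-of-frame state; the lag correlation still decays by
    exp(-alpha_u d) per frame step and the block-sum signal follows
    scale * g(alpha_u m d) exactly.  Without it, frames are instantaneous
    snapshots (the discrete frame-sum covariance regime).
    """
    n = config.n_pixels
    shape = (n, n)
    r = freq_radius(shape) / config.pixel_size
    g_filter = structure_filter(config)

    z = alpha_u(r, config.sigma0_sq) * config.fluence_per_frame
    phi = np.exp(-z)
    sd1 = np.sqrt(np.maximum(1.0 - phi**2, 0.0))
    tiny = z < 1e-12
    zs = np.where(tiny, 1.0, z)
    psi = np.where(tiny, 1.0, -np.expm1(-z) / zs)  # (1 - e^-z)/z
    var_y = np.maximum(_two_g_over_z(z) - psi**2, 0.0)  # conditional on X_i
    cov_xy = np.where(tiny, 0.0, np.expm1(-z) ** 2 / zs)  # (1 - phi)^2 / z
    c1 = np.where(sd1 > 0, cov_xy / np.where(sd1 > 0, sd1, 1.0), 0.0)
    c2 = np.sqrt(np.maximum(var_y - c1**2, 0.0))

    scale = np.sqrt(n * n) * g_filter
    x = hermitian_white(rng, shape)  # stationary start
    for _ in range(config.n_frames):
        z1w = hermitian_white(rng, shape)
        if config.frame_integration:
            z2w = hermitian_white(rng, shape)
            y = psi * x + c1 * z1w + c2 * z2w
        else:
            y = x
        yield np.fft.ifft2(scale * y).real
        x = phi * x + sd1 * z1w


def simulate_movie_spectral(config: SimConfig) -> MovieStack:
    """Fourier-domain movie generator realising the Gauss-Markov model.

    The structure component of each frame comes from
    :func:`spectral_structure_frames`; detector shot noise, gain noise and
    the point-spread filtering are added by
    :func:`icemotion.detector.simulate_response`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pixels
    frames = np.empty((config.n_frames, n, n))
    for i, struct in enumerate(spectral_structure_frames(config, rng)):
        expected = np.clip(config.dose_per_frame + struct, 0.0, None)
        frames[i] = simulate_response(expected, config.detector, rng)
    return MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        dose_per_frame=config.dose_per_frame,
        voltage=config.optics.voltage,
    )


def noise_movie(config: SimConfig) -> MovieStack:
    """Specimen-free movie: the detector's response to uniform illumination."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pixels
    flat = np.full((n, n), config.dose_per_frame)
    frames = np.empty((config.n_frames, n, n))
    for i in range(config.n_frames):
        frames[i] = simulate_response(flat, config.detector, rng)
    return MovieStack(
        frames=frames,
        pixel_size=config.pixel_size,
        dose_per_frame=config.dose_per_frame,
        voltage=config.optics.voltage,
    )
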