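"""Stochastic detector response and the noise-power-spectrum model.

A direct electron detector converts each incident electron into an output
blob whose integrated value is random (mean gain ``g``, variance
``sigma_g^2``).  Gain variance alone fixes the zero-frequency detective
quantum efficiency, DQE(0) = g^2/(g^2 + sigma_g^2); the spatial extent of
the blob (charge diffusion) shapes the noise power spectrum N(u).  Because
the sensor is sampled on a pixel grid, replicas of the pre-sampling
spectrum fold back into the Nyquist band, so N(u) is modelled as a radially
symmetric falling function B(|u|) plus its low-order aliased copies,
normalised to N(0) = 1.

The same model drives both directions: :func:`evaluate_nps` produces the
surface used for noise whitening, and :func:`simulate_response` filters
simulated shot+gain noise so that its power spectrum *is* that surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._fourier import freq_radius

__all__ = [
    "DetectorModel",
    "NPSSurface",
    "NPSFitError",
    "dqe_zero",
    "nps_zero",
    "simulate_response",
    "evaluate_nps",
    "fit_nps_model",
]


def dqe_zero(gain_mean: float, gain_var: float) -> float:
    """DQE(0) = g^2 / (g^2 + sigma_g^2) for stochastic single-electron gain.

    Scale-invariant: multiplying the gain mean and gain standard deviation
    by a common factor leaves it unchanged.  Equal mean and variance (the
    working point of the Falcon II at unit gain) gives 0.5.
    """
    if gain_mean <= 0:
        raise ValueError("gain_mean must be positive")
    if gain_var < 0:
        raise ValueError("gain_var must be >= 0")
    return gain_mean**2 / (gain_mean**2 + gain_var)


@dataclass(frozen=True)
class DetectorModel:
    """Gain statistics plus a parameterised noise-power-spectrum surface.

    ``mtf_params`` are non-negative coefficients (a_1, a_2, ...) of the
    radially symmetric noise-power falloff

        B(|u|) = exp(-(a_1 |u| + a_2 |u|^2 + ...)),   u in cycles/pixel,

    which satisfies B(0) = 1 and is monotonically non-increasing by
    construction.  ``n_aliases`` is the number of folded replica orders
    included when building N(u).

    The default mimics a Falcon II-like sensor: unit gain with unit gain
    variance (DQE(0) = 0.5) and a rapidly falling B; the true Falcon II
    curves are not tabulated here, so this is a configurable surrogate.
    """

    gain_mean: float = 1.0
    gain_var: float = 1.0
    mtf_params: tuple[float, ...] = (3.0, 2.0)
    n_aliases: int = 1

    def __post_init__(self) -> None:
        if self.gain_mean <= 0:
            raise ValueError("gain_mean must be positive")
        if self.gain_var < 0:
            raise ValueError("gain_var must be >= 0")
        if any(a < 0 for a in self.mtf_params):
            raise ValueError("mtf_params must be non-negative")
        if self.n_aliases < 0:
            raise ValueError("n_aliases must be >= 0")

    @property
    def dqe0(self) -> float:
        return dqe_zero(self.gain_mean, self.gain_var)

    def radial_falloff(self, u):
        """B(|u|) evaluated at ``u`` in cycles/pixel."""
        u = np.abs(np.asarray(u, dtype=float))
        expo = np.zeros_like(u)
        for k, a in enumerate(self.mtf_params, start=1):
            expo += a * u**k
        return np.exp(-expo)

    def to_dict(self) -> dict:
        return {
            "gain_mean": self.gain_mean,
            "gain_var": self.gain_var,
            "mtf_params": list(self.mtf_params),
            "n_aliases": self.n_aliases,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorModel":
        return cls(
            gain_mean=float(d.get("gain_mean", 1.0)),
            gain_var=float(d.get("gain_var", 1.0)),
            mtf_params=tuple(float(x) for x in d.get("mtf_params", (3.0, 2.0))),
            n_aliases=int(d.get("n_aliases", 1)),
        )


@dataclass(frozen=True)
class NPSSurface:
    """Normalised noise power spectrum on an unshifted 2D DFT grid.

    ``values`` are strictly positive with ``values[0, 0] == 1``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("NPS values must be strictly positive")
        if not np.isclose(v[0, 0], 1.0):
            raise ValueError("NPS must be normalised to N(0) = 1")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def nps_zero(dose_per_pixel: float, model: DetectorModel) -> float:
    """Un-normalised noise power at zero frequency, (g^2 + sigma_g^2) d.

    With the output expressed in incident electrons (unit gain) this equals
    d / DQE(0), the mean background of the whitened spectrum.
    """
    if dose_per_pixel < 0:
        raise ValueError("dose must be >= 0")
    return (model.gain_mean**2 + model.gain_var) * dose_per_pixel


def evaluate_nps(shape: tuple[int, int], model: DetectorModel) -> NPSSurface:
    """Build N(u) = sum_k B(|u - k|) over alias replicas, rescaled to N(0)=1.

    Replica offsets k run over integer multiples of the sampling frequency
    (1 cycle/pixel per axis) with |k| <= n_aliases per axis; any departure
    of the surface from circular symmetry comes solely from these folded
    terms.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    n = model.n_aliases
    total = np.zeros(shape, dtype=float)
    for ky in range(-n, n + 1):
        for kx in range(-n, n + 1):
            total += model.radial_falloff(np.hypot(fy - ky, fx - kx))
    return NPSSurface(values=total / total[0, 0])


def _transfer(shape: tuple[int, int], model: DetectorModel) -> np.ndarray:
    """Amplitude transfer sqrt(N(u)) applied to the sampled image."""
    return np.sqrt(evaluate_nps(shape, model).values)


def simulate_response(
    expected_electrons_image: np.ndarray,
    model: DetectorModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample the detector output for a given expected-electron image.

    Per pixel, a Poisson number of electrons arrives; each deposits an
    independent gamma-distributed gain with mean ``gain_mean`` and variance
    ``gain_var`` (gamma is the non-negative two-moment choice; the sum of n
    such gains is again gamma).  The resulting noise field is then filtered
    in Fourier space by sqrt(N(u)) so that its power spectrum matches the
    model NPS exactly while the mean level is preserved (N(0) = 1).
    """
    expected = np.asarray(expected_electrons_image, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected electron counts must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rng.poisson(expected)
    if model.gain_var == 0:
        out = model.gain_mean * n.astype(float)
    else:
        shape_1e = model.gain_mean**2 / model.gain_var
        scale = model.gain_var / model.gain_mean
        out = np.zeros_like(expected)
        hit = n > 0
        out[hit] = rng.gamma(n[hit] * shape_1e, scale)
    filt = _transfer(expected.shape, model)
    return np.fft.ifft2(np.fft.fft2(out) * filt).real


class NPSFitError(RuntimeError):
    """Raised when the NPS model cannot be fitted to a measured spectrum."""


def fit_nps_model(
    measured,
    n_aliases: int = 1,
    n_basis: int = 3,
    gain_mean: float = 1.0,
    gain_var: float = 1.0,
    contamination_threshold: float = 0.15,
):
    """Fit the radial-falloff + alias-fold NPS model to a measured spectrum.

    ``measured`` is a :class:`~icemotion.spectra.Spectrum2D` of specimen-free
    (uniformly illuminated) frames.  Least squares adjusts an overall
    amplitude and the ``n_basis`` non-negative polynomial coefficients of
    B(|u|); the gain statistics are not identifiable from the shape of N(u)
    and are carried through unchanged.

    Returns ``(model, amplitude)``.  If the whitened residual profile shows
    structured (e.g. Thon-ring) deviations beyond ``contamination_threshold``
    a warning is issued: the input then violates the specimen-free premise.
    """
    values = np.asarray(measured.values, dtype=float)
    r = freq_radius(values.shape)
    mask = np.ones(values.shape, dtype=bool)
    mask[0, 0] = False  # DC carries the mean intensity
    y = values[mask]
    rad = r[mask]

    fy = np.fft.fftfreq(values.shape[0])[:, None]
    fx = np.fft.fftfreq(values.shape[1])[None, :]

    def surface(coeffs):
        model = DetectorModel(
            gain_mean=gain_mean,
            gain_var=gain_var,
            mtf_params=tuple(coeffs),
            n_aliases=n_aliases,
        )
        total = np.zeros(values.shape, dtype=float)
        for ky in range(-n_aliases, n_aliases + 1):
            for kx in range(-n_aliases, n_aliases + 1):
                total += model.radial_falloff(np.hypot(fy - ky, fx - kx))
        return total / total[0, 0], model

    def resid(params):
        amp = np.exp(params[0])
        surf, _ = surface(np.abs(params[1:]))
        return amp * surf[mask] - y

    # Seed amplitude from the low-frequency plateau, slopes from a crude
    # log-linear fit of the radial decay.
    amp0 = max(float(np.mean(y[rad < 0.05])), 1e-12)
    lo, hi = rad < 0.1, rad > 0.4
    decay = np.log(max(np.mean(y[lo]), 1e-12) / max(np.mean(y[hi]), 1e-12))
    x0 = np.concatenate([[np.log(amp0)], [max(decay, 0.1)], np.zeros(n_basis - 1)])
    try:
        res = least_squares(resid, x0, method="lm", max_nfev=2000)
    except Exception as exc:  # pragma: no cover - defensive
        raise NPSFitError(f"NPS fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.x)):
        raise NPSFitError(f"NPS fit diverged (status {res.status}): {res.message}")

    amp = float(np.exp(res.x[0]))
    surf, model = surface(np.abs(res.x[1:]))

    # Whitened residual profile should be flat for specimen-free input.
    white = values / surf
    nbins = min(values.shape) // 2
    idx = np.minimum((rad * 2 * nbins).astype(int), nbins - 1)
    prof = np.bincount(idx, weights=white[mask] / amp, minlength=nbins)
    cnt = np.bincount(idx, minlength=nbins)
    prof = prof[cnt > 0] / cnt[cnt > 0]
    dev = float(np.max(np.abs(prof - 1.0)))
    if dev > contamination_threshold:
        warnings.warn(
            "fit_nps_model: whitened radial profile deviates by "
            f"{dev:.1%} from flat; the input spectrum appears to contain "
            "specimen signal (e.g. Thon rings) and the background model is "
            "likely contaminated",
            stacklevel=2,
        )
    return model, amp
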