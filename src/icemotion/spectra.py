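"""Power spectra, noise whitening, block sums and ring-signal extraction.

The power spectrum of an image f is S(u) = |DFT(f)|^2 / N_tot (unnormalised
DFT, N_tot pixels).  Dividing by the detector's normalised noise power
spectrum gives the noise-whitened power spectrum W(u) = S(u)/N(u), whose
specimen-free background is flat with exponential statistics of mean
Gamma = d/DQE(0) per frame of d electrons/pixel.

For an M-frame movie, ``W_{M,m}`` is the sum of the M/m whitened power
spectra of m-frame block sums.  Its background M d/DQE(0) is independent of
m while its noise grows as sqrt(m) — so the growth of a structure signal
with m measures how coherently that structure persists across frames.

Internal frequency grids are in cycles/pixel (unshifted DFT layout);
conversion to 1/Angstrom happens exactly once, at the RadialCurve boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._fourier import freq_radius
from .detector import NPSSurface

__all__ = [
    "MovieStack",
    "Spectrum2D",
    "RadialCurve",
    "BlockSeries",
    "BackgroundStats",
    "dose_to_fluence",
    "power_spectrum",
    "noise_whiten",
    "block_sum_nwps",
    "predicted_background",
    "predicted_noise",
    "radial_average",
    "background_stats",
    "anchor_shift",
    "ring_signal_at",
    "measure_modulation",
    "block_series",
]


def dose_to_fluence(dose_per_pixel: float, pixel_size: float) -> float:
    """Convert a per-pixel dose (e-/pixel) to fluence (e-/Angstrom^2).

    The single place where pixel area enters; every quantity fed to the
    motion model is fluence in e-/A^2.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return dose_per_pixel / pixel_size**2


@dataclass
class MovieStack:
    """A dose-fractionated exposure: M frames in incident-electron units.

    ``frames`` has shape (M, ny, nx); ``pixel_size`` is in Angstrom,
    ``dose_per_frame`` in e-/pixel, ``voltage`` in kV.
    """

    frames: np.ndarray
    pixel_size: float
    dose_per_frame: float
    voltage: float = 300.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (M, ny, nx) stack with M >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dose_per_frame <= 0:
            raise ValueError("dose_per_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fluence_per_frame(self) -> float:
        """Fluence per frame in e-/A^2."""
        return dose_to_fluence(self.dose_per_frame, self.pixel_size)

    def divisors(self) -> list[int]:
        m = self.n_frames
        return [k for k in range(1, m + 1) if m % k == 0]


@dataclass
class Spectrum2D:
    """A (possibly whitened) power spectrum on the unshifted DFT grid."""

    values: np.ndarray
    pixel_size: float
    n_pixels_total: int
    kind: str = "raw"  # "raw" | "whitened"
    frames_summed: tuple[int, int] | None = None  # (M, m) bookkeeping

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Angstrom."""
        return 0.5 / self.pixel_size


@dataclass
class RadialCurve:
    """Circular average of a spectrum: bin centres in 1/Angstrom."""

    u: np.ndarray
    value: np.ndarray
    count: np.ndarray
    noise: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.u) == len(self.value) == len(self.count) == len(self.noise)):
            raise ValueError("curve arrays must have equal length")

    def bin_of(self, u_target: float) -> int:
        """Index of the bin whose centre is nearest ``u_target``."""
        if not (self.u[0] <= u_target <= self.u[-1]):
            raise ValueError(
                f"u_target={u_target} outside curve range "
                f"[{self.u[0]:.4g}, {self.u[-1]:.4g}]"
            )
        return int(np.argmin(np.abs(self.u - u_target)))


@dataclass
class BlockSeries:
    """Background-subtracted ring signal versus block size m."""

    m: np.ndarray
    block_dose: np.ndarray  # m * d in e-/A^2
    value: np.ndarray
    error: np.ndarray
    total_dose: float  # D_tot in e-/A^2
    u_target: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.error) <= 0):
            raise ValueError("errors must be positive")


@dataclass
class BackgroundStats:
    """Exponential-background summary of a whitened spectrum."""

    gamma: float
    sd: float
    ks_distance: float
    n: int

    @property
    def cv(self) -> float:
        """SD/mean; 1 for an exponential distribution."""
        return self.sd / self.gamma

    def is_exponential(self, cv_tol: float = 0.05, ks_tol: float = 0.01) -> bool:
        return abs(self.cv - 1.0) < cv_tol and self.ks_distance < ks_tol


def power_spectrum(image: np.ndarray, pixel_size: float) -> Spectrum2D:
    """S(u) = |f(u)|^2 / N_tot with f the unnormalised DFT of the image.

    With this convention Parseval reads sum_u S(u) = sum_pixels f^2.  The DC
    term is stored but excluded from all downstream statistics.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    f = np.fft.fft2(image)
    return Spectrum2D(
        values=(f.real**2 + f.imag**2) / image.size,
        pixel_size=pixel_size,
        n_pixels_total=image.size,
        kind="raw",
    )


def noise_whiten(s: Spectrum2D, nps: NPSSurface) -> Spectrum2D:
    """W(u) = S(u)/N(u): flatten the detector's spectral signature."""
    if s.values.shape != nps.shape:
        raise ValueError(
            f"grid mismatch: spectrum {s.values.shape} vs NPS {nps.shape}"
        )
    return replace(s, values=s.values / nps.values, kind="whitened")


def block_sum_nwps(movie: MovieStack, m: int, nps: NPSSurface) -> Spectrum2D:
    """W_{M,m}: sum of the M/m whitened power spectra of m-frame block sums.

    m = M gives the whitened spectrum of the full frame sum (static
    structure adds coherently); m = 1 gives the sum of per-frame whitened
    spectra (structure only needs to persist within single frames).
    """
    big_m = movie.n_frames
    if m < 1 or big_m % m != 0:
        raise ValueError(
            f"m={m} does not divide M={big_m}; valid divisors: {movie.divisors()}"
        )
    total = np.zeros(movie.frames.shape[1:], dtype=float)
    for i in range(big_m // m):
        block = movie.frames[i * m : (i + 1) * m].sum(axis=0)
        total += noise_whiten(
            power_spectrum(block, movie.pixel_size), nps
        ).values
    return Spectrum2D(
        values=total,
        pixel_size=movie.pixel_size,
        n_pixels_total=movie.frames[0].size,
        kind="whitened",
        frames_summed=(big_m, m),
    )


def predicted_background(M: int, d: float, dqe0: float) -> float:
    """Expected W_{M,m} background M d / DQE(0), independent of m."""
    if M <= 0 or d <= 0 or not 0 < dqe0 <= 1:
        raise ValueError("require M > 0, d > 0, 0 < dqe0 <= 1")
    return M * d / dqe0


def predicted_noise(M: int, d: float, dqe0: float, m: int) -> float:
    """Expected noise of W_{M,m} per Fourier sample: (M d/DQE) sqrt(m/M).

    Summing M/m independent exponential spectra (each with SD equal to its
    mean m d/DQE) gives SD sqrt(M/m) (m d/DQE).  For circularly averaged
    curves divide further by sqrt(samples per bin).
    """
    if m < 1 or M % m != 0:
        raise ValueError(f"m={m} must divide M={M}")
    return predicted_background(M, d, dqe0) * np.sqrt(m / M)


def radial_average(
    s: Spectrum2D,
    bin_width: float | None = None,
    noise_level: float | None = None,
) -> RadialCurve:
    """Circularly average a spectrum into equal-width |u| bins.

    ``bin_width`` is in 1/Angstrom and defaults to one Fourier pixel of the
    smaller image dimension.  Bins are half-open [lo, hi); the DC sample is
    excluded and the average runs out to the Nyquist circle.  If
    ``noise_level`` (the per-sample noise of the input spectrum, e.g.
    :func:`predicted_noise`) is given, each bin is assigned noise
    ``noise_level/sqrt(count)``; otherwise the per-bin sample error of the
    mean is used.
    """
    r = freq_radius(s.shape)  # cycles/pixel
    width_cpp = (
        1.0 / min(s.shape) if bin_width is None else bin_width * s.pixel_size
    )
    if width_cpp <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.ones(s.shape, dtype=bool)
    mask[0, 0] = False
    mask &= r <= 0.5
    rr = r[mask]
    vv = s.values[mask]
    idx = (rr / width_cpp).astype(int)
    # Fold samples lying exactly on the Nyquist circle into the last full
    # bin rather than a sliver bin of their own (bins stay [lo, hi) inside).
    idx_max = int((0.5 - 1e-12) / width_cpp)
    idx = np.minimum(idx, idx_max)
    nbins = int(idx.max()) + 1
    cnt = np.bincount(idx, minlength=nbins)
    keep = cnt > 0
    mean = np.bincount(idx, weights=vv, minlength=nbins)[keep] / cnt[keep]
    if noise_level is not None:
        noise = noise_level / np.sqrt(cnt[keep])
    else:
        sq = np.bincount(idx, weights=vv**2, minlength=nbins)[keep] / cnt[keep]
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        noise = sd / np.sqrt(cnt[keep])
    centres_cpp = (np.arange(nbins)[keep] + 0.5) * width_cpp
    return RadialCurve(
        u=centres_cpp / s.pixel_size,
        value=mean,
        count=cnt[keep],
        noise=noise,
    )


def background_stats(
    w: Spectrum2D,
    exclusion: tuple[float, float] | None = None,
) -> BackgroundStats:
    """Estimate the exponential background of a whitened spectrum.

    ``exclusion`` is an optional (u_lo, u_hi) annulus in 1/Angstrom (e.g.
    the Thon-ring band) left out of the statistics.  Returns the mean Gamma,
    the SD, and a Kolmogorov-Smirnov distance to Exponential(Gamma); for
    pure-noise input SD/mean -> 1 and the KS distance is small.
    """
    if w.kind != "whitened":
        raise ValueError("background statistics require a whitened spectrum")
    r = freq_radius(w.shape) / w.pixel_size  # 1/Angstrom
    mask = np.ones(w.shape, dtype=bool)
    mask[0, 0] = False
    if exclusion is not None:
        lo, hi = exclusion
        mask &= ~((r >= lo) & (r <= hi))
    vals = w.values[mask]
    if vals.size == 0:
        raise ValueError("exclusion removes every frequency sample")
    gamma = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0 or gamma <= 0:
        return BackgroundStats(gamma=max(gamma, 1e-300), sd=sd, ks_distance=1.0, n=vals.size)
    ks = stats.kstest(vals, "expon", args=(0.0, gamma)).statistic
    return BackgroundStats(gamma=gamma, sd=sd, ks_distance=float(ks), n=vals.size)


def anchor_shift(
    curves: dict[int, RadialCurve],
) -> tuple[dict[int, RadialCurve], dict]:
    """Anchor each W_{M,m} curve to the m=1 curve at the Nyquist bin.

    Residual inter-frame correlations (gain-correction or readout
    artifacts) add a small m-dependent offset to the whitened background;
    since genuine structure signal has died away by Nyquist, forcing all
    curves to agree with the m=1 curve in the top frequency bin removes it.
    Returns the shifted curves and a report with each shift and the maximum
    shift as a fraction of the background; shifts above 5% of background
    are flagged.
    """
    if 1 not in curves:
        raise ValueError("anchor_shift requires the m=1 curve")
    ref = curves[1]
    background = float(np.mean(ref.value))
    shifted: dict[int, RadialCurve] = {}
    shifts: dict[int, float] = {}
    for m, c in curves.items():
        if len(c.u) != len(ref.u) or not np.allclose(c.u, ref.u):
            raise ValueError("all curves must share the same binning")
        delta = float(ref.value[-1] - c.value[-1]) if m != 1 else 0.0
        shifts[m] = delta
        shifted[m] = RadialCurve(
            u=c.u, value=c.value + delta, count=c.count, noise=c.noise
        )
    max_frac = max(abs(v) for v in shifts.values()) / background if background else 0.0
    report = {
        "shifts": shifts,
        "background": background,
        "max_shift_fraction": max_frac,
        "ok": max_frac <= 0.05,
    }
    return shifted, report


def ring_signal_at(
    curve: RadialCurve,
    u_target: float,
    background: float | None = None,
    background_band: tuple[float, float] | None = None,
    band: float = 0.0,
) -> tuple[float, float]:
    """Background-subtracted curve value at ``u_target`` with its error.

    The signal is the mean over the bins within ``band`` (1/Angstrom) of
    ``u_target`` (just the containing bin when band = 0).  The background
    is either given explicitly (e.g. the analytic M d/DQE prediction) or
    estimated from the ``background_band`` annulus, which must not overlap
    the target bins.  Errors propagate from the per-bin noise.
    """
    i0 = curve.bin_of(u_target)
    sel = (
        np.abs(curve.u - u_target) <= band
        if band > 0
        else np.arange(len(curve.u)) == i0
    )
    if not np.any(sel):
        sel = np.arange(len(curve.u)) == i0
    sig = float(np.mean(curve.value[sel]))
    sig_err2 = float(np.sum(curve.noise[sel] ** 2)) / int(sel.sum()) ** 2

    if background_band is not None:
        lo, hi = background_band
        bsel = (curve.u >= lo) & (curve.u <= hi)
        if np.any(bsel & sel):
            raise ValueError("background band overlaps the target bins")
        if not np.any(bsel):
            raise ValueError("background band contains no bins")
        bg = float(np.mean(curve.value[bsel]))
        bg_err2 = float(np.sum(curve.noise[bsel] ** 2)) / int(bsel.sum()) ** 2
    elif background is not None:
        bg, bg_err2 = float(background), 0.0
    else:
        raise ValueError("provide either background or background_band")
    return sig - bg, float(np.sqrt(sig_err2 + bg_err2))


def measure_modulation(
    curve: RadialCurve,
    u_range: tuple[float, float],
    background: float,
) -> float:
    """Thon-ring modulation depth over ``u_range``.

    Defined as one half the peak-to-peak excursion within the range divided
    by the mean value above ``background``; 0 for a structureless curve.
    """
    lo, hi = u_range
    sel = (curve.u >= lo) & (curve.u <= hi)
    if not np.any(sel):
        raise ValueError("u_range contains no curve bins")
    v = curve.value[sel]
    half_ptp = 0.5 * float(v.max() - v.min())
    excess = float(np.mean(v - background))
    if excess <= 0:
        return 0.0
    return half_ptp / excess


def block_series(
    movie: MovieStack,
    nps: NPSSurface,
    m_values,
    u_target: float,
    dqe0: float,
    band: float = 0.01,
    background_band: tuple[float, float] | None = None,
    anchor: bool = True,
    bin_width: float | None = None,
):
    """Full pipeline from a movie to a ring-signal-versus-m series.

    For each m in ``m_values`` computes the circularly averaged W_{M,m}
    with analytic per-bin noise, optionally anchors the curves at Nyquist
    to the m=1 curve, and extracts the background-subtracted signal at
    ``u_target`` (band-averaged over +-``band`` 1/Angstrom).  The default
    background is the analytic M d/DQE(0) prediction.

    Returns ``(series, curves, anchor_report)``.
    """
    m_values = sorted(set(int(m) for m in m_values))
    if anchor and 1 not in m_values:
        m_values = [1] + m_values
    big_m = movie.n_frames
    d = movie.dose_per_frame
    curves: dict[int, RadialCurve] = {}
    for m in m_values:
        spec = block_sum_nwps(movie, m, nps)
        curves[m] = radial_average(
            spec,
            bin_width=bin_width,
            noise_level=predicted_noise(big_m, d, dqe0, m),
        )
    report = None
    if anchor:
        curves, report = anchor_shift(curves)
    gamma_m = predicted_background(big_m, d, dqe0)
    vals, errs = [], []
    for m in m_values:
        v, e = ring_signal_at(
            curves[m],
            u_target,
            background=None if background_band else gamma_m,
            background_band=background_band,
            band=band,
        )
        vals.append(v)
        errs.append(e)
    d_fluence = movie.fluence_per_frame
    series = BlockSeries(
        m=np.array(m_values),
        block_dose=np.array(m_values) * d_fluence,
        value=np.array(vals),
        error=np.array(errs),
        total_dose=big_m * d_fluence,
        u_target=u_target,
    )
    return series, curves, report
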