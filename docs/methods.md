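# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic data do and do
not emulate. Symbols: `d` is fluence per frame (e⁻/Å²) unless a per-pixel
dose is stated explicitly; pixel doses convert to fluence by dividing by
the pixel area, in exactly one place (`spectra.dose_to_fluence`).

## Spectral conventions

Power spectra use `S(u) = |f(u)|²/N_tot` with the unnormalised DFT, so
Parseval reads `Σ_u S = Σ_px f²`. Internal frequency grids are in
cycles/pixel (unshifted DFT layout); conversion to Å⁻¹ happens once, at
the `RadialCurve` boundary. The DC term carries the mean intensity and is
excluded from all statistics and fits. Radial bins are half-open
`[lo, hi)` with a default width of one Fourier pixel of the smaller image
dimension; samples lying exactly on the Nyquist circle are folded into
the last full bin (a sliver bin containing only the two axis samples
would otherwise dominate the Nyquist anchoring noise). Circular averages
run out to the Nyquist circle; corner frequencies beyond it are ignored.

## Detector model

Single-electron gain is gamma-distributed with mean `ḡ` and variance
`σ_g²` — the non-negative two-parameter family matching the two moments
that determine `DQE(0) = ḡ²/(ḡ²+σ_g²)`; sums of per-electron gains stay
gamma, so a pixel with a Poisson electron count can be sampled in one
draw. The default `ḡ = σ_g² = 1` gives `DQE(0) = 0.5`, the working point
of the detector class this emulates; the true MTF/NPS curves of any real
camera are not tabulated here, so the spectral falloff is a configurable
surrogate.

The noise power spectrum is modelled as a radially symmetric falling
function plus its folded alias replicas,

    N(u) = Σ_k B(|u − k|),   B(r) = exp(−Σ_j a_j r^j),  a_j ≥ 0,

rescaled to `N(0) = 1`, with replica offsets `k` at integer multiples of
the sampling frequency up to `n_aliases` (default 1). The exponential-
of-non-negative-polynomial basis makes `B` smooth, monotone and equal to
1 at DC by construction; `fit_nps_model` fits its coefficients plus an
amplitude to a measured specimen-free spectrum by least squares and warns
if the whitened residual profile is not flat (Thon-ring contamination of
the background model).

Simulation and whitening share one surface: `simulate_response` filters
the sampled shot+gain noise by `sqrt(N(u))` in Fourier space, so the
simulated noise power spectrum *is* the model surface (charge-diffusion
behaviour: signal and noise share the point-spread function, and DQE does
not fall with the MTF), whitening with the generating model is exactly
flat, and the NPS fit round-trips.

## Thon rings through a thick film

Molecules at height `z` in a film of thickness `t` see defocus
`Δf + z`. Their ring *power* adds incoherently, which damps only the
oscillatory part of the squared CTF:

    ⟨ctf²⟩ = ½ [1 − cos(2γ̄) · sin(ξ)/ξ],   ξ = π λ u² t

(at zero amplitude contrast; the general form is implemented). Total ring
power therefore survives a thick film even when the ring *modulation* —
half the peak-to-peak excursion over the mean excess above background —
is strongly damped; at `t = 620 Å` the damping factor at the 3.7 Å ring
is ≈ 0.12, which is why the default simulated modulation comes out at the
observed single-digit-percent level. The first node of `sin(ξ)/ξ` gives
the familiar diagnostics `t = 1/(λu²)` and `u = 1/√(λt)`.

## Motion model and estimation

The per-axis displacement variance per unit fluence is `σ₀²`; Fourier
components decorrelate at `α_u = 2π²σ₀²u²`. Closed forms are provided for
the expected spectrum of an `M`-frame sum of snapshots (with an exact
`O(M)` summation fallback when `α_u d < 10⁻⁶`, avoiding catastrophic
cancellation) and for the continuous-exposure limit; `g(z)` switches to
its Taylor series below `z = 10⁻⁴`.

`fit_sigma0` performs weighted nonlinear least squares of
`scale · g(α_u m d)` against the block series, weights `1/error²` with
the analytic `√m` error bars. Both parameters are fitted in log space
(positivity); a coarse log-grid scan over `σ₀² ∈ [10⁻³, 10]` with the
scale profiled out linearly seeds a Levenberg–Marquardt refinement, so the
result is deterministic in the inputs. The covariance comes from the
Jacobian at the optimum. A series with no significant signal, or one so
flat that only `scale·α_u` is identified, is flagged unidentifiable with
a warning rather than returning a silently meaningless number.

The ring signal per block size is the band mean around the target
frequency (default ±0.01 Å⁻¹) minus the analytic background
`M d_px/DQE(0)`; an annulus-estimated background is available when the
detector calibration is not trusted. Before extraction, each curve is
anchored to the `m = 1` curve at the Nyquist bin — residual inter-frame
correlations (gain-correction or readout artifacts in real data) offset
the whitened background by a small m-dependent constant, and no genuine
structure survives at Nyquist; shifts above 5 % of background are
flagged. The SNR objective is `g(z)/√z` because the noise of `W_{M,m}`
grows as `√m`; its stationary point `z* = 2.1491…` (bracketed root of
`1.5 − 0.5z = e^{−z}(z+1.5)`) gives the optimal block fluence
`d_opt = z*/α_u`.

Blur extrapolation uses the Stokes–Einstein scaling of the diffusion
coefficient with particle size: mean-squared displacement scales with
`D`, so RMS scales with `1/√(D_water/D_particle)`; the ratio defaults to
the size rule `(MW/18)^{1/3}` and accepts an empirical override (measured
ratios for globular proteins run higher than the size rule). The B-factor
convention is `B = 8π²⟨u_x²⟩` with per-axis variance `rms²/3`; B-factor
conventions differ by up to 3×, so this is stated once and used
everywhere.

## Synthetic movies

**What is emulated.** Dose-fractionated exposures of a weakly scattering
amorphous film on a gain-noisy, strongly spectrally shaped detector:
1.04 Å pixels, 300 kV, 7070 Å underfocus, 2.33 e⁻/pixel/frame, 120
frames, `DQE(0) = 0.5`, `σ₀² = 0.38 Å²/(e⁻/Å²)`, film thickness 620 Å —
the conditions of the reference ice exposure — at a desk-scale 256²
field. The structure signal is a Gaussian bump at `u = 1/3.7 Å⁻¹` (width
0.025 Å⁻¹) times the thickness-averaged CTF power.

**Frame integration.** Real molecules move *during* a frame, not just
between frames. At the reference conditions the per-frame decorrelation
is `α_u d ≈ 1.2` at the ring — far from infinitesimal — and fitting the
continuous-exposure saturation curve to data whose frames are
instantaneous snapshots biases `σ₀²` upward by ~50 %. The spectral
generator therefore evolves every Fourier mode as a stationary
Ornstein–Uhlenbeck process in accumulated fluence and records, by exact
joint sampling of the window average and the end-of-frame state, the
average of the process over each frame's fluence window. Summing `m`
window averages reconstitutes the average over the whole block window, so
the block-sum curve follows `g(α_u m d)` exactly and the fit is exactly
self-consistent; the lag correlation between frames still decays by
`exp(−α_u d)` per frame step. `frame_integration=False` switches to
instantaneous snapshots — the regime of the discrete frame-sum covariance
formula — which is what the oracle-equivalence tests use. The particle
simulator approximates the same integration by averaging `n_substeps`
(default 8) sub-renders per frame.

**Particle simulator.** Scatterers are placed by batched hard-core
rejection (Matérn-style thinning within each candidate batch) with core
diameter `0.92 ×` the target spacing, so the pair correlation peaks near
3.7 Å; the default density 0.012 Å⁻³ keeps the packing fraction at ~0.25,
comfortably below rejection-placement jamming (real water is ~3× denser;
the contrast knob absorbs the difference). Frames are histograms of the
projected positions, normalised to unit density fluctuation, filtered by
a 0.5 Å Gaussian footprint and `sqrt(⟨ctf²⟩)`, scaled by `contrast`
(default 0.6) on the uniform exposure, then passed through the detector.
Scatterers random-walk per the motion model between sub-renders and wrap
periodically, so the projected field is statistically stationary and the
frame-to-frame Fourier correlation is exactly `exp(−α_u |i−j| d)`. One
caveat is physical and deliberate: free random walks destroy the initial
pair correlations with *accumulated* fluence, so the 3.7 Å pair peak
fades over the movie while the (flat-spectrum) self term is stationary.
`pre_exposure` (e⁻/Å²) lets that transient decay before recording;
quantitative oracle comparisons use it, qualitative ring demonstrations
need not.

**Amplitude calibration.** The absolute scattering contrast of ice is not
known here. `ring_strength` (default 0.5) sets the expected whitened ring
signal of the full-sum spectrum at the band centre as a fraction of the
`M d/DQE(0)` background, computed analytically from the block-sum formula
for the configured motion and integration mode — a loose calibration
chosen to make rings about as visible as in published spectra, applied
identically whatever `σ₀²` or `M` is simulated.

**Not emulated.** Per-pixel gain-map residuals and row-reset correlations
of real cameras (only their Nyquist-anchored correction is implemented),
radiolytic thinning of the film across successive exposures (the fit
scale would decay), charging and collective stress-relief motion,
multiple and inelastic scattering in thick ice, and counting-mode
detectors. Passing tests therefore demonstrate the statistical machinery
and the estimator's consistency under the stated model, not the absolute
contrast or artifact spectrum of any particular camera.

## Problem sizes and tolerances

The test suite runs desk-scale versions of every experiment: 256² fields
for background statistics (3-standard-error bands, with the effective
sample count halved for Hermitian pairing of `|f(u)|²`), 128²/16-frame
movies over ≥10 seeds for the simulator-vs-closed-form comparisons (5 SE),
and ten 256²/120-frame movies for parameter recovery (median within 10 %
of the generative value). Closed forms are checked against brute-force
covariance sums to 10⁻¹⁰ relative and against the continuous limit to
10⁻³ at `M = 10⁴`. The full suite takes about a minute on one CPU.

## Known limitations

* `σ₀²` and the scale are near-degenerate when `α_u M d ≲ 1` (no
  curvature within the movie); the fit warns rather than failing.
* The NPS fit assumes the radial-plus-aliases form; a camera with strongly
  anisotropic (non-alias) noise structure would leave systematic
  whitening residuals.
* Elliptical (astigmatism-aware) averaging is not implemented; strong
  astigmatism smears the ring band in the circular average.
* The band-averaged ring signal mixes `α_u` over ±0.01 Å⁻¹ (±4 % in
  `α`); the resulting bias on `σ₀²` is well below the statistical error
  at the default settings.
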