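# Methods

This note documents the models behind each analysis stage, the synthetic
data used to validate them, and the numerical choices that were genuinely
open.

## Flicker spectroscopy

A quasi-spherical vesicle of mean radius R fluctuates thermally around a
sphere. Expanding the radial displacement in spherical harmonics,
u(θ,φ) = Σ u_lm Y_lm, the Helfrich energy with bending rigidity κ and
tension σ gives by equipartition

    ⟨|u_lm|²⟩ = k_BT / { κ (l−1)(l+2) [l(l+1) + σ̄] },   σ̄ = σR²/κ.

Microscopy sees only the equatorial cross-section r(φ). Its Fourier modes
u_q (one-sided complex coefficients, `fft/n` normalization) collect all
l ≥ q through the equatorial weight N_lq = |Y_lq(π/2,0)|², so the
observable spectrum is

    V(q) = (k_BT/κ) Σ_{l=max(q,2)}^{l_max} N_lq / [(l−1)(l+2)(l(l+1)+σ̄)].

`flicker.fit_helfrich` fits (κ, σ̄) to the measured mean-square amplitudes
by weighted least squares (weights 1/SE², parameters in log space,
standard errors from the scaled Jacobian). σ follows as σ̄κ/R².

**Truncation.** N_lq is evaluated entirely in log-gamma space (the
factorial ratio and [P_l^q(0)]² individually overflow near l ≈ 300 while
their product is O(1/l)). The Legendre tail decays slowly: truncating at
l_max = 2q_max leaves ≈5% of V(q) missing at every q, enough to bias κ
upward of a percent. The default is therefore l_max = 8·q_max, where
doubling l_max changes V(q) by < 0.1%. Generator and estimator share the
same truncation so distributional closure is exact by construction.

**Fit range.** Modes are reported for 2 ≤ q ≤ n_points/4. The default fit
uses q_min = 3 (modes 3–5 carry the tension information; q = 2 is most
sensitive to residual ellipticity of real vesicles) and
q_max = n_points/8, where the synthetic spectrum is still well above any
detection-noise floor.

**Quality control.** A vesicle is accepted when 10 µm ≤ R ≤ 25 µm,
10⁻⁹ ≤ σ ≤ 10⁻⁷ N/m, it is defect-free, and the tension fit did not pin
at an optimizer bound. Reasons are reported as strings
(`reject(radius)`, `reject(tension)`, ...).

**What the generator emulates.** `gen_flicker_contours` draws each mode
amplitude per frame as an independent complex Gaussian with the model
variance, adds radial Gaussian detection noise (default 10 nm ≈ 0.05 px
subpixel localization error at a typical 0.16 µm pixel pitch), and
contains no temporal correlation between frames. Real flicker movies are
correlated on the mode relaxation times and taken at finite exposure; the
200 µs exposures of the protocol make motion blur negligible, and the
estimator uses only per-mode variances, so neither omission affects the
recovery claim. Passing recovery tests therefore demonstrate estimator
correctness under the stated spectral model, not robustness to optical
artifacts (halo, uneven focus) that the generator does not render.

## Contour detection

Synthetic images place a dark Gaussian-profile ring along the contour on
a light background (the phase-contrast appearance of a sugar-loaded GUV).
Detection casts n rays from the current centre estimate, smooths each
radial profile (Gaussian, σ = 1 px), takes the deepest local minimum with
contrast above threshold, and refines it by 3-point parabolic
interpolation; the centre is iterated from the contour's first Fourier
moment until it moves < 0.1 px. The edge is defined as the radial
*minimum*, not the maximum gradient — switching to a gradient edge is a
one-line change in `_radial_profiles` usage. Rays may fail on low
contrast; isolated failures are interpolated periodically, > 5% failures
raise "open contour", and a second comparable minimum on a majority of
rays raises "ambiguous contour" unless a centre hint disambiguates.
Angles are counterclockwise from the +x (column) axis on a row-major
grid; radii are stored in metres.

## Electrodeformation

The prolate surface area uses the closed form with a series guard:
arcsin(ε)/ε is replaced by its Taylor expansion 1 + ε²/6 + 3ε⁴/40 below
ε = 10⁻⁴ to avoid 0/0 at the sphere limit; the two branches agree with
numerical quadrature to 10⁻¹² there. Oblate inputs raise by default
(the area-measurement protocol guarantees prolate shapes by preparing a
higher-conductivity interior); `allow_oblate=True` enables the standard
oblate formula for sweep data past the transition. Areas are strictly
monotone in a at fixed b.

Kinetic epochs (dark/UV/blue) are maximal runs of the per-frame
illumination label. The relaxation fit is
aspect(t) = baseline − amplitude·exp(−(t−t₀)/τ) with t₀ *fixed* to the
epoch start: illumination switches stepwise, and floating t₀ only
correlates with τ. An amplitude smaller than twice its own standard error
is flagged flat (τ meaningless). The generator's defaults — 100 frames/s,
5 s epochs, 1% aspect noise, 0.1 aspect-ratio jump — match the kinetics
protocol's acquisition settings and typical deformation amplitudes.

One-way ANOVA wraps the classical F-test with two explicit degenerate
branches: zero between-group variability returns (F=0, p=1), zero
within-group variance with distinct means returns (∞, 0).

## Capacitance

The critical-frequency model is
f_c = λ_in/(2πRC_m) · [(1−Λ)(3+Λ)]^(−1/2). The exponent of the radical is
a single named constant (`RADICAL_EXPONENT = −0.5`) recorded in output
metadata; it reproduces the downstream protocol numbers and must not be
changed silently. Crossing detection median-filters the sweep (kernel 3,
endpoints kept raw) and interpolates aspect vs log₁₀f linearly across the
sign change; with several surviving crossings the lowest-frequency one is
used with a warning. C_m comes from an ordinary least-squares fit (with
intercept) of f_c against 1/R over ≥ 3 vesicles, with the SE propagated
from the slope.

The synthetic sweep is a tanh of log-frequency crossing 1 exactly at the
model f_c, with amplitude 0.12 and width 0.6 decades (typical measured
sweeps fall from a/b ≈ 1.1 to ≈ 0.9 over about a decade), 41 log-spaced
points over 500 Hz–1 MHz, and independent Gaussian per-point aspect noise
(default 2%). Per-point noise propagates into a ≈ 20% scatter on a single
vesicle's detected f_c; the 10-vesicle slope fit averages this to a few
percent on C_m, which is what the recovery studies measure.

Debye lengths use λ_D = √(ε_r,W ε₀ k_BT / (2 N_A e² c)) for a 1:1
electrolyte with CODATA-2018 constants, ε_r,W = 80 and T = 296 K
defaults; double layers are C_D = ε_r,W ε₀/λ_D, the bare bilayer is the
series inverse, and ε_r,B = C_B·d/ε₀. `capacitance_set` guarantees the
series identity to 10⁻¹² by construction.

## AFM thickness

Flattening follows the three-pass line fit: (i) linear fit to all pixels
of a fast-scan line, (ii) refit after rejecting pixels more than 1 nm
*above* the fit, (iii) refit after rejecting pixels more than 0.5 nm
above the second fit, then subtract. Rejection is one-sided because SLB
patches protrude upward. A line left with fewer than 4 pixels falls back
to the previous pass with a warning. The substrate mode of the flattened
map is centred at zero. Smoothing is a 10×10 moving average with
shrunken edge windows (ratio of zero-padded box filters).

The thickness histogram uses 0.05 nm bins whose grid is aligned so the
minimum height sits at a bin centre (exact two-level maps then do not
straddle bin edges) with one guaranteed-empty pad bin per side so
boundary spikes remain local maxima. The two most prominent peaks
separated by at least 1 nm are substrate (lower) and patch (upper); peak
positions are refined by parabolic interpolation (a local Gaussian fit is
available as `gaussian_peaks=True`). A third peak with prominence within
20% of the second raises "ambiguous peaks". Bin width and separation
floor are config keys: they resolve the few-ångström spread of real patch
measurements while suppressing noise peaks, and are not claimed to match
any lab's in-house scripts bit for bit. The fast-scan axis is assumed to
be CSV rows; `--scan-axis cols` transposes.

The generator's default map — 256×256 pixels, 40% elliptical patch,
6.2 nm step, 2 nm row tilt, 0.1 nm roughness — mimics a typical QI-mode
scan of an SLB patch at step/roughness SNR ≈ 60; recovery at this SNR is
limited by the histogram bin width (±0.05 nm), not by noise. Real maps
with scars, multi-patch crops or tip artifacts are out of the generator's
scope, which is why crops are user-supplied rather than auto-segmented.

## Elasticity

The stretching-modulus fit uses the linear-in-A parameterization
Σ = (K_A/A₀)·A − K_A, i.e. ordinary least squares with K_A = −intercept
and A₀ recovered from intercept/slope — the same optimum as the nonlinear
strain form but with better conditioning. Degenerate area spacing and
zero tension variation raise; a negative fitted K_A warns. The coupling
constant is 1/β = K d²/κ (12 bound leaflets, 24 polymer-brush prediction,
48 free sliding). Volume conservation of an elastic sheet gives
Δd/d₀ = (ΔA/A)/(1 + ΔA/A). All percent outputs carry sign; monolayer
expansion is reported as 100 (A_cis − A_trans)/A_trans so the larger
cis molecular area gives a positive number.

## Problem sizes and reproducibility

Every generator takes an explicit integer seed and is bit-reproducible;
recovery protocols derive per-replicate 31-bit seeds from a master seed
via `numpy.random.default_rng`. The validation protocols use the study's
own problem sizes — 3000 frames × 256 contour points per flicker stack,
10 vesicles of 3–10 µm per capacitance fit, 256×256 height maps, 100
frames/s traces, 5 tension–area points at 1–8% strain — with medians over
100 replicates (flicker, AFM) or 200 replicates (capacitance, kinetics,
stretching); the full set completes in well under a minute on one CPU.

## Known limitations

* Absolute bending rigidities of real compositions require the original
  videos; only normalized ratios and synthetic recovery are meaningful
  here.
* The sweep model captures only the crossing point, not the full
  electrokinetic shape response across frequency.
* The interleaflet-coupling endpoints for specific compositions need
  per-composition κ and d from simulation trajectories; the package
  provides the formula and its validation, not those inputs.
* ANOVA p-values for specific experiments require the per-vesicle raw
  measurements, which are not reconstructable from summary statistics.
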