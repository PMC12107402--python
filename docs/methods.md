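# Methods

This note records the models behind `oceandark`, the defaults that matter,
the numerical choices, and what the synthetic tests do and do not show.

## Trend detection

Each pixel carries a short annual series (default 2003–2022, n = 20) of
K_d(490) in m⁻¹. The chain is:

1. **ARIMA prefilter.** The most parsimonious ARIMA(p,1,q) model with a
   drift term is selected by AIC over p, q ∈ {0, 1, 2}; d = 1 is fixed.
   Twenty points cannot support larger orders, and the drift (a constant in
   the differences) is required for the fitted values of a trending series
   to carry that trend forward. Estimation is by conditional sum of squares
   on the differenced series: pure-AR models solve exactly by least
   squares, mixed models by a Levenberg–Marquardt refinement of
   Hannan–Rissanen starting values, with AIC from the Gaussian CSS
   likelihood (n_eff = n − 1 − p, k = p + q + 2). CSS is standard for short
   series and is two orders of magnitude faster than state-space maximum
   likelihood, which matters when millions of pixels are mapped; the
   state-space engine (`engine="statespace"`, via statsmodels) remains
   available and the two are cross-checked in the test suite. In-sample
   one-step fitted values are reconstructed on the level scale as
   ŷ_t = y_{t−1} + ŵ_t; the first fitted value equals the first
   observation, since no information precedes it once a difference is
   taken. A failed fit cascades to (0,1,0)+drift and then to
   "insufficient data".

2. **Median quantile regression.** A τ = 0.5 regression of the fitted
   values on calendar year gives the rate of change; regression to the
   median is robust to outlying years and assumption-free about the error
   distribution. Perfectly collinear input short-circuits to the exact
   interpolating line (iteratively reweighted fitting is fragile when every
   residual is zero).

3. **Rank-inversion confidence interval.** The 95% CI for the slope
   inverts the quantile-regression rank-score test (iid-error variant): for
   a hypothesized slope b, the intercept-only median of y − b·x yields
   regression rank scores (midrank-fractional at ties), and the normalized
   score statistic is monotonically nonincreasing in b, so the interval
   endpoints are found by bisection. A pixel is classified *increasing*
   when the CI lies above zero, *decreasing* below, *no change* otherwise.

4. **Endpoint prediction.** Significant pixels evaluate the regression
   line at the first and last year (floored at the K_d validity minimum,
   0.01 m⁻¹); non-significant pixels take the median of the observed
   series as both endpoints — no change in K_d implies no change in photic
   depth.

Pixels need ≥ 10 of 20 valid years; interior gaps are linearly
interpolated for the ARIMA stage only, and interpolated years are excluded
from the quantile regression. Results are independent of worker count and
pixel order.

### Known limitation: anti-conservative classification

The rank-score CI is exact under iid errors, and the implementation
reproduces the nominal level on iid series (measured ~5% at n = 20). The
chain as a whole, however, computes that CI on **ARIMA fitted values**,
which are one-step predictions and therefore retain serial dependence: for
a drifted random walk they are essentially the lagged series, and when the
differencing over-differences a stationary series the AIC-selected MA
terms push toward θ = −1, producing smooth, strongly dependent fitted
curves. On null AR(1) series with φ = 0.5 the measured significant
fraction is ≈ 0.32 (CSS engine; the exact-MLE engine is higher still) —
the familiar (1+φ)/(1−φ) variance inflation of trend tests under positive
autocorrelation, which the prefilter removes from the residuals but not
from the fitted values the CI is computed on. Classification maps from
this procedure should therefore be read as anti-conservative on
autocorrelated nulls: effective false-positive rates are well above the
nominal 5%. The acceptance suite asserts the nominal-level expectation and
documents this failure rather than hiding it.

## Surface irradiance

**TOA solar.** A packaged extraterrestrial spectrum H₀(λ) on a 1 nm grid
(350–700 nm) is scaled by the orbital-eccentricity factor
[1 + ε·cos(2π(D−3)/365)]², ε = 0.0167, with a 365-day denominator in all
years. The packaged table is a smooth synthetic stand-in (a 5772 K Planck
spectrum scaled to the ~1361 W m⁻² solar constant; H₀(490) ≈ 1.78
W m⁻² nm⁻¹), adequate for band-integrated work near 490 nm; any tabulated
reference spectrum can be substituted via `SolarConfig`.

**Clear-sky marine atmosphere.** The Gregg–Carder-style model computes,
per wavelength: Kasten air mass (pressure-corrected for Rayleigh, a
dedicated ozone air mass), Rayleigh transmittance, Angström-law aerosol
transmittance with optical thickness from horizontal visibility (τ₅₅₀ ≈
0.158 at the default 23 km) and exponent 0.5 (spectrally flat marine
aerosol), Chappuis-band ozone, oxygen and water-vapour absorption from
packaged synthetic band-shape tables (all ≈ 0 in 485–495 nm), and a
direct beam TOA·cosθ·ΠT. Diffuse irradiance is single-scattering
Rayleigh (half of the scattered flux downward) plus forward-scattered
aerosol with the asymmetry-parameter forward-fraction (g = 0.65, single-
scatter albedo 0.95). Global = direct + diffuse exactly, direct ≤
TOA·cosθ everywhere, and the band integral decreases monotonically with
zenith angle; a luminary at or below the horizon yields exactly zero.
Defaults (1013.25 hPa, 2.5 cm water vapour, 350 DU ozone, RH 80%, wind
5 m s⁻¹, visibility 23 km, marine air mass) are canonical marine values
and all overridable. No air–sea interface transmission is applied: the
photic-zone inversion consumes the just-above-surface (0⁺) irradiance.

**Lunar irradiance.** The Moon is a Lambertian disk: E_moon(λ) =
E_sun(λ)·A(λ)·f(α)·θ_s², with the spectral albedo A(λ) a smooth packaged
curve (~0.085 at 490 nm, mildly reddening), the phase factor f normalized
to 1 at opposition and implemented with the two-term H,G analytic phase
functions (slope parameter G = 0.08, a steep lunar-like opposition
surge), and θ_s = 0.26° the fixed mean semi-diameter in radians (no
time-varying Earth–Moon distance). The full-moon/solar TOA band ratio is
then ~1.7 × 10⁻⁶ at opposition, and scales with θ_s² and A.

**Ephemeris.** Solar position uses the standard low-precision series
(declination via Spencer's formula for the noon zenith |φ − δ|); lunar
ecliptic position uses a truncated ELP-style periodic series (16
longitude, 8 latitude, 9 distance terms; residual ~0.01° geocentric) with
a topocentric parallax correction (up to ~1° at the horizon). Full moons
minimize the Sun–Moon–observer phase angle within each calendar month
(3-hour scan + bounded refinement); culminations maximize apparent
altitude on the full-moon civil date (10-minute scan + refinement that may
resolve a boundary maximum to a transit a few minutes outside the date).
Computed 2022 full moons fall within ~0.6 h of the published almanac
instants, whose May and November entries are pinned independently by that
year's total lunar eclipses.

**The monthly field.** Sunlight: 15th of each month at solar noon (the
longitude-free minimum daily zenith). Moonlight: the month's full-moon
culmination computed once at longitude 0, after which zenith varies with
latitude as |φ − δ_moon| plus parallax. Two physically necessary
qualifications to intuitive invariants: (i) during polar night the full
moon (opposite the sun) can be above the horizon while the noon sun never
rises, so moonlight legitimately exceeds sunlight there; (ii) the
June/December mirror symmetry of noon irradiance across the equator holds
to ~0.2% only once the eccentricity factor is removed — perihelion in
early January makes austral summer ~6.9% brighter, per (1±ε)².

## Photic-zone inversion

Z = −(1/K_d)·ln(I_sens/I₀) with K_d vertically constant (no mixed-layer or
deep-chlorophyll-maximum structure), floored at 0 when I₀ ≤ I_sens
(including polar-night zeros, which still contribute to the 12-month
average), clipped to bathymetry with ties counting as clipped, and
differenced **after** clipping. The default threshold 0.027 µW m⁻²
(converted once to 2.7 × 10⁻⁸ W m⁻² at config parse) is the *Calanus*
photosensitivity minimum; because Z depends on I_sens only through a
log-offset, the proportional change z_end/z_start = kd_start/kd_end is
exactly independent of the threshold for unclipped pixels — the formal
statement that proportional photic-zone loss is the same for every species
regardless of photosensitivity. Percent change where the start depth is
zero is defined as 0 and flagged.

## Areas and aggregation

Spherical mode (default) uses exact cell areas R²·Δλ·(sinφ₂ − sinφ₁) with
R = 6371.0088 km; summed over a 1° global grid this reproduces 4πR² to
better than 0.1%. Mercator-grid mode assigns each point of an s-metre
Mercator grid its ground footprint (s·cosφ)², for fidelity with workflows
that count constant-spacing Mercator points; the projection is not
equal-area, and per-cell values differ from spherical by a cosφ factor,
but **regional totals** agree (point density compensates the footprint),
which the tests verify at low latitude. Thresholds use strict ">" on the
reduction magnitude; histogram bins are left-open (0,10], (10,20], …;
pixels with insufficient data are excluded from every percentage
denominator. Region tables rank by percent-of-region increasing.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
per-pixel linear trends (positive/negative/null, with planted-truth maps
returned for parameter recovery), additive stationary AR(1) noise
(innovation SD σ, marginal variance σ²/(1−φ²); default φ = 0.5 because
the ARIMA stage must have autocorrelation to remove, σ = 0.005 m⁻¹ as a
plausible open-ocean annual-composite jitter — the literature reports no
calibrated value, so these are sensitivity-sweep defaults, not
measurements), clamping to the K_d(490) product validity range
(0.01, 6.4] m⁻¹, independent 5% per-pixel-per-year dropout (polar-night
whole-winter dropout available), a smooth shelf/abyss bathymetry
(edge-distance ramp, default 50 → 4000 m, plus correlated roughness), and
contiguous Voronoi region masks. Synthetic grids are regular lat/lon so
that truth maps stay exact; the Mercator point-grid resampler covers
projected-grid fidelity separately. What passing tests do **not** show:
real MODIS radiometry, retrieval-algorithm bias in turbid coastal water,
spatially correlated noise, or cloud-driven gap structure — conclusions
about real archives require the real archive.

## Problem sizes and determinism

Single-seed reproducibility is enforced end to end (same config + seed ⇒
identical CSV digests). The shipped tests and the acceptance script run
planted-truth recovery at 32–64² pixels × 20 years and Monte-Carlo error
rates at 2000 null series, sizes at which every statistical property
checked is already stable; the per-pixel chain runs at ~6 ms/pixel, so a
9 km global grid (~10⁷ ocean pixels) is a routine parallel batch job with
the same code path.
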