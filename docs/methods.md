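# Methods

This note documents the models and numerical choices behind `ftirlip`: the
preprocessing chain, the band analytics, the GC reference arithmetic, the
calibration machinery, and the synthetic-experiment generator that the test
suite and the acceptance script run against.

## Spectral model and preprocessing

Spectra are absorbance rows on a strictly descending wavenumber grid
(default 4000 → 502 cm⁻¹ at 6 cm⁻¹ spacing, 584 points). All selection is
by wavenumber value with closed interval bounds; mixed grids are rejected
rather than resampled, because silent interpolation is a classic source of
irreproducible chemometrics.

The standard chain is:

1. **Technical-replicate averaging.** Arithmetic mean within
   (species, temperature, day, biological replicate); output order is
   sorted by group key, so the result is independent of input row order.

2. **Savitzky–Golay second derivative** — window 9 points, 2nd-degree
   polynomial. The derivative is taken with respect to wavenumber including
   the 1/h² spacing factor (units absorbance·cm²), so analytic tests
   against closed-form derivatives are possible; a config switch
   (`sg_scale_spacing=False`) gives the unscaled vendor-style output.
   Edge points where the full window does not fit are trimmed (half-window
   at each end) instead of polynomial edge-fitting: edge artifacts would
   otherwise enter the EMSC fit. Note the inherent smoothing bias of a
   local-quadratic filter: for a unit Gaussian band of σ = 15 cm⁻¹ on this
   grid the maximum deviation from the analytic second derivative is
   2.0·10⁻³ (≈ 45 % of the derivative's peak, because the 48 cm⁻¹ window
   spans 3.2 σ). Sharper windows reduce bias but amplify noise; window 9 is
   the conventional compromise at 6 cm⁻¹ resolution.

3. **EMSC** on the combined 3100–2800 + 1800–500 cm⁻¹ range (the regions
   carrying the microbially diagnostic bands), as **one** least-squares
   problem over the concatenated grid, not per region. Each derivative
   spectrum z is modelled as
   `z = a·1 + c·p₁ + d·p₂ + b·r + e`, where r is the reference spectrum
   and p₁, p₂ are the wavenumber axis mapped affinely to [−1, 1] and its
   square (raw wavenumbers squared reach 10⁷ and make normal equations
   ill-conditioned; the mapped basis is numerically benign and the
   coefficients are reported in it). The corrected spectrum is
   `(z − a − c·p₁ − d·p₂)/b`. |b| < 10⁻⁸ raises an error naming the
   sample; polynomial order is configurable (order 0 recovers classic MSC).
   The reference defaults to the mean of the set being corrected; a fixed
   external reference can be supplied, which is what the cross-validation
   uses (below).

Whether the derivative should be taken before or after region restriction
is genuinely open; this package derives first and then selects, so the
derivative never sees an artificial discontinuity at region boundaries.

## Band analytics

On second-derivative spectra, absorbance maxima appear as minima, so band
intensity is the **negated window minimum** (ester carbonyl: window
1760–1730 cm⁻¹ around 1745; both window and mode are config keys). Band
position (olefinic =C–H, window 3020–2995 cm⁻¹) is refined below the grid
spacing by a three-point parabolic interpolation through the discrete
extremum and its neighbours — exact for a symmetric peak, and within
±0.6 cm⁻¹ for Gaussian bands on the 6 cm⁻¹ grid. An extremum on the window
boundary cannot be refined; it is returned as-is with a warning.

Replicate reproducibility is summarized as the mean over groups of the
average pairwise Pearson correlation between member spectra, computed on
preprocessed spectra over the full combined region by default (level
"technical" groups within a biological replicate, "biological" within a
condition-day). The region is configurable because published
reproducibility figures do not always state it.

## GC reference arithmetic

FAME masses follow the internal-standard relation
`mass_i = (area_i / area_IS) · RRF_i · mass_IS`; composition is mass as %
of total FAME mass (it therefore sums to exactly 100 before any rounding,
whatever the RRFs), and **total lipid** is defined as total FAME mass as %
of dry biomass — the fatty-acid-based lipid content a
direct-transesterification protocol measures, with no FAME→TAG mass
correction. Ingested composition tables may sum to 100 ± 0.5 (published
tables round minor acids); an optional renormalization rescales rows to
exactly 100.

The unsaturation index is
`UI = Σᵢ (%ᵢ · nᵢ) / 100` with nᵢ the double-bond count of acid i —
equivalently [Σ(% monoene) + 2·Σ(% diene) + 3·Σ(% triene)]/100 for the
acids in scope, i.e. the mean number of double bonds per fatty-acyl chain.
The built-in descriptor catalogue covers C12:0–C24:0 saturates, C16:1,
C18:1n9, C18:2n6, C18:3n6, C18:3n3 and C20:4n6, and is user-extensible.

Pooled SD over replicate groups uses the usual
`sqrt(Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1))` with n−1 group SDs.

## Calibration

One PLS1 model per response (NIPALS, mean-centering only, no variance
scaling of X, deterministic — no random initialisation anywhere).
PLS1-per-response rather than PLS2 because calibration tables in this field
report different factor counts per response; PLS2 is available for a shared
decomposition. With k components the coefficients are
`B = W(PᵀW)⁻¹Qᵀ`; at full rank PLS reproduces the least-squares solution
(asserted against a normal-equations oracle in the tests, and
cross-checked against scikit-learn's PLSRegression).

**Leave-one-day-out cross-validation**: all samples measured on the same
cultivation day form one segment; each day is held out in turn and
predicted by a model fit on the remaining days, for 1–25 components. This
is the honest validation for a monitoring platform — the model must
predict an unseen *time point*, not an unseen replicate of a seen one.
Leak-freedom is enforced structurally: X/y centering comes from the
training days only, and by default the EMSC reference is recomputed from
each fold's training spectra and applied to the held-out day
(`emsc_policy="per-fold"`; a "global" switch reproduces the simpler common
practice of correcting everything once up front).

The component count is the smallest k whose pooled RMSE is within one
between-segment standard error of the minimum (one-SE rule), i.e. the most
parsimonious model statistically indistinguishable from the best — the
criterion "insignificantly higher RMSE than the minimum" operationalized;
the SE is the SD of per-segment RMSEs at the minimizing k divided by
√(number of segments). The chosen k never exceeds the argmin.

Reported per response: reference min–max, mean, SD (n−1), cross-validated
R² (squared Pearson correlation of pooled CV predictions vs reference),
RMSECV, RPD_CV = SD/RMSECV (exactly, before any display rounding; infinite
for a perfect model), and the factor count. The text renderer rounds to
1 decimal (2 for small-magnitude responses such as the unsaturation index);
full precision is kept internally.

`build_calibration` joins spectra to the GC table on
(species, temperature, day) — one pooled GC composition maps onto all
biological-replicate spectra of that condition — applies an optional
exclusion list of condition-days (early-growth biomass measured before
lipogenesis starts does not follow the lipid-dominated
spectrum↔composition relationship and is conventionally excluded), and
runs one day-segmented CV per response.

## The synthetic-experiment generator

`generate_experiment` emulates a microtiter-plate screening study:
3 species × 2 temperatures (20/30 °C) × 12 days × 3 biological × 3
technical replicates (648 raw spectra, 216 biological samples; a drop-list
reproduces incomplete designs such as a 210-sample study). All randomness
flows through one seeded generator; identical seeds give bitwise-identical
outputs.

**Spectra** are Beer–Lambert mixtures of Gaussian-band pure components
(Gaussian rather than Voigt so second derivatives have closed forms):

- *lipid*: acyl CH₃/CH₂ stretches (2955/2925/2850), ester carbonyl (1745),
  CH₂ scissor/rock (1465/725), plus one olefinic =C–H sub-band per
  double-bond class — monoene 3004, diene 3008, triene 3011 (n-6) or
  3014 cm⁻¹ (n-3) — each weighted by its =C–H oscillator count
  (class double bonds × class fraction). The aggregate olefinic maximum
  therefore drifts up with the unsaturation index, consistent with the
  linear anchor relation `olefinic_center(UI)` through (0.93, 3006 cm⁻¹)
  and (1.43, 3012 cm⁻¹) that the package exposes; the two triene isomers
  are given slightly different centers, as the band position of the n-3
  isomer sits higher.
- *protein*: amide I/II (1650/1540); *carbohydrate*: glucan/C–O bands
  (1150/1080/1033); *polyphosphate*: 1260/880 cm⁻¹.

Per condition-day, the mixture is
`L·lipid + (1−L)·[w_p·protein + w_c·carbohydrate + w_pp·polyphosphate]`,
where the lipid fraction L(day) follows a logistic from 6 % of CDW to a
species×temperature plateau of 26–37 % (a biological ceiling of 70 % is
enforced), and the non-lipid weights drift with cultivation time —
cell-wall glucan rising everywhere and polyphosphate rising
species-specifically (strongly in *M. circinelloides*, weakly in
*P. glabrum*), the kind of fingerprint drift observed in real fungal
spectra. The fatty-acid composition interpolates from a PUFA-rich
growth-phase profile to a MUFA-rich stationary profile; because both the
composition shift and lipid accumulation are consequences of nitrogen
depletion, they share one logistic clock (onset day 3 at 30 °C, 4.5 at
20 °C, rate 1.2 d⁻¹). At 30 °C the stationary oil carries more diene and
less triene than at 20 °C. Day-to-day composition jitter is Dirichlet with
concentration 4000, putting the relative SD of the dominant acid near 2 % —
the reproducibility level of replicated GC composition measurements.

Measurement artifacts per technical replicate: multiplicative scatter
b ~ U(0.7, 1.3), additive offset (SD 0.02), linear/quadratic baseline
(±0.05 on the [−1,1]-mapped axis), white noise SD 0.002 absorbance units
(the regime of a 64-scan transmission measurement); biological replicates
get a lognormal amplitude jitter (σ = 0.03). Glucose declines
logistically from the 80 g/L medium with residuals per species×temperature
(the cold-stressed *M. circinelloides* leaves half the glucose unconsumed)
and replicate noise of SD 1.1 g/L. A `noise_free()` constructor switches
every stochastic term off for exact-ordering tests.

**What the generator does and does not emulate.** It reproduces the
covariance structure the analysis relies on: lipid bands growing at the
expense of amide bands, olefinic position/shape tracking unsaturation,
species- and time-specific fingerprints, scatter artifacts that EMSC must
remove, and matched GC/glucose tables with exact ground truth. It does
*not* emulate real band shapes (Voigt profiles, hydrogen-bonding shifts),
water-vapour/CO₂ interference, detector nonlinearity, Mie scattering of
intact cells, or biological phenomena beyond the planted kinetics
(pelleting, wall growth, autolysis). Passing recovery tests therefore
demonstrates that the pipeline is correct and leak-free and that the
planted signal levels are recoverable — not that any particular instrument
will achieve the same figures. One structural consequence of the strictly
linear Beer–Lambert world: responses expressed as % of the lipid fraction
couple *bilinearly* to the lipid amount (the spectrum carries
L × composition products), so a linear calibration recovers summed
parameters (UI, PUFA, MUFA) well but individual minor acids — most
visibly the n-6 triene, whose absolute band intensity rises while its
percentage falls — only partially. Real spectra, with their much higher
effective rank, support stronger individual-acid models than this
simulation does.

## Numerical choices and degenerate inputs

- Wavenumber grids must be uniform within 1 % for the derivative step.
- EMSC rank-deficient designs raise; |b| < 10⁻⁸ names the offending sample.
- PLS stops extracting components when the residual carries no covariance
  with y (‖Xᵀy‖ ≈ 0); an all-orthogonal response yields zero coefficients
  and mean-only predictions rather than an error.
- Constant responses are rejected (undefined R²); perfect predictions
  report RPD as infinity rather than overflowing.
- Ties in component selection break toward fewer components.
- PCA uses SVD with a deterministic sign convention (largest-magnitude
  loading element positive per component).
- Problem sizes used in the shipped tests and acceptance run — the full
  648-spectrum design, 25-component CV over 12 day-segments, six
  responses — complete in a few seconds; they are the study-scale sizes,
  not reduced versions.

## Known limitations

- JCAMP-DX support covers only the uncompressed AFFN `(X++(Y..Y))` dialect.
- No outlier/leverage diagnostics beyond the degenerate-sample errors; no
  variable selection or orthogonal-signal-correction PLS variants.
- The Pearson-reproducibility region and the regression X-range default to
  the combined EMSC region; published figures of this kind do not always
  state their choices, so both are configurable rather than fixed.
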