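# Methods

## Scope and data model

`lciso` processes scan-level Orbitrap isotopologue data — one row per
(averaged spectrum × isotopologue) with intensity, peak noise, resolving
power, microscans, charge — into drift-corrected, calibrated δ values,
and simulates the full LC → capture → ESI → Orbitrap chain that produces
such data. Spectral extraction (peak picking, centroiding) is upstream:
intensities and noise are taken as given. The scan-table dialect is
tab-separated UTF-8 with fixed column names; a `channel` column records
the position of the reference-bracketing valve, which is not recoverable
from the spectra themselves (the simulator writes it; for real data a
bracketing schedule can be supplied instead). Times are minutes; scan
numbers are per-file and 1-based.

## Ion counting and block statistics

The number of ions behind a mass peak in one averaged spectrum is
`(S/N)·(C_N/z)·√(R_N/R)·√μ` with `C_N = 3` and `R_N = 240,000`. The
conversion is deterministic and kept real-valued: Poisson statistics
enter through the measurement, never the conversion, and the simulator's
inverse (`sn_from_ions`) round-trips to better than 1e-12 relative.
Blocks are half-open windows `[start, end)` so that consecutive blocks
partition time exactly; a block straddling a valve switch is an error
rather than being silently trimmed (guard-time trimming is the
scheduler's job). The shot-noise relative standard error of a block
ratio, `√(1/N_rare + 1/N_base)`, neglects covariance between the two
mass peaks — they are separate peaks read from the same spectra, and the
dominant common-mode term (total ion number) cancels in the ratio only
approximately; simulated z-scores confirm the approximation holds to
within ~15 % under realistic count rates.

## Bracketing, drift correction and uncertainty

Runs alternate reference/sample segments (default 20-min valve period,
reference first and last). The first 2 min of each segment are discarded
(`guard_min`, configurable) to let the source settle after a switch; the
value is a settling allowance chosen once, not fitted. Within segments,
consecutive 15-min blocks are formed from the usable start; a trailing
remainder shorter than one block is dropped.

Each sample block is referenced to the **linear interpolation** of the
two nearest bracketing reference-block ratios at the sample block's
mid-time. Any multiplicative drift linear in time between consecutive
reference blocks therefore cancels exactly; higher-order interpolation
schemes were rejected as untestable against ground truth. δ values are
propagated on the ratio scale and converted to ‰ once at reporting.

The combined 95 % CI uses `SE = √(s_s²/n_s + s_r²/n_r)` with
Welch–Satterthwaite degrees of freedom and the two-sided t quantile.
The reference-side scatter is computed **after removing the linear time
trend** of the reference blocks: bracketing removes linear drift from the
sample side, so leaving the raw drift trend in the reference scatter
would double-count a component the correction has already eliminated.
The residuals retain counting noise and any nonlinear drift. With only
5 reference blocks the two-parameter detrend slightly deflates the
variance estimate (ddof = 1 is kept for simplicity); the simulated
coverage of the interval is still 95 % ± 3 %.

One-point calibration is an offset through a single anchor; two-point
calibration is the affine map through two anchors and inverts any affine
scale distortion (such as a day-specific scale expansion) exactly. Note
that a one-point offset calibration leaves a second-order residual
(~δ·bias/1000) when the underlying bias is multiplicative — visible in
the simulated standard recoveries as a ≲0.2 ‰ shortfall at +18.2 ‰.

The Allan deviation is the non-overlapping estimator
`σ_A(τ) = √(½·mean[(ȳ_{k+1} − ȳ_k)²])` over consecutive τ-averages; τ
values leaving fewer than two averages are skipped with a warning. Under
pure counting noise σ_A ∝ τ^(−1/2); a linear drift adds a term growing
as τ, placing the optimal integration time at the crossover.

Exact masses sum nuclide masses (2020 atomic-mass evaluation, rounded at
1e-8 u) and correct by one electron mass according to polarity. All
printed m/z values of the three sulfamethoxazole fragments (F99 positive;
F92 and F64 negative) are reproduced within 0.001. Computed values that
deviate from a supplied nominal m/z by more than 0.001 are flagged with a
warning, not forced into agreement. The mass-dependent δ³³S expectation
uses the conventional exponent 0.515.

## The simulator: what it emulates

The generator's defaults are the documented operating conditions of the
hyphenated setup: 0.5 mL/min analytical flow, 4 μL/min infusion flow,
540-μL capillary (0.7 mm i.d.), 1140-μL mixing chamber, 80-s capture
window, AGC target 1.5×10⁵ charges per fill, 10 microscans, 1000 ms
maximum injection time, resolution 90,000 (F99/F92) or 30,000 (F64),
4 μM syringe reference, 20-min bracketing with 15-min processing blocks.

**Chromatography.** Each isotopologue elutes as a Gaussian of common
width σ (default 15 s), the heavier species offset by a signed retention
shift Δt_R (positive = more retained, the "normal" effect; default
+0.075 s for ³⁴S in the capillary scenario). The instantaneous
heavy/light log-ratio is then linear in time with slope Δt_R/σ², so a
±2σ window spans 1000·4Δt_R/σ ‰ — 20 ‰ at the defaults. Isotopologue
abundances assume a stochastic (binomial) distribution: the singly
substituted over unsubstituted ratio is n_atoms × atom ratio, with
13C/12C = 0.0107/0.9893, 15N/14N = 0.00364/0.99636,
34S/32S = 0.0425/0.9499, 33S/32S = 0.0075/0.9499.

**Capillary capture** is plug flow: the loaded slug elutes time-reversed
(last-captured fluid reaches the source first) with times stretched by
the flow ratio (125× at defaults), conserving moles to < 1e-6. Loading
more than the capillary volume raises an overflow error quoting both
volumes; the default 80-s window at 0.5 mL/min (≈667 μL) exceeds the
540-μL capillary, so the capillary scenario uses a ±2σ (60 s, 500 μL)
window.

**Chamber capture** homogenizes all captured analyte instantaneously at
capture end (the 1-min stir), so outlet ratios are constant for the
entire elution. The washout is modeled as plug displacement with axial
dispersion, `C(t)/C₀ = Φ((τ − t)/σ_t)` with `τ = V/Q` and
`σ_t = τ·√(2/Pe)`, Péclet number 40 by default. An ideal stirred tank
would decay immediately, contradicting the observed ~3-h stable plateau;
the dispersed-front model reproduces it (C/C₀ crosses 0.95 at 180.2 min)
while remaining a one-parameter description. Pe = 40 is the single
calibrated geometry parameter.

**ESI amount-dependency** is a δ-shift on the rare/basepeak ratio,
`bias(c) = β·ln(min(c, c_lin)/c_ref)` — logarithmic below the linear
threshold, constant above, zero at the 4 μM reference concentration.
Defaults: ¹³C β = 65/ln 8 ‰ (−65 ‰ at 0.5 μM), c_lin = 10 μM; ³⁴S
β = 9/ln 8 ‰ (≤9 ‰ below 4 μM), c_lin = 4 μM; ³³S mass-dependently
scaled from ³⁴S; ¹⁵N intermediate (β = 30/ln 8 ‰, chosen between the
carbon and sulfur magnitudes). The bias acts on isotopologue
partitioning, not on total signal: the observable is a δ deviation, and
its mechanism is deliberately not modeled.

**Drift** multiplies the measured ratio by
`1 + (d_lin·t + walk(t))/1000`, defaults 1 ‰/h linear plus a 0.2 ‰/√h
random walk — a slow, partly non-removable drift of realistic size.
Both channels share one drift trace, which is what bracketing corrects.

**Scan generation.** Expected ions per spectrum are
`min(AGC, rate × max injection) × μ`, with the source rate 300 ions per
μM per ms — sized so the reference concentration fills the trap in
~125 ms, i.e. AGC-limited (shot-noise-limited at the AGC ceiling) for
concentrations ≳0.5 μM. The AGC target is applied per microscan fill
(whether the printed target is per fill or per averaged spectrum is not
documented; per fill was chosen). Counts are Poisson draws split across
isotopologues by the instantaneous composition × bias × distortion ×
drift; they are encoded with peak noise fixed at 1.0 so that intensity
directly encodes S/N and the ion-count round trip is exact. Spectrum
periods default to 2.0 s at resolution 90,000 and 0.75 s at 30,000
(transient-length scaling from the 240,000 reference at 10 microscans
plus overhead; no scan rate is documented). A `scale_distortion` factor
can expand measured δ about the natural ratio to emulate day-specific
scale expansions, making two-point-calibration recovery testable.

**What it does not emulate**, hence what passing tests do not show about
real data: electrospray physics and space-charge, real AGC prescan
behavior, isobaric interference, column equilibration, analyte
speciation chemistry (the large ¹⁵N variation of the aniline fragment is
reproducible only by configuring a large retention offset), dead-time or
coalescence effects, and day-to-day variability of the bias parameters.
Simulated precision is a shot-noise + configured-drift floor; real
instruments add excess noise, so simulated CIs are expected to undercut
measured ones.

## Problem sizes and numerics

Simulated runs use the full 180-min bracketed structure (≈5,400 spectra
at 2 s, ≈14,400 at 0.75 s). The acceptance script averages the capillary
span and precision targets over 10 seeded replicates and the standard
recoveries over 20 replicate run pairs; the test suite uses 3–5
replicates per scenario to keep the default run fast. Chromatograms are
evaluated on a σ/200 grid and capillary outlet profiles on a matching
grid so trapezoid quadrature conserves moles to < 1e-6; truncation at
±6σ contributes ~2e-9. The chamber stability time is found by Brent root
finding on the continuous front model. All randomness flows from a
single seed through `numpy` `SeedSequence` spawning; identical
configuration and seed produce byte-identical scan tables.

## Known limitations

- `combined_ci` treats sample and reference block values as i.i.d.;
  autocorrelation from the random-walk drift inflates true coverage
  error slightly at large walk amplitudes.
- The one-point calibration residual discussed above is inherent to
  offset calibrations under multiplicative bias, not a defect.
- The capillary model ignores Taylor dispersion during the 125×-slower
  elution; peak shape is exactly retained.
- Blocks are aligned to the bracketing schedule (segment start + guard),
  not to acquisition start; for unbracketed runs they align to t = 0.
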