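# Methods

## The aerodynamic power model

Muscle-mass-specific mechanical power during flapping flight is modelled as
the sum of induced and profile power under the standard assumption that
thoracic elastic storage absorbs the inertial power of wing oscillation:

```
P*_ind = κ (F_t/m_M) √(F_t / (2 ρ Φ R²))          [W kg⁻¹]
P*_pro = ρ S n³ Φ³ R³ r̂₃³(S) ⟨|dφ̂/dt̂|³⟩ C̄_D,pro / (16 m_M)
Re     = S n Φ / ν
```

The induced term is the actuator-disc momentum cost of supporting the total
flight force `F_t` over the disc area swept by a stroke of amplitude `Φ`
(radians) and wing length `R`; `κ ≥ 1` corrects for periodic vortex
shedding.  The profile term is the drag cost of moving the wings, with wing
area `S` (both wings), the dimensionless third moment of area `r̂₃³(S)`, and
the mean cube of the dimensionless stroke angular velocity
`⟨|dφ̂/dt̂|³⟩`.  The mean profile drag coefficient defaults to the
Reynolds-scaling approximation `7/√Re`; a fixed measured value can override
it per parameter set, and the default *Drosophila* fixture uses the
robotic-wing measurement 1.36 obtained at tethered-flight kinematics, which
exceeds the Re-based value (≈0.61 at `Re ≈ 130`).

Consequences used throughout the package: with a fixed drag coefficient,
`log P*_pro` is exactly linear in `log(nΦ)` with slope 3 (slope 2.5 with the
Re-based coefficient), and since profile power dominates at flight
amplitudes the constant-power isolines in the (n, Φ) plane are close to
`nΦ = const`.  A fixed muscle power budget therefore forces an inverse
amplitude–frequency relationship — the mechanism probed by the optogenetic
analyses.

### Default morphometrics

The bundled fixture is a plausible wild-type *Drosophila melanogaster*
parameter set, chosen once and documented here rather than fitted to
anything: flight force `F_t = 1.1e-5 N` (a ~1.1 mg fly hovering), air
density 1.2 kg m⁻³, wing length 2.5 mm, combined wing area 3.6 mm²,
flight-muscle mass 0.33 mg (~30 % of body mass), `κ = 1.2`,
`r̂₃³(S) = 0.26`, `ν = 1.5e-5 m² s⁻¹`.  `⟨|dφ̂/dt̂|³⟩` uses the sinusoidal-
stroke value `32π²/3 ≈ 105.3` (stroke angle normalised to the
half-amplitude).  With the fixed drag coefficient 1.36 this puts
`P*_mech ≈ 119 W kg⁻¹` at (212 Hz, 160°) and ≈190–200 W kg⁻¹ at the peak of
strongly activated kinematics (~240 Hz, ~170°) — the physiologically
expected order of magnitude for peak muscle power.  These values are a
documented stand-in, not a measured data set; analyses that depend on
absolute power levels should substitute measured morphometrics via the YAML
reader.

### Numerical choices

* Amplitudes cross public interfaces in degrees when flagged
  (`degrees=True`), matching wingbeat trackers; all evaluation is in radians.
* Isoline solving: at fixed `n`, `P*_mech(Φ)` diverges as `Φ → 0` (induced
  term `∝ Φ^-1/2`) and grows `∝ Φ³` at large `Φ`, so the level equation can
  have a low-amplitude induced branch and a high-amplitude profile branch.
  The solver brackets from the interior minimum upward and returns the
  profile-dominated branch — the physically relevant one, on which `Φ`
  decreases in `n`.  Brent root-finding at `xtol = 1e-14`; residuals are
  verified against a relative tolerance of 1e-9 and grid frequencies with no
  root are reported as omitted rather than silently dropped.
* The inverse problem (frequency at given amplitude and power) is closed
  form because the profile term is a pure power law in `n` (exponent 3 fixed
  cd, 2.5 Re-based) and the induced term is `n`-independent.

## Optogenetic trial scoring and the population-code regression

Each light pulse is scored on half-open windows `[onset−0.5 s, onset)` and
`[onset, onset+0.5 s)` — the onset sample counts once, in the response; the
convention is a package decision since sample-level conventions are not
usually printed.  Baseline and response are plain sample means of the
(L+R)/2 amplitude; `delta_wba` is their difference, which is invariant to
adding a constant to the whole trace.  The same windows applied to the
frequency channel give `baseline_freq`/`delta_freq`.  A peak-within-window
response metric is exposed as an option (`metric="peak"`), window mean being
the default and primary metric.

Trials are averaged within a fly (one measurement per individual), flies are
summarised per driver line by median and interquartile range
(linear-interpolation quantiles), and the dose–response fit is ordinary
least squares of line medians on the number of targeted cell pairs (several
lines may share a count).  `r²` is the squared Pearson correlation.  A
per-fly fit is available and is the observation unit for the
baseline-subtraction interaction test, an OLS of
`value ~ n_pairs * mode(BLS/RAW)` whose interaction p-value tests whether
baseline subtraction changes the slope.

The frequency-coupling regression fits per-fly `delta_freq` on
`baseline_freq`; under a shared power cap the slope is negative and the zero
crossing `−intercept/slope` estimates the baseline frequency above which
activation lowers frequency.

## The two-photon pipeline

Fixed order of operations (the source description interleaves these steps;
the order here is a package decision): (1) rigid registration of both
channels to the time-averaged tdTomato image using the integer-pixel peak of
the plain 2-D cross-correlation (no normalisation, no subpixel refinement),
exposed edges filled with the frame's median; (2) ROI masks = the 20 % most
temporally variable GCaMP pixels of each FOV half (split at `W//2`),
background = the 20 % dimmest pixels of the whole FOV on the temporal mean
image — floor counts, ties broken in raster order; (3) per-frame, per-channel
`F_t = mean(ROI) − mean(background)`; (4) ratiometric normalisation `G/R` on
those background-subtracted ROI means (not pixelwise), with the denominator
floored at `0.05 × median` — a shared per-frame gain (z-motion) multiplies
both channels and cancels exactly; (5) `F₀` = mean of the lowest 10 % of
`F_t`; (6) `ΔF/F = (F_t − F₀)/max(F_t − F₀)`, whose maximum is exactly 1 per
fly and side and which is invariant to positive affine transforms of the raw
intensities.  Whether ratio normalisation precedes or follows background
subtraction is ambiguous in the source description; subtracting background
per channel first is the adopted, documented choice.

Behaviour (32 Hz wingbeat amplitudes) is corrected for the tracker's ~30 ms
processing delay by evaluating the reported series at `t + 0.03 s` (linear
interpolation, edge hold) — a flag prevents double correction — then
interpolated onto frame times.  Epoch averages subtract the mean over the
1 s before stimulus onset (the baseline window length is a package decision)
and report a percentile bootstrap 95 % CI of the mean (default 1000
resamples, resampling units = epochs within a session or flies across
sessions), bit-for-bit reproducible given the seed.  Tuning curves z-score
both signals and bin ΔF/F into equal-occupancy quantile bins.  Pixel
correlation maps report per-pixel Pearson r against each wing's amplitude;
zero-variance pixels get r = 0 with an invalid flag.

## What the synthetic generators emulate — and what they do not

**Optogenetic sessions**: 30 pulses of 100 ms at 10 s intervals.  The
latent amplitude follows an exponential approach (τ = 50 ms) to
`baseline + gain`, holds through the 0.5 s response window, then decays
(τ = 300 ms).  Latent frequency rises linearly with amplitude
(1 Hz per degree) until mechanical power would exceed the cap, beyond which
it sits on the power isoline `P*_mech(n, Φ) = cap` — so the aero-power
module drives every opto simulation rather than an ad-hoc saturation curve.
The default cap is the power at the saturation amplitude (160°) and its
uncapped frequency, making the cap bind there exactly.  Gaussian noise on
the observed amplitude (2°), frequency (3 Hz) and left–right half-difference
(1°).

**Dose–response screens**: per-fly response = `intercept + slope·n_pairs +
N(0, sd)`, default slope 2.77°/pair, 15 lines (1–15 pairs), 8 flies/line,
sd 4°.  For the interaction test's null calibration the BLS and RAW rows are
drawn with independent per-observation noise — the textbook iid null of the
OLS interaction test; paired same-trial noise would make the nominal p
conservative.  A slope difference and per-fly baseline offset can be
injected for power checks.

**Imaging sessions**: one Gaussian arbor per hemisphere (different
anatomical brightness on the two sides, as in real preparations — which
also removes the half-FOV periodicity that would make cross-correlation
registration ambiguous), driven by a 13-pattern visual protocol (3 s epochs,
3 s static-starfield gaps, seeded shuffle) through a single-exponential
calcium kernel (τ = 0.6 s).  Behaviour couples each wing positively to the
*contralateral* hemisphere's activity (+15°/unit) and weakly negatively to
its own side (−5°/unit), which builds in the left–right amplitude
anticorrelation during asymmetric epochs.  The movie shares injected
integer motion jitter between channels (drawn in ±s pairs so the jitter has
exactly zero mean — the trial-average registration reference then sits on
the unshifted grid and exact shift recovery is well defined), a sinusoidal
z-drift gain multiplying both channels, and scaled-Gaussian shot noise
(`sd ∝ √intensity`); the tracker delay is injected into the reported
behaviour.  Presets: `small_noiseless` and `small_moderate`
(2100 frames of 32×64 px, two protocol blocks) keep simulations fast while
exercising every failure mode; the default config mirrors the recording
geometry (1600 frames, 64×128 px, 13.1 Hz).

Not emulated: biophysically realistic calcium dynamics and indicator
nonlinearity, subpixel or z-axis motion, neuropil contamination, bleaching,
cell-resolved demixing of the pooled arbor signal, spike-level dynamics, or
visual-pattern rendering.  Passing tests therefore certify the analysis
code's correctness on data obeying the stated generative assumptions, not
the robustness of the pipeline to every artefact of real recordings.

## Problem sizes and seeds

Simulation sizes used by the test suite and the acceptance script — 15-line
screens with 8 flies/line, 7-fly baseline-frequency sweeps at 500 Hz
sampling with 10 trials each, 2100-frame 32×64 movies, 500-replicate
calibration and coverage runs with 1000 bootstrap resamples — were chosen as
the package's own working sizes: large enough that the statistical
assertions are stable across seeds, small enough to iterate on quickly.
Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); generators are bit-reproducible given their
config, and pipeline outputs are byte-identical across reruns with the same
inputs and seed.

## Known limitations

* The morphometric fixture is plausible rather than measured; absolute
  power levels (isoline labels, the derived cap) carry that uncertainty,
  while the scaling relationships and trade-off structure do not.
* Registration is integer-pixel only, as in the emulated method; subpixel
  motion appears as residual noise in ΔF/F.
* The ΔF/F normalisation by the session maximum makes traces
  scale-comparable across flies but sensitive to the single brightest
  excursion; robust-max alternatives are deliberately not the default.
* The interaction test inherits OLS assumptions (homoscedastic, independent
  errors); with strongly paired BLS/RAW noise its p-values are conservative.
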