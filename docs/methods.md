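# Methods

This note records the scientific and numerical choices behind
`porpclick`: what is modelled, which conventions are fixed where the
field leaves room, and what a green test does and does not establish.

## Medium physics

Absorption uses the Francois–Garrison empirical model (boric-acid,
magnesium-sulfate and pure-water terms), evaluated per click at the
measured peak frequency when a spectrum is available and at 134 kHz
otherwise (the long-term mean peak frequency of NBHF porpoise clicks).
Inputs: temperature (°C), salinity (PSU), depth (m), pH. pH is almost
never logged on coastal moorings; the default is 8.0 (typical coastal
seawater) and is configurable (`WaterState.ph`). Averaged over a
coastal summer span (T 12–29 °C, S 30–34 PSU, 3.5 m depth) the model
gives α ≈ 0.048 dB/m at 134 kHz, the value the absorption test pins.

Sound speed uses Mackenzie (1981). No single shallow-water formula is
canonical; Mackenzie covers the relevant T/S/depth envelope and differs
from the Coppens/Del Grosso family by well under 1 m/s here, i.e. by
far less than the TDOA quantization error. Every geometric routine
takes `c` as a plain argument, so the formula is swappable.

## The synthetic scene: what it emulates, what it does not

Clicks are Gaussian-enveloped tone pips — the standard NBHF surrogate:
carrier 100–160 kHz (default 134), envelope σ default 15 µs, giving a
−3 dB bandwidth √(ln 2)/(π σ) ≈ 17.7 kHz and an e⁻²-threshold duration
of 4σ = 60 µs, inside the observed ranges for the species. The sampling
constraint σ·fs ≥ 8 at fs = 576 kHz puts a floor of ≈ 14 µs on σ.

Propagation is spherical spreading plus absorption applied per sensor,
`TL = 20 log10 r + r·α`, with per-sensor delays r/c. The array is
vertical: current meter at 2 m, stereo pulse loggers at 3 m and 4 m
(190 mm vertical baselines), calibrated recorder at 3.5 m. The recorder
waveform adds white ambient noise, optional low-passed vessel noise,
an optional surface-reflection ghost (delayed, attenuated copy), and
clips at the 172 dB re 1 µPa clip level — so overdriven clicks are
genuinely distorted, as on the instrument. Event streams carry one row
per pulse whose zero-to-peak pressure on the high-frequency channel
exceeds the 6.3 Pa detector threshold, with times quantized to the
0.5 ms event clock and TDOAs to a configurable resolution (default
2 µs; the true internal TDOA clock of such loggers is not public, so
this is an emulation knob, not a claim — the 0.5 ms event clock itself
could not resolve a 190 mm baseline, whose maximum geometric delay is
≈ 0.127 ms).

Deliberately not modelled: animal movement and beam patterns (the
rise-then-fall amplitude scan is imposed as a per-train envelope,
default a Hann profile with floor 0.35), multipath beyond the single
ghost, refraction, sea-state acoustics. A green round-trip test
therefore establishes that the *measurement chain* is unbiased on
clicks shaped like the model — not that the chain is robust to beam
aspect or reverberation, which field data add.

Ambient noise defaults: ordinary scenes use 85 dB re 1 µPa rms. Field
recordings report broadband rms noise of 112–124 dB, but that figure is
dominated by low-frequency energy far below the click band; in-band
(>100 kHz) ambient is much lower, and at the field figure the quieter
end of the simulated source-level span could never pass the
peak-to-peak SNR > 20 dB screen. The environmental-covariate tables
carry field-scale noise-level values independently of the waveform
noise floor. All randomness flows from one seed, with per-train
substreams derived deterministically; the same config + seed reproduces
byte-identical tables.

## Detection conventions

* Reflected-wave exclusion chains off *retained* pulses (< 1 ms rule),
  making it idempotent; the first pulse always survives.
* The "1–200 ms" window is read as the admissible inter-pulse interval,
  consistent with the separate < 1 ms reflection rule; reading it as a
  total-train-duration bound is available via
  `window_is_train_duration=True`.
* Buzz = ≥ 5 consecutive clicks with all flanking ICIs strictly
  < 10 ms (4 qualifying intervals).
* The buzz ratio is a percentage of buzzes over *non-buzz* click
  trains. This denominator is fixed by the published field counts this
  pipeline mirrors (110 buzzes against 1,257 click trains excluding
  buzz → 8.8 %); including buzzes in the denominator would give 8.0 %.

## Localization conventions

* Bearings are signed angles off the broadside plane, positive toward
  the deeper hydrophone: θ = arcsin(c·Δt/d). TDOAs exceeding d/c by
  ≤ 5 % (quantization) clamp to endfire with a warning; larger excesses
  raise.
* Range comes from intersecting the two loggers' bearing lines in the
  vertical plane and is referenced to the array midpoint (co-located
  with the calibrated recorder), matching the transmission-loss path.
  Bearing separations < 0.5° return `geometry_ok=False` (unresolvable
  or distant source), not an error. Range error grows with range at
  fixed TDOA resolution; at 2 µs quantization the top/bottom bearing
  difference falls below the quantization step beyond ~40 m, so
  long-range triangulations are noisy by physics, not by bug — the
  round-trip contract is a ≤ 3 dB median ASL error with triangulated
  ranges, versus ≤ 1 dB with exact ranges.
* The species pressure ratio is low-frequency-sensitive channel over
  high-frequency-sensitive channel, pass iff ≥ 0.6. NBHF clicks still
  register at ~0.75 relative response on a 70-kHz-peaked hydrophone,
  so porpoise clicks pass while lower-frequency broadband clicks drive
  the ratio out of band. The orientation is a config flag
  (`ratio_orientation`) because instrument conventions vary.

## Screening operationalizations

Criteria applied by eye in manual workflows are made numeric here, and
validated only on synthetic scenes:

* *Rise-then-fall*: the max-amplitude click is interior to the train
  AND a 3-point moving average of the per-click peak-to-peak amplitudes
  has exactly one interior local maximum (a monotone ramp has none).
* *Undistorted*: no sample at ≥ 99.9 % of the clip level, and a
  smoothed (11-sample) analytic-signal envelope has a single mode above
  half its maximum.
* *Ghost comparison*: the primary envelope peak must exceed the
  envelope maximum in a [0.2, 5] ms trailing window (covering
  surface/bottom paths at the deployment depths; config-exposed).
* Snippets are 512 samples centred on the envelope peak found within
  ±1 ms of the event time — wide enough for event-clock quantization
  plus the logger-to-recorder path difference, narrow enough that a
  trailing ghost cannot capture the centring.
* SNR is peak-to-peak: 20·log10(pp_signal/pp_noise) against a 5 ms
  noise window ending 7 ms before the click.

Every rejection names its failed criteria in the audit table.

## Click parameters

* RL is peak-to-peak re 1 µPa, consistent with the pp SNR rule and
  NBHF practice (rms selectable via `rl_convention="rms"`).
* Spectra: Hann window over a 512-sample snippet (short snippets are
  centre-padded so the taper does not bite into the pip), zero-padded
  to 4096 points (~141 Hz bins at 576 kHz). The −3 dB edges are the
  first crossings walking outward from the peak, linearly interpolated
  between bins — so a minor lobe ≥ 3 dB down never joins the band.
* Center frequency is the midpoint of the two −3 dB crossings (a
  bespoke convention of this analysis family — NOT the spectral
  centroid), and bandwidth is their separation.
* Duration is the first-to-last crossing of the envelope above the
  background level, where background is the envelope peak of a
  pre-click noise window (multiplier configurable, default 1.0). This
  makes duration SNR-dependent by construction, as in any
  threshold-crossing definition.
* Train ICI is the mean of the two intervals flanking the
  max-amplitude click; clicks per train is the train length.

## Environmental covariates

Day/night uses a NOAA-style solar-position computation (zenith 90.833°)
at the station coordinates, cross-checked in the tests against an
independently transcribed sunrise-equation oracle; a published
(date, sunrise, sunset) override table takes precedence when supplied,
so any almanac can be reproduced exactly. Polar latitudes raise an
explicit unsupported-latitude error. Noise level is the rms (dB re
1 µPa) of the two 1-minute windows flanking a train, DC-removed, pooled
by default (`combine="mean_of_levels"` selects the alternative reading;
the two differ by < 0.2 dB on stationary noise). Sparse series
(monthly salinity, 5-minute temperature/flow bursts) join
nearest-in-time with ties to the earlier sample. Vessel presence is an
input label column — simulation truth or human annotation; no vessel
detector is implemented.

## Model selection

ASL is gaussian with identity link; the strictly positive responses are
gamma with log link. (A printed "logit link" in the source workflow is
incompatible with these families and is not taken literally; inverse
and identity links are selectable for the gamma family.)

Conventions follow R's `glm` so selection tables are comparable with R
output: gaussian log-likelihood at the ML variance RSS/n; gamma
log-likelihood with the deviance-based dispersion dev/n; df = number of
coefficients + 1 for the scale/dispersion. AIC = −2ℓ + 2·df and
AICc = AIC + 2·df(df+1)/(n−df−1). `dredge` enumerates every
marginality-valid term subset (the vessel × day/night interaction
requires both mains; 80 candidates for the full 7-term set), ranks by
**AICc** — the criterion MuMIn's dredge ranks by, and the one whose
values published selection tables of this workflow print — and
computes Akaike weights over the full candidate set (they sum to 1 to
1e-12). The ranked table is invariant to row order and to term listing
order (canonical term labels, deterministic tie-breaks by delta, df,
label). Model averaging is not performed; the best model's coefficient
table is reported. Complete-case analysis only.

Site comparisons use Student's t (ASL) or Mann–Whitney U, with the
conventional encoding: 0.01 ≤ p < 0.05 as >/<, p < 0.01 as >>/<<,
direction by which site is larger.

## Known limitations

* The triangulation formula is an equivalent-geometry reconstruction
  (law-of-sines intersection); the original instrument software's exact
  trigonometric form is not public, so agreement is validated against
  the simulator, not against that software.
* Screening criteria 3 and 5 are numeric stand-ins for visual
  inspection; thresholds (smoothing windows, mode floor) were fixed a
  priori and only synthetic scenes certify them.
* The gamma-family link actually used in comparable field analyses is
  uncertain; AICc values for gamma responses depend on it.
* Duration and SNR are peak-to-peak/threshold quantities and therefore
  degrade gracefully but measurably as noise rises; the acceptance
  contracts are stated as medians for this reason.
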