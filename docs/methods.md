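# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `audiotactile` pipeline, in the spirit of a package
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Experimental model

The pipeline targets passive auditory–tactile experiments imaged at 5 Hz:
blocks of sixteen 500 ms sinusoidal whisker deflections (2–128 Hz,
geometrically spaced, randomized within a block, onsets 2 s apart)
interleaved with blocks of SAM tones and combined tactile+tone
presentations. Stimulus intensity is parameterized by frequency; the
equivalent mean angular deflection speed is
atan(amplitude/needle distance) × 2 × frequency (66.8°/s at 2 Hz for a
0.6 mm deflection 2 mm from the skin, i.e. 33.4°/s per Hz).

## Trace processing

**Baseline.** F₀ is fit in two passes: a rolling 8th-percentile filter
(60 s window) smoothed with a 10 s Gaussian gives a rough lower envelope;
samples more than 3 robust SD above it (putative transients) are then
masked, the remaining samples interpolated and re-smoothed. The second
pass removes the downward bias a raw low-percentile filter shows on
drifting traces while still excluding transients. F₀ ≤ 0 anywhere is a
degenerate-trace error.

**Neuropil subtraction** removes `coef ×` the *mean-centred* neuropil
trace (default coef 1.0). Centring means the somatic baseline keeps its
level and only fluctuations are removed, so corrected fluorescence stays
positive for realistic traces.

**Deconvolution** solves min‖c − ΔF/F₀‖² subject to
s_t = c_t − γ c_{t−1} ≥ 0, with γ = exp(−1/(τ·rate)) and τ = 0.7 s, by an
O(n) pool-adjacent-violators pass. This is exactly the non-negative least
squares problem against the exponential kernel exp(−t/τ); the test suite
checks equality with a brute-force NNLS solve to 10⁻⁴ per frame. Event
amplitudes below a per-neuron threshold (2 × the MAD of the deconvolved
amplitudes; for very sparse traces the MAD is 0 and no threshold applies)
are zeroed.

**Responses.** A frame belongs to a presentation's window if its start
time lies in [onset, onset + 0.6 s) — half-open and onset-inclusive, which
is exactly 3 frames at 5 Hz. The response is the mean event amplitude over
those frames scaled to events/s, minus the neuron's mean event rate over
frames belonging to no window (the inter-stimulus baseline). Presentations
whose window runs past the trace end are flagged and excluded.

## Responsiveness and selectivity

The score sums three components, each mapped through x/(x + c):
−log₁₀ p of a one-way ANOVA across stimulus levels (c = 2), the summed
positive tuning-curve area in events/s (c = 5), and the in/out activity
ratio minus one (c = 1); threshold θ = 1.0 of a maximum 3. With a single
stimulus level (typical for sound-alone blocks) the ANOVA component is 0
with a warning. The constants and θ were calibrated with
`scripts/calibrate_threshold.py` on the default synthetic population:
shuffle false-positive rate below 0.2% with power above 90% on
default-gain responders. The shuffle null circularly time-shifts all
stimulus onsets jointly (preserving trace autocorrelation — a stricter
null for slow calcium signals than label permutation) and re-runs scoring
on the already-deconvolved events.

Selectivity: responsive to touch only → touch-selective; responsive to any
sound stimulus set only → sound-selective; both → `both` (excluded from
spatial group analyses); neither → none.

## Tuning and BTF

Tuning curves average repeats per frequency and normalize to the
mode-appropriate maximum (within the tactile condition; across tactile and
combined; or across three modalities). The BTF averages, in the octave
(log₂) domain, (1) the response-weighted mean frequency over significant
responses (weights clipped at 0) and (2) the argmax frequency (ties to the
lowest frequency, for determinism); frequencies are log-spaced so octaves
are the natural scale. Per-frequency significance is a one-sided
(response > 0) one-sample t-test at p < 0.05 — one-sided because a
"significant response" is inherently positive here. Low/high categories
split at 60 Hz. Smooth fits use a GCV-selected cubic smoothing spline in
log₂ frequency, with a monotone (isotonic + PCHIP) option.

## Cross-modal statistics

Modulation class uses the sound main effect of a balanced two-way ANOVA
(tactile frequency × sound presence, with interaction), computed in closed
form for speed and verified against the statsmodels OLS route in the
tests; p ≥ 0.05 → no change, otherwise the sign of the mean sound effect
picks inhibited/facilitated. Unbalanced cells are trimmed to the smallest
repeat count with a warning.

ΔR = Σ(R_T+S − R_T)/Σ(R_T+S + R_T) over all tactile frequencies; it is
negative for inhibition, and summaries report the magnitude as a
percentage with the sign retained in the stored value.

r_sound(f) = (combined(f) − b)/(tactile(f) − b), evaluated only at
frequencies with a significant tactile response and tactile(f) > b. The
normalized population baseline default is b = 0.08, appropriate for curves
that are not baseline-corrected; inside `analyze_session` the responses
already have the inter-stimulus rate subtracted, so b = 0 is used there.
The fit is a monotone (non-decreasing) logistic in log₂ frequency; the
half-maximum is the fitted 0.5 crossing when it falls inside 2–128 Hz. A
u-shaped profile cannot be represented by this fit by construction; the
unconstrained spline in `tuning.smooth_fit` is available when that
possibility matters.

For sound-selective neurons the response ratio is
(r_lo − r_hi)/(r_lo + r_hi), with r_lo/r_hi the baseline-subtracted
(floored at 0) mean responses to sounds paired with 2–8 Hz and 76–128 Hz
touch; positive values mean suppression by high tactile frequencies. (An
alternative sign convention is selectable, as both appear in the
literature.) "Significant suppression" is a one-tailed rank-sum of hi-band
vs lo-band trials at p < 0.05. The 1.5×-baseline cutoff is the lowest
fitted frequency at which the combined response falls below 1.5 × baseline
(requires a positive baseline estimate).

## Behaviour GLM

Included trials: tactile alone, tactile+SAM, SAM alone, silent. The design
has an intercept, four tactile frequency channels (the 16-step ladder
split into consecutive log-frequency quartets — boundaries are otherwise
arbitrary), a sound indicator, and the transformed running velocity
log₂(6v + 1)/10, which is 0 at rest and exactly 1 at 170.5 cm/s. The
velocity covariate is the mean raw velocity over the response window,
transformed after averaging (transform-then-average differs only at the
third decimal for realistic bouts). Responses are max-normalized to [0, 1]
and clipped to [10⁻³, 1 − 10⁻³]; the fit is quasi-binomial (logit link,
dispersion from Pearson χ²) because the outcome is a continuous amplitude,
not a count. z-scores are coefficient/SE. Non-convergence or huge SEs
(separation) flag the fit rather than failing.

## Spatial analysis

Strength maps disc-average (100 μm radius, 10 μm pixels) the
area-under-tuning-curve of soma-excluded neuropil sites; the argmax pixel
(ties to the smallest linear index; flat maps flagged low-confidence) is
the registration center. Distances pool across FOVs weighting by neuron.
Spontaneous frames are those outside every
[onset, onset + duration + 1.5 s) window — the 1.5 s pad covers indicator
decay (about two time constants). Correlations are Pearson on deconvolved
event traces; pairs within 15 μm are excluded to avoid optical crosstalk.

## Synthetic sessions

Each neuron draws a cell type (defaults emulate S2: 9% touch-selective
with high-BTF cells outnumbering low-BTF 4:1, 1.2% sound-selective of
which ~38% touch-inhibited, 0.3% dual), a tactile tuning curve (low-BTF:
log₂-Gaussian, width 0.8 octave; high-BTF: saturating sigmoid, width 0.4
octave; gains lognormal around 5 events/s), an inhibitory r_sound curve
(logistic, floor 0.1, ceiling 0.8, 0.5-crossing at 20 Hz), and for
touch-inhibited sound cells a falling suppression curve midpointed at
32 Hz. The declared `btf_true` is drawn on the stimulus ladder and the
tuning-curve center is then solved numerically so that the noiseless
two-measure BTF estimator returns `btf_true` exactly — BTF-recovery tests
therefore measure noise, not parameterization bias.

The forward model is rate → Poisson events per frame → AR(1) calcium
(γ from τ = 0.7 s) → F = F₀(1 + 0.2·c)·drift + 0.7 × centred neuropil +
shot-like noise (σ scaling with √F). F₀ = 100 a.u.; only ratios matter
downstream. The shared neuropil signal is the population-mean tactile
drive through the same kernel, weighted by a 150 μm Gaussian around the
true FOV center, which makes the neuropil strength map peak recoverable.
Running is alternating exponential rest/run bouts (means 20 s / 5 s,
per-bout speed ~15 cm/s) with smoothed edges, capped at 170.5 cm/s. All
randomness descends from one seed via `SeedSequence.spawn` (separate
streams for running, Poisson events, and noise).

What the generator does *not* emulate: pixel-level movies and segmentation
errors, motion artefacts, spike-to-fluorescence nonlinearity (saturation),
correlated network variability beyond the shared neuropil term, and
habituation/bleaching trends other than slow sinusoidal drift. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative assumptions, not robustness to every failure mode of
real recordings.

## Problem sizes and determinism

Simulation-based checks use deliberately modest problem sizes chosen to
give stable statistics: e.g. 100-run GLM recovery at 200 trials, 1000-run
ANOVA calibrations, 2000 neuron×shuffle null evaluations, 50-neuron
half-max recovery, and 20-draw spatial orderings over four 1500-neuron
FOVs. The spatial-ordering check samples populations and synthetic
strength fields directly (label-level), since trace-level label recovery
is covered by the end-to-end classification test. Every stochastic test
and script is seeded; identical config + seed reproduces outputs
byte-for-byte.

## Known limitations

- The r_sound denominator is unstable where tactile responses barely
  exceed baseline; the significance gate removes most but not all such
  frequencies, and half-max estimates are undefined when the monotone fit
  never crosses 0.5 (narrowly tuned low-BTF neurons).
- The balanced two-way ANOVA trims unbalanced designs rather than fitting
  a type-III model.
- The quasi-binomial GLM treats amplitudes as exchangeable across trials;
  slow state drift within a session is only captured through the velocity
  covariate.
- The responsiveness score constants are calibrated on the synthetic
  population; real datasets with different kinetics or noise should be
  recalibrated with `scripts/calibrate_threshold.py`.
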