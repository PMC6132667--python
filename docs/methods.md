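# Methods

This note documents the models, estimators and design choices behind
`vsdcortex`, in the spirit of a methods appendix: what is simulated, what
is measured, which knobs matter, and what the tests do and do not show.

## Array geometry

The detector is modeled as a 12-ring centered hexagonal lattice
(3·12·13 + 1 = 469 sites) with five designated corner sites switched off,
giving the 464 active channels of the hexagonal photodiode array.  469 is
the nearest centered hexagonal number to 464, and corner truncation is how
commercial hexagonal arrays reach non-hexagonal channel counts; the
deactivated list is a fixed constant so geometry is bit-reproducible.  The
physical pitch is not an independent datum: it is derived by requiring the
464 hexagonal Voronoi cells to tile the imaged 0.416 mm² field, giving
32.2 µm — the per-site spacing convention is therefore a consequence of
the stated area, and is flagged as derived in the geometry module.

Cortical depth maps onto the vertical axis of the hexagon (upper part =
supragranular).  `assign_layer_bands` thresholds the projection of each
site onto a configurable cortical axis; the default supragranular fraction
is 0.4 (layers I–III of six).  Bands are a partition of the active sites
and a function of depth only.

## Synthetic recordings

**VSD forward model.**  Raw intensities are
`I_rest · (1 − r(t, site)) + ε`, `I_rest` = 1500 a.u., ε i.i.d. Gaussian
per diode and sample with SD 0.03 % of `I_rest` (in dI/I units).  The
response `r` is an alpha function `(t/τ)·exp(1 − t/τ)` scaled to the
slice's drawn peak dI/I, with τ = 4 ms in the supragranular band
(transient) and τ = 7 ms in the infragranular band (sustained),
reproducing the transient-then-sustained laminar sequence of healthy A1.
These time constants are a package choice: the kernel peaks τ after its
onset, so the onset delay is (latency − τ), and τ must lie below the
smallest group latency (7.6 ms supragranular, 8.0 ms infragranular) for
the response to begin after the stimulus.  Longer decay constants would
contradict the published peak times.  The drawn peak time is snapped to
the 1.274 ms acquisition grid so that a sampled trial attains its analytic
peak exactly; zero-noise recovery of amplitude is then exact and latency
is exact at sample resolution.

**Between-slice variability.**  Each slice draws per-layer amplitude and
latency from normal distributions whose SD is the published SEM·√n —
presets must reproduce published SEMs at published n.  Amplitude draws are
clipped at zero (a renormalized truncated normal would shift the control
FP group mean by ≈1.5 SEM, clipping by ≈0.5 SEM; the recovery tolerance
absorbs the latter).  Latencies are clipped at τ + one sample so the
kernel cannot start before the stimulus.  Random streams are keyed by
(master seed, preset label, purpose, slice, intensity, distance, trial)
through `SeedSequence` spawn keys: groups are mutually independent
cohorts, cohorts are bit-reproducible, and enlarging a cohort does not
reshuffle earlier slices.

**FP forward model.**  The slow wave is a fixed biphasic shape (negative
Gaussian, depth 1 at 10 ms, σ 4 ms; positive Gaussian 0.9 at 16.5 ms,
σ 3.8 ms; zero before the stimulus), renormalized on the actual sample
grid so its peak-to-peak distance equals the drawn amplitude exactly, and
returning to baseline well before the 25 ms assessment point.  Population
spikes are sharp negative Gaussian transients (σ 0.3 ms, ≈1.2 ms visible
width; depth 0.35·amplitude clipped to [0.7, 1.0] mV), one or two per
stimulation with the preset per-intensity probability, placed 3.5–7.1 ms
post-stimulus and ≥2.2 ms apart.  Traces are sampled at 10 kHz with
0.02 mV additive noise.  Both supra- and infragranular electrodes of a
slice see the same spike event (one network discharge).

**Behavior.**  Freezing percentages are drawn from Beta distributions
moment-matched to the preset (mean, SD), linked across the two tones of an
animal by a Gaussian copula with latent correlation 0.5 (paired
structure).  Means are exact marginally, supports are bounded in [0, 100].
The immobility-series path (10 Hz binary scoring over a configurable
window, default 180 s — the published protocol does not state the scored
window length) exists for interface completeness; presets generate
percentages directly, since only percentages are published.

## Measurement pipeline

dI/I is computed per trial with that trial's own 50 ms resting level
(robust to slow bleaching between trials), then trials are averaged; with
a common baseline this is identical to averaging raw intensities first,
which is available as a configuration and property-tested for equivalence.
The six-diode layer signal takes the in-band site nearest the recording
electrode (default: band centroid) plus its five nearest in-band
neighbors, ties broken by site id.  Amplitude/latency use a 100 ms
post-stimulus search window — generously above every observed peak time
(≤ 12.4 ms) while excluding late drift — with the baseline defined as the
mean over the 50 ms pre-stimulus window; latency is reported at sample
resolution, without sub-sample interpolation, matching the acquisition
limit.  Normalization to a reference dI/I (e.g. the 0.34 % control level)
and per-session-max pseudocolor scaling are display transforms only and
are never applied before measurement.

**Detectable-response rule.**  A latency is only reported when the peak
clears 3× the baseline SD of the layer-averaged signal.  A slice whose
amplitude draw clips to ≈0 has no response, and the arg-max of pure noise
over a 100 ms window is a meaningless "latency" (uniform over the
window); conditioning on detectability mirrors how peak times are read off
visible responses in practice.  Amplitude summaries keep all slices.

**Population-spike detector.**  Published spike scoring was visual; the
package commits to an explicit rule.  The first difference of the trace is
thresholded at k·SD of the baseline first difference (k = 4 by default);
supra-threshold runs closer than 1 ms are merged into one event (the
falling and rising edge of a single spike); an event counts as a spike if
it lasts ≤ 3 ms, opens negative-going, and its negative-going phase lasts
≥ 0.2 ms (two samples — a single noise sample cannot count).  When the
baseline is (near) noise-free the k·SD threshold degenerates, so an
absolute slope floor of 0.1 mV/sample takes over, with a warning.
Validated against generator ground truth: ≥ 98.9 % recall and ≤ 0.5 %
false positives over 1,000 traces per condition at default noise, exact
spike counts at zero noise.  The detector is an operationalization
validated only against the synthetic generator — no claim is made that it
reproduces the original visual scoring on real traces.

## Statistics

One-way, two-way factorial and mixed (split-plot) fixed-effects ANOVA are
implemented directly (sums of squares via nested least-squares model
comparisons with sum-to-zero coding).  Unbalanced factorial designs use
Type II sums of squares — the published designs are mildly unbalanced
(e.g. 16 vs 11 slices) and main effects are reported without
interaction-driven ambiguity.  The mixed ANOVA tests the between factor
against subjects-within-groups and the within factor and interaction
against within×subjects(group); no sphericity correction is applied (none
is reported in the modeled analyses, and with two within levels it is
vacuous), noted in the result metadata.  Newman–Keuls uses a stepdown over
ordered means with studentized-range critical values q(r, df, α) obtained
by numerical CDF inversion (validated against published q tables at a
grid of (k, df) points); non-significant stretches block interior pairs.
Tukey–Kramer and Bonferroni are provided with adjusted p capped at 1.
Unequal group sizes use the harmonic mean of each pair.  Type-I error of
the one-way test is calibration-tested at 0.05 ± 0.01 over 10,000 null
replicates.

## What the tests show — and what they do not

Passing tests demonstrate that the pipeline is an unbiased, exact-at-zero-
noise implementation of the stated estimators, and that at published
sample sizes it recovers the published group parameters from data with
the assumed structure.  The generator draws i.i.d. Gaussian slice effects
and white measurement noise; real recordings have bleaching trends,
correlated optical noise, heartbeat/vibration artifacts, heterogeneous
response shapes within a band, and operator-dependent electrode
placement, none of which are emulated.  Recovery on synthetic cohorts
therefore validates the analysis logic, not its robustness to real-world
artifacts.

Problem sizes used by the test suite: recovery cohorts at the published n
(4–24 slices/animals); at-scale bias checks at 200 slices; detector
performance at 1,000 traces per condition; statistical calibration at
10,000 replicates (one-way) and 2,000 cohorts (behavior contrast).

## Known limitations

* The FP peak-to-peak read-out (max − min over the scoring window) is
  positively biased under noise by ≈2.6 σ_noise (≈0.05 mV at the default
  0.02 mV trace noise).  This bias cannot be pushed below ~2 % of the
  smallest group means without lowering the noise to a level at which the
  derivative threshold of the spike detector (which scales with baseline
  noise) drops below the slow-wave falling-edge slope of plausible
  large-amplitude traces, destroying its specificity.  The package keeps
  the realistic noise level; FP amplitude accuracy is guaranteed by the
  zero-noise identity and by group-mean recovery within 2 SEM at published
  n, and the residual bias is bounded by a dedicated test (≤ 0.06 mV,
  half the narrowest published FP SEM).
* Spike *fraction* recovery on any single cohort is binomial; at n = 24
  its 95 % CI spans ±20 percentage points.  Incidence checks therefore use
  the binomial CI, plus exact recovery at probability 0 and 1.
* Latency recovery at the published n = 4 is dominated by the published
  between-slice SD (SEM·√n up to 2.6 ms); the tolerance adds one sampling
  interval for grid quantization.
* Group values the publications do not report (10 %/100 % intensity means,
  some supragranular entries, late-remyelination behavior) are
  interpolated once in `data/presets.yaml`, flagged `unreported`, and used
  only to make full-factorial reports possible — no validation targets
  them.
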