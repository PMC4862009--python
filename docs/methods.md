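# Methods

This note documents the models, defaults and design choices behind
`cinevoc`, in the order data flows through the pipeline.

## Room box model (`cinevoc.simulate`)

The screening room is one well-mixed compartment.  For each species the
balance `dC/dt = λ(C_bg − C) + N(t)E(t)/V` is integrated exactly over
each 30 s grid step with the forcing held constant within the step
(`C(t+Δ) = C_eq + (C−C_eq)e^{−λΔ}`, `C_eq = C_bg + NE/(λV)`).  The
exact per-step update was chosen over a generic ODE solver because it
has a closed form to test against (steady state, e-fold decay time
1/λ) and is unconditionally stable.

Assumptions: instantaneous mixing (no spatial gradients, no multi-zone
exchange), constant air-exchange rate, emissions proportional to
occupancy.  None of these hold exactly in a real auditorium; they are
the minimal physics producing the observed shark-fin dynamics.

Defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| air exchanges λ | 6 h⁻¹ | typical full-flush ventilation of a commercial auditorium |
| room volume V | 800 m³ | plausible for a 230-seat room; not independently measurable here |
| capacity | 230 persons | room size the study design assumes |
| CO₂ background | 400 ppm | ambient outdoor level |
| breathing rate | 10 L min⁻¹ person⁻¹ | seated adult minute ventilation |
| exhaled CO₂ | 4 % (40 000 ppm) | physiological constant |
| grid step | 30 s | analysis resolution of the measurement chain |

With these values a full house equilibrates near 1550 ppm CO₂ and a
186-person audience near 1330 ppm — inside the 1000–2400 ppm range such
rooms reach in practice.  V and the breathing rate are the two knobs
that cannot be pinned down independently; they were fixed once from
that envelope and typical physiology, not fitted to anything
downstream.

Per-person VOC baselines (ppb·m³·s⁻¹·person⁻¹) are set so audience
plateaus sit at realistic few-ppb levels (e.g. acetone ≈ 8 ppb at a
186-person house).  Scene labels act as first-order pulses: while a
pulse is active the per-person emission of the target species is
multiplied by `1 + gain·intensity`, starting `lag` seconds after event
onset and lasting `duration` seconds.  An optional exit spike (default:
isoprene, gain 2, 5 min) models the burst of limb movement at the
exodus.  Rectangular pulses are the simplest mechanism that produces
transient concentration peaks through the box model's low-pass
response; real emission dynamics are certainly smoother.

## Scene scripts

Each label is an independent stationary two-state Markov chain on the
30 s slot grid: mean on-run `mean_event_length` (default 60 s, min one
slot) and off→on hazard chosen so the stationary covered fraction
equals the label's registered frequency (e.g. conversation 0.680,
suspense 0.283, comedy 0.054, injury 0.008).  Generating on the grid
makes the covered-slot count an unbiased estimator of the frequency;
continuous-time events would over-count partially covered slots.  The
chain has no within-film structure (no acts, no climax pacing).

## Instrument model and processing (`cinevoc.ptrms`)

Synthesis inverts the normalization: per mass,
`raw = C·sens · (500·m21 + 250·m39)/10⁶ · (P/P_ref)(T_ref/T)`, with
slow sinusoidal drift on primary ions (±3 %), temperature (±0.5 K) and
pressure (±0.01 hPa around a 2.20 hPa operating point), plus Poisson
counting noise at a 30 s dwell.  The inverse factor is computed before
multiplying so that the no-noise, reference-condition round trip is the
bit-exact identity — the processing chain's correctness test.

Processing applies the standard primary-ion normalization (reference
298.15 K and 2 mbar), isotopic scale-up factors 500 (m21) and 250
(m39) reflecting ¹⁸O natural abundance — both configurable, since
instruments differ — calibration division by per-mass sensitivities
(default 20 ncps/ppb; 15 % relative uncertainty carried as metadata),
3σ detection-limit flags (flagged values retained, never zeroed), and
mean-aggregation onto the 30 s grid.  Temperature enters the numerator
(T/T_ref), the usual drift-tube number-density correction; a site using
the inverse convention can flip it via the arguments.  Empty slots stay
missing and propagate to instance dropping — never interpolated.

## Annotators and consensus (`cinevoc.annotation`)

Annotator noise is three independent mechanisms: Gaussian jitter of
event boundaries (default SD 15 s), per-slot misses of covered slots
(default 5 %) and false marks of uncovered slots (default 1 %).  No
systematic per-annotator bias or fatigue is modelled.  Because a slot
counts as covered when any (jittered) event overlaps it, boundary
jitter inflates apparent coverage of densely eventful labels; consensus
largely, but not completely, removes this.

Consensus requires at least two thirds of all annotators:
`ceil(f·n)` with a numerical guard so 10 annotators need 7 and 9 need 6
(a naive `ceil` on binary floats gives 7 for n = 9).  The 1–5 affect
scales (happy–sad, excited–calm) are averaged, not thresholded; for use
as classification targets they can be binarized at a configurable cut
(default: top two scale points).  Parent/child label roll-up
(suspense ⊃ chase/hidden-threat/hiding, etc.) is OR-semantics and off
by default, since parents and children are normally reported as
separate labels; the hierarchy is configuration, not hard-coded,
because the label taxonomy is genuinely ambiguous.

## Windowed instances (`cinevoc.windows`)

Channels are z-scored per screening (population SD; zero-variance
channels dropped with a warning).  Per-screening scope removes
audience-size offsets that would otherwise dominate any pooled model; a
global-scope alternative would leave occupancy as a confound across
screenings.  Backward instances use the strictly future window
(offsets +1..+10 × 30 s; the anchor slot can be included by flag),
forward instances the strictly past window (−10..−1) over all channels
*and* all labels, with the target's own past included (autoregression).
Instances never span screening boundaries, and any instance containing
a missing value is dropped.

## Evaluation and significance (`cinevoc.linkage`)

The protocol: 15 repeats; in each, a uniformly random two-thirds of
instances trains a 100-tree random forest (class-probability scores)
and the held-out third is scored by AUC (rank/Mann–Whitney form, ties
one half — property-tested against exhaustive pair counting).
Instance-level splitting is the default; screening-level splitting is
available for leakage-free evaluation across films.  Splits whose train
or test part is single-class are redrawn (logged), which matters for
rare labels (frequencies down to 0.008).

Leave-one-mass-out reuses each repeat's exact split and model seed with
one channel's ten lag columns removed, so per-repeat (baseline −
reduced) AUC differences isolate the removed channel.  Significance
uses the corrected resampled paired t-test,
`t = d̄/√(σ̂²_d(1/k + n_test/n_train))` with k−1 df, two-sided (the
direction of an ablation effect is not presumed).  Degenerate cases:
zero variance with zero mean → p = 1; zero variance with nonzero mean
→ p = 0, flagged.  The reported per-mass AUC is the mean reduced-model
AUC; "none" rows carry the all-mass baseline.  The final report keeps
rows with AUC > 0.5 and p < 0.05, sorted by p within label.  No
multiple-testing correction is applied: the table is a screening device
and corrected p-values would suppress exactly the weak candidate links
it exists to surface.

The coherence check trains the backward classifier on measured windows
and scores held-out anchors twice — measured vs forward-model-predicted
windows.  The AUC difference is 0 for a perfect forward model and the
predicted-window AUC falls to 0.5 when forward predictions are replaced
by noise; the metric is monotone in forward fidelity.

## Calibration studies and problem sizes (`cinevoc.studies`)

Three constructed truths validate the statistics: (i) *null* — the
label is an independent Bernoulli(0.1) process over ~1520 instances ×
12 channels (four screenings, 3 h films); mean held-out AUC must
calibrate to 0.5 ± 0.05 across generator seeds; (ii) *separable* — one
channel alternates between well-separated plateaus and the label is its
future-window sign, with boundary-straddling anchors dropped so every
retained instance has ≥ 2 within-class SDs of margin; AUC must be 1.0
in every repeat; (iii) *injected link* — exactly one mass (isoprene)
responds to one label (suspense, gain 3×, lag 1 min) over two
screenings (~520 instances, 7 channels); leave-one-mass-out must flag
it and not the five pure-baseline masses.  These sizes are the
package's desk-scale study conditions; they were chosen so each study
is a few minutes of single-core compute while keeping the Monte-Carlo
error of the checked rates well below the margins being asserted.

## Determinism

One master seed per entry point; all child seeds derive from it via
`numpy.random.SeedSequence.spawn`, including per-repeat split and
model seeds.  Entire runs (tables byte-for-byte) are reproducible under
a fixed seed.  Figures are excluded from the byte-level guarantee
(PNG encoding is not contractually stable across library versions).

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes: occupancy-driven baselines, label-locked transient pulses
filtered by room ventilation, multiplicative instrument drift, Poisson
counting noise, independent annotator errors.  It does not emulate
spatially inhomogeneous mixing, humidity-dependent sensitivity,
spectral peak overlap between masses, correlated annotator biases, or
audience heterogeneity (age, activity, group behaviour).  Passing the
suite therefore demonstrates that the pipeline recovers known structure
under its own model assumptions — it cannot certify those assumptions
for any particular auditorium or instrument.

## Known limitations

The ventilation time constant sets a hard ceiling on event attribution:
a pulse's chemical trace persists ~1/λ (10 min) after the scene ends,
so negatives within that horizon of an event carry residual signal in
their future window.  For a label covering ~28 % of slots with ~1 min
events, this caps the attainable backward AUC near 0.75 even at 3×
emission gain — sharper attribution requires rarer labels, stronger
gains or faster air exchange, not more data.  Relatedly, annotator
boundary jitter acts as an inadvertent event-length filter at the
consensus stage (short events fail the 7-of-10 threshold), which can
*raise* measured AUC by discarding chemically weak positives.
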