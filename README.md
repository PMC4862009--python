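# cinevoc

Do the volatile chemicals a cinema audience exhales carry a reproducible
imprint of what is happening on screen?  `cinevoc` is a tested pipeline
for that question: it links time-resolved, breath-borne trace-gas
concentrations measured in the exhaust air of a ventilated screening
room (PTR-ToF-MS mass channels plus CO₂, on a 30 s grid) to time-coded,
multi-annotator scene labels (suspense, comedy, injury, …), and ships a
physically motivated synthetic-data generator so the whole statistical
chain is verifiable end to end without access to measured data.

The package is aimed at researchers in breath volatilomics / indoor-air
chemistry who need a defensible screening statistic for "label ↔ mass"
association in crowd-scale time series.

## The model and the statistic

**Room chemistry.** The screening room is a single well-mixed
compartment of volume *V* flushed λ times per hour; each of the *N(t)*
occupants emits species *s* at rate *E_s(t)* (scene labels transiently
multiply the baseline emission).  Concentrations obey

    dC/dt = λ (C_bg − C) + N(t) E(t) / V,

solved exactly per 30 s step under piecewise-constant forcing:
`C(t+Δ) = C_eq + (C(t) − C_eq) e^{−λΔ}` with
`C_eq = C_bg + N E/(λV)`.  This yields the characteristic "shark-fin"
CO₂ profile: rise toward equilibrium during the film, abrupt fall at
the exodus.

**Instrument.** Raw ion count rates are normalized to the primary-ion
signal (the ¹⁸O isotopologues m21/m39 of H₃O⁺ and its first water
cluster) and to reference drift conditions (298.15 K, 2 mbar):

    ncps = R · 10⁶ / (500·[m21] + 250·[m39]) · (P_ref/P) · (T/T_ref),

then converted to mixing ratios by per-mass calibration sensitivities
(15 % relative uncertainty), with 3σ detection limits flagged.

**Linkage statistic.** For each scene label, a random forest predicts
the label at time *t* from all standardized channels in the next
5-minute window ("backward prediction"); training uses a random two
thirds of the instances and scoring the held-out third, repeated 15
times (held-out AUC).  Each mass is then ablated on identical splits
and the paired per-repeat AUC differences are tested with the corrected
resampled paired t-test,

    t = d̄ / √( σ̂²_d (1/k + n_test/n_train) ),  df = k − 1,

whose variance correction accounts for overlapping training sets.
Forward prediction (each channel regressed on the past 5 minutes of
chemistry + labels, held-out Pearson *r*) and a forward→backward
coherence check complete the analysis.  Rows with AUC > 0.5 and
p < 0.05 form the final linkage table; no multiple-testing correction
is applied (the rows are screening indications, not confirmatory
tests).

## Worked example

The numbered drivers under `analysis/` run the full synthetic study —
four screenings of one film (audiences 87, 96, 104, 186 in a 230-seat
room flushed 6×/hour), ten noisy annotators, four label tracks:

```
cd analysis
python 01_simulate.py && python 02_process.py && python 03_consensus.py
python 04_features.py && python 05_linkage.py
```

Output of `01_simulate.py` (full houses approach the observed
1000–2400 ppm CO₂ range; background is 400 ppm):

```
  scr00: audience   87, peak CO2     835 ppm, 127 scene events
  scr03: audience  186, peak CO2    1330 ppm, 119 scene events
```

and of `05_linkage.py` — the generator drives isoprene (m69.070) from
"suspense" scenes and acetone (m59.049) from "comedy", and the linkage
table recovers exactly that structure:

```
  backward 'suspense': baseline AUC 0.754; strongest mass m69.070 (AUC without it 0.672, p 0.0084)
  backward 'comedy':   baseline AUC 0.885; strongest mass m59.049 (AUC without it 0.609, p 0.0000)
  forward 'co2':      mean held-out Pearson r 1.000
  forward 'm69.070':  mean held-out Pearson r 0.993
```

Reading: predicting *suspense* from the following five minutes of
chemistry achieves AUC 0.75 (0.5 = chance); removing isoprene's lag
columns drops it to 0.67, and the corrected paired t-test puts that
drop at p = 0.008 — isoprene is the load-bearing channel.  All other
masses are non-significant, as constructed.  CO₂ is almost perfectly
forward-predictable because occupancy plus its own recent past
determine it through the box model.

`cinevoc.pipeline.run_pipeline(RunConfig(...))` performs the same study
in one call and writes tables, figures and a manifest;
`analysis/06_calibration.py` re-checks the statistics on constructed
truths (null labels → AUC ≈ 0.5, separable labels → AUC = 1.0,
injected links recovered).

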