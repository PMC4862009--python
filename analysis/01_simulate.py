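#!/usr/bin/env python
"""Simulate four screenings of one film and write the raw records.

Generates, per screening: a scene script (slot-coverage frequencies from
the registered label vocabulary), a trapezoidal occupancy profile, exact
box-model concentrations for CO2 and six VOC masses, a raw PTR-ToF-MS
record with primary-ion drift and Poisson counting noise, and ten noisy
annotator label tracks.  Writes raw/truth/annotation CSVs under
results/demo/screenings/.
"""

import numpy as np

import common
from cinevoc import simulate

common.ensure_dirs()
master = np.random.SeedSequence(common.SEED)
seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
         for s in master.spawn(len(common.AUDIENCES))]

from cinevoc.vocabulary import LABEL_FREQUENCIES

freqs = {lab: LABEL_FREQUENCIES[lab] for lab in common.LABELS}

print(f"simulating {len(common.AUDIENCES)} screenings of "
      f"'{common.FILM_NAME}' ({common.FILM_DURATION_S / 3600:.1f} h)")
for sid, audience, seed in zip(common.SCREENING_IDS, common.AUDIENCES,
                               seeds):
    sim = simulate.simulate_screening(
        audience_size=audience, film_duration=common.FILM_DURATION_S,
        label_frequencies=freqs, n_annotators=common.N_ANNOTATORS,
        annotator_noise=common.ANNOTATOR_NOISE, rng_seed=seed)
    sim["raw"].to_csv(common.SCREENINGS / f"{sid}_raw.csv",
                      index_label="time_s", float_format="%.10g")
    truth = sim["concentrations"].assign(
        occupancy=sim["occupancy"].occupancy)
    truth.to_csv(common.SCREENINGS / f"{sid}_truth.csv",
                 index_label="time_s", float_format="%.10g")
    rows = []
    for aid, frame in sim["annotations"].tracks.items():
        long = frame.stack().rename("value").reset_index()
        long.columns = ["time_s", "label_name", "value"]
        long.insert(1, "annotator_id", aid)
        rows.append(long)
    import pandas as pd
    pd.concat(rows).to_csv(common.SCREENINGS / f"{sid}_annotations.csv",
                           index=False)
    co2 = sim["concentrations"]["co2"]
    print(f"  {sid}: audience {audience:4d}, peak CO2 "
          f"{co2.max():7.0f} ppm, {len(sim['script'].events)} scene events")
print(f"wrote raw/truth/annotation CSVs to {common.SCREENINGS}")
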