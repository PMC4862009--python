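#!/usr/bin/env python
"""Standardize screenings and build the windowed supervised instances.

Each screening's channels are z-scored within the screening (removing
audience-size offsets), then backward instances (scene label at t vs
all channels over the next 5 minutes) and forward instances (channel at
t vs all channels and labels over the past 5 minutes) are assembled.
Writes the feature schema plus instance counts; the full matrices are
rebuilt in seconds by the linkage driver.
"""

import json

import pandas as pd

import common
from cinevoc import windows

common.ensure_dirs()
std_frames, cons_frames = [], []
for sid in common.SCREENING_IDS:
    data = pd.read_csv(common.PROCESSED / f"{sid}_processed.csv",
                       index_col="time_s")
    cons = pd.read_csv(common.CONSENSUS / f"{sid}_consensus.csv",
                       index_col="time_s")
    channels = [c for c in data.columns if c != "occupancy"]
    std, state = windows.standardize(data[channels])
    std.attrs["screening_id"] = sid
    film_start = 600.0  # arrival ramp precedes the film clock
    cons.index = cons.index + film_start
    cons = cons.reindex(std.index, fill_value=0)
    std_frames.append(std)
    cons_frames.append(cons)

schema = {}
for label in common.ANALYSIS_LABELS:
    inst = windows.build_backward_instances(
        std_frames, [c[label] for c in cons_frames],
        horizon=common.WINDOW_S)
    schema[f"backward:{label}"] = {
        "n_instances": inst.n_instances,
        "n_positive": int(inst.y.sum()),
        "feature_names": [f"{ch}@{off:+d}"
                          for ch, off in inst.feature_names]}
    print(f"  backward '{label}': {inst.n_instances} instances, "
          f"{int(inst.y.sum())} positive, "
          f"{len(inst.feature_names)} features")
for mass in common.FORWARD_MASSES:
    inst = windows.build_forward_instances(
        std_frames, cons_frames, target_mass=mass,
        history=common.WINDOW_S)
    schema[f"forward:{mass}"] = {
        "n_instances": inst.n_instances,
        "feature_names": [f"{ch}@{off:+d}"
                          for ch, off in inst.feature_names]}
    print(f"  forward '{mass}': {inst.n_instances} instances, "
          f"{len(inst.feature_names)} features")
(common.TABLES / "instance_schema.json").write_text(
    json.dumps(schema, indent=1))
print(f"wrote feature schema to {common.TABLES / 'instance_schema.json'}")
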