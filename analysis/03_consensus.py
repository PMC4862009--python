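#!/usr/bin/env python
"""Build consensus scene-label tracks from the annotator CSVs.

A slot carries a label only when at least two thirds of the ten
annotators agree (ceil(2/3 * 10) = 7 of 10).  Writes per-screening
consensus CSVs on the analysis grid.
"""

import pandas as pd

import common
from cinevoc.annotation import AnnotationSet, consensus_frame

common.ensure_dirs()
for sid in common.SCREENING_IDS:
    long = pd.read_csv(common.SCREENINGS / f"{sid}_annotations.csv")
    tracks = {
        aid: grp.pivot(index="time_s", columns="label_name",
                       values="value")
        for aid, grp in long.groupby("annotator_id")}
    ann = AnnotationSet(tracks=tracks)
    cons = consensus_frame(ann)
    cons.to_csv(common.CONSENSUS / f"{sid}_consensus.csv",
                index_label="time_s")
    cover = {lab: f"{cons[lab].mean():.3f}" for lab in cons.columns}
    print(f"  {sid}: consensus slot coverage {cover}")
print(f"wrote consensus tracks to {common.CONSENSUS}")
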