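"""Shared paths and study parameters for the numbered analysis drivers.

The demo study mirrors one film screened four times to audiences of 87,
96, 104 and 186 people in a 230-seat room flushed six times per hour,
with ten annotators labelling four scene-label tracks.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "demo"
SCREENINGS = RESULTS / "screenings"
PROCESSED = RESULTS / "processed"
CONSENSUS = RESULTS / "consensus"
TABLES = RESULTS / "tables"
FIGURES = RESULTS / "figures"

SEED = 1
AUDIENCES = (87, 96, 104, 186)
FILM_DURATION_S = 7200.0
FILM_NAME = "Demo Feature"
LABELS = ("conversation", "suspense", "comedy", "injury")
ANALYSIS_LABELS = ("suspense", "comedy")
FORWARD_MASSES = ("co2", "m69.070")
N_ANNOTATORS = 10
ANNOTATOR_NOISE = {"miss_rate": 0.05, "false_rate": 0.01, "jitter": 15.0}
WINDOW_S = 300.0
N_REPEATS = 15
N_TREES = 100

SCREENING_IDS = tuple(f"scr{i:02d}" for i in range(len(AUDIENCES)))


def ensure_dirs() -> None:
    for d in (SCREENINGS, PROCESSED, CONSENSUS, TABLES, FIGURES):
        d.mkdir(parents=True, exist_ok=True)
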