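"""Canned synthetic study designs for calibration and power analysis.

The statistical claims of the pipeline are checked against constructed
truths: a *null* study in which the scene label is independent of every
chemical channel (held-out AUC must calibrate to 0.5), a *separable*
study in which the label is a noiseless threshold of one channel's
future window (AUC must reach 1.0), and an *injected-link* study in
which exactly one mass responds to a scene label through the room's box
model (leave-one-mass-out must flag that mass and no other).  These
builders are used by the test-suite, the acceptance script and the
analysis drivers alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import linkage as link_mod
from . import ptrms, simulate, windows
from .windows import WindowedInstances

__all__ = [
    "EXTENDED_MASSES",
    "simulate_processed_screenings",
    "null_label_instances",
    "threshold_label_instances",
    "injected_link_study",
]

#: twelve analysis channels: eleven VOC masses plus CO2
EXTENDED_MASSES: dict[str, str] = {
    **simulate.DEFAULT_MASSES,
    "m31.018": "formaldehyde",
    "m42.034": "acetonitrile",
    "m63.027": "dimethyl sulfide",
    "m79.054": "benzene",
    "m93.070": "toluene",
}


def _extended_models(label_responses=None, exit_spike="default"):
    base = simulate.EmissionModel().baseline_per_person
    baseline = dict(base)
    extra = {"m31.018": 0.010, "m42.034": 0.008, "m63.027": 0.002,
             "m79.054": 0.003, "m93.070": 0.005}
    baseline.update(extra)
    spike = (simulate.EmissionModel().exit_spike if exit_spike == "default"
             else exit_spike)
    em = simulate.EmissionModel(
        baseline_per_person=baseline,
        label_responses=label_responses if label_responses is not None
        else simulate.EmissionModel().label_responses,
        exit_spike=spike)
    inst = simulate.InstrumentModel(
        sensitivity={m: 20.0 for m in EXTENDED_MASSES})
    scen = simulate.RoomScenario(
        background={simulate.CO2: 400.0,
                    **{m: 0.2 for m in EXTENDED_MASSES}})
    return scen, em, inst


def simulate_processed_screenings(
        seed: int,
        audiences=(87, 96, 104, 186),
        film_duration: float = 7200.0,
        label_frequencies: dict[str, float] | None = None,
        emissions: simulate.EmissionModel | None = None,
        instrument: simulate.InstrumentModel | None = None,
        scenario: simulate.RoomScenario | None = None,
        n_annotators: int = 10,
        annotator_noise: dict | None = None,
        ) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Simulate, process and standardize a set of screenings.

    Returns per-screening standardized channel frames (mass channels +
    CO2, z-scored within each screening) and aligned consensus label
    frames on the same grid.
    """
    emissions = emissions or simulate.default_emissions()
    instrument = instrument or simulate.default_instrument()
    calibration = ptrms.CalibrationTable.uniform(instrument.sensitivity,
                                                 sensitivity=20.0)
    seeds = np.random.SeedSequence(seed).spawn(len(audiences))
    std_frames, cons_frames = [], []
    for i, audience in enumerate(audiences):
        scr_seed = int(seeds[i].generate_state(1)[0] % (2**31 - 1))
        sim = simulate.simulate_screening(
            audience_size=audience, film_duration=film_duration,
            scenario=scenario, emissions=emissions, instrument=instrument,
            label_frequencies=label_frequencies,
            n_annotators=n_annotators, annotator_noise=annotator_noise,
            rng_seed=scr_seed)
        scr = ptrms.process_screening(sim["raw"], calibration,
                                      screening_id=f"scr{i:02d}")
        std, _ = windows.standardize(scr)
        std.attrs["screening_id"] = scr.screening_id
        cons = ann_mod.consensus_frame(sim["annotations"])
        cons.index = cons.index + sim["film_start"]
        cons = cons.reindex(std.index, fill_value=0)
        std_frames.append(std)
        cons_frames.append(cons)
    return std_frames, cons_frames


def null_label_instances(seed: int,
                         audiences=(87, 96, 104, 186),
                         film_duration: float = 10800.0,
                         label_frequency: float = 0.1,
                         ) -> WindowedInstances:
    """Backward instances whose binary label is an independent Bernoulli
    process: the ground truth for AUC null calibration (12 channels,
    ~1500 instances at the default sizes)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    scen, em, inst = _extended_models(label_responses={}, exit_spike=None)
    std_frames, _ = simulate_processed_screenings(
        int(ss[0].generate_state(1)[0] % (2**31 - 1)),
        audiences=audiences, film_duration=film_duration,
        emissions=em, instrument=inst, scenario=scen,
        label_frequencies={"conversation": 0.68},
        n_annotators=1,
        annotator_noise={"miss_rate": 0, "false_rate": 0, "jitter": 0})
    rng = np.random.default_rng(ss[1])
    labels = [pd.Series((rng.random(len(f)) < label_frequency).astype(int),
                        index=f.index, name="null_label")
              for f in std_frames]
    return windows.build_backward_instances(std_frames, labels,
                                            horizon=300.0)


def threshold_label_instances(seed: int,
                              n_slots: int = 1100,
                              n_noise_channels: int = 5,
                              level: float = 1.0,
                              noise_sd: float = 0.05,
                              run_slots: int = 25,
                              ) -> WindowedInstances:
    """Backward instances with a perfectly separable label.

    One designated channel alternates between plateaus at +/-``level``
    (runs of ``run_slots`` slots, small within-class noise); the label
    is 1 iff the channel's future-window mean exceeds zero.  Window
    means of boundary-straddling anchors fall near the threshold and
    those instances are dropped, leaving a margin of at least two
    within-class standard deviations on every retained instance.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_runs = n_slots // run_slots + 1
    states = rng.random(n_runs) < 0.5
    sig = np.repeat(np.where(states, level, -level), run_slots)[:n_slots]
    channels = {"m_target": sig + noise_sd * rng.standard_normal(n_slots)}
    for j in range(n_noise_channels):
        channels[f"m_noise{j}"] = rng.standard_normal(n_slots)
    idx = pd.Index(np.arange(n_slots) * 30.0, name="time_s")
    frame = pd.DataFrame(channels, index=idx)
    target = frame["m_target"].to_numpy()
    h = 10
    window_mean = np.array([target[i + 1: i + 1 + h].mean()
                            for i in range(n_slots - h)])
    margin = 2 * noise_sd
    keep = np.abs(window_mean) > margin
    y = pd.Series(0, index=idx, dtype=int)
    y.iloc[: n_slots - h] = (window_mean > 0).astype(int)
    inst = windows.build_backward_instances(frame, y, horizon=300.0)
    rows = np.where(keep)[0]
    return WindowedInstances(
        direction="backward", target="threshold_label",
        X=inst.X[rows], y=inst.y[rows],
        feature_names=inst.feature_names,
        anchors=[inst.anchors[i] for i in rows])


def injected_link_study(seed: int,
                        gain: float = 3.0,
                        lag: float = 60.0,
                        pulse_duration: float = 120.0,
                        linked_mass: str = "m69.070",
                        label: str = "suspense",
                        audiences=(104, 186),
                        film_duration: float = 7200.0,
                        plan: link_mod.EvaluationPlan | None = None,
                        ) -> link_mod.LinkageResult:
    """One seed of the leave-one-mass-out power/size experiment.

    Exactly one mass responds to the scene label (through the room's box
    model, with the stated gain and lag); all other masses carry only
    occupancy-driven baseline emissions and instrument noise.  Returns
    the linkage result of ablating every *mass* channel (CO2 retained
    as a feature but not ablated).
    """
    em = simulate.EmissionModel(
        label_responses={label: (simulate.LabelResponse(
            linked_mass, gain=gain, lag=lag, duration=pulse_duration),)},
        exit_spike=None)
    std_frames, cons_frames = simulate_processed_screenings(
        seed, audiences=audiences, film_duration=film_duration,
        emissions=em,
        label_frequencies={"conversation": 0.68, label:
                           simulate.LABEL_FREQUENCIES[label]},
        n_annotators=10,
        annotator_noise={"miss_rate": 0.05, "false_rate": 0.01,
                         "jitter": 15.0})
    inst = windows.build_backward_instances(
        std_frames, [c[label] for c in cons_frames], horizon=300.0)
    plan = plan or link_mod.EvaluationPlan(seed=seed)
    masses = [ch for ch in inst.channels if ch != "co2"]
    return link_mod.leave_one_mass_out(inst, plan, channels=masses)
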