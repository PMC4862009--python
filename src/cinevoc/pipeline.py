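"""End-to-end orchestration of the synthetic cinema study.

One call (or one driver script) takes a run configuration to a complete
set of artifacts: simulated screenings, processed instrument records,
consensus annotation, windowed instances, backward/forward evaluation,
leave-one-mass-out linkage tables, coherence check, figures and a
manifest.  Every stage is a pure function of (inputs, config, seed), so
two runs with the same configuration produce identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestRegressor

from . import annotation as ann_mod
from . import linkage as link_mod
from . import ptrms, simulate, windows
from .vocabulary import LABEL_FREQUENCIES

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

#: audiences of the four demo screenings of one film
DEMO_AUDIENCES = (87, 96, 104, 186)


@dataclass
class RunConfig:
    """Configuration of one full synthetic run."""

    outdir: str = "results/run"
    seed: int = 0
    film_name: str = "Demo Feature"
    audiences: tuple[int, ...] = DEMO_AUDIENCES
    film_duration_s: float = 7200.0
    start_time_iso: str = "2013-12-26T20:00:00"
    label_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            lab: LABEL_FREQUENCIES[lab]
            for lab in ("conversation", "suspense", "comedy", "injury")
        })
    analysis_labels: tuple[str, ...] = ("suspense", "comedy")
    forward_masses: tuple[str, ...] = ("co2", "m69.070")
    n_annotators: int = 10
    annotator_noise: dict = field(
        default_factory=lambda: {"miss_rate": 0.05, "false_rate": 0.01,
                                 "jitter": 15.0})
    window_s: float = 300.0
    n_repeats: int = 15
    train_fraction: float = 2.0 / 3.0
    n_trees: int = 100
    split_unit: str = "instance"
    auc_min: float = 0.5
    p_max: float = 0.05
    agreement_fraction: float = 2.0 / 3.0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.n_repeats < 2:
            raise ValueError(
                "n_repeats must be >= 2 (the paired t-test needs at "
                "least two repeats)")
        unknown = set(self.analysis_labels) - set(self.label_frequencies)
        if unknown:
            raise ValueError(f"analysis labels not simulated: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"cannot parse config {path}: {exc}") from exc
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys in {path}: {sorted(bad)}")
        for key in ("audiences", "analysis_labels", "forward_masses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def plan(self, seed: int) -> link_mod.EvaluationPlan:
        return link_mod.EvaluationPlan(
            n_repeats=self.n_repeats, train_fraction=self.train_fraction,
            n_trees=self.n_trees, seed=seed, split_unit=self.split_unit)


def _iso_index(frame: pd.DataFrame, start_iso: str) -> pd.Series:
    base = pd.Timestamp(start_iso)
    return pd.Series(
        [(base + pd.Timedelta(seconds=float(t))).isoformat()
         for t in frame.index], index=frame.index, name="time_iso")


def _write_csv(frame: pd.DataFrame, path: Path, start_iso: str) -> None:
    out = frame.copy()
    out.insert(0, "time_iso", _iso_index(frame, start_iso))
    out.to_csv(path, index_label="time_s", float_format="%.10g")


def _annotations_long(ann: ann_mod.AnnotationSet,
                      start_iso: str) -> pd.DataFrame:
    rows = []
    base = pd.Timestamp(start_iso)
    for aid, frame in ann.tracks.items():
        for label in frame.columns:
            for t, v in frame[label].items():
                rows.append({
                    "time_iso": (base + pd.Timedelta(seconds=float(t))
                                 ).isoformat(),
                    "time_s": float(t), "annotator_id": aid,
                    "label_name": label, "value": int(v)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Run the full synthetic study and write all artifacts.

    Returns a dict with the output directory, the manifest, and the key
    in-memory results (linkage table, forward results, coherence).
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    outdir = Path(config.outdir)
    for sub in ("screenings", "processed", "consensus", "tables", "figures"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def record(path: Path) -> None:
        written.append(str(path.relative_to(outdir)))

    master = np.random.SeedSequence(config.seed)
    scr_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in master.spawn(len(config.audiences) + 1)]
    eval_seed = scr_seeds[-1]

    # stage 1+2: simulate screenings and process the raw records --------
    instrument = simulate.default_instrument()
    calibration = ptrms.CalibrationTable.uniform(
        instrument.sensitivity, sensitivity=20.0, detection_limit=0.05)
    screenings: list[ptrms.ScreeningTimeSeries] = []
    consensus_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for i, audience in enumerate(config.audiences):
        sid = f"scr{i:02d}"
        sim = simulate.simulate_screening(
            audience_size=audience,
            film_duration=config.film_duration_s,
            label_frequencies=config.label_frequencies,
            n_annotators=config.n_annotators,
            annotator_noise=config.annotator_noise,
            instrument=instrument,
            rng_seed=scr_seeds[i])
        raw, conc = sim["raw"], sim["concentrations"]
        occ = sim["occupancy"].as_series()
        _write_csv(raw, outdir / "screenings" / f"{sid}_raw.csv",
                   config.start_time_iso)
        record(outdir / "screenings" / f"{sid}_raw.csv")
        _write_csv(conc.assign(occupancy=occ.values),
                   outdir / "screenings" / f"{sid}_truth.csv",
                   config.start_time_iso)
        record(outdir / "screenings" / f"{sid}_truth.csv")
        long_ann = _annotations_long(sim["annotations"],
                                     config.start_time_iso)
        long_ann.to_csv(outdir / "screenings" / f"{sid}_annotations.csv",
                        index=False)
        record(outdir / "screenings" / f"{sid}_annotations.csv")

        scr = ptrms.process_screening(
            raw, calibration, screening_id=sid,
            film_name=config.film_name, occupancy=occ,
            grid_step=30.0)
        screenings.append(scr)
        _write_csv(scr.data, outdir / "processed" / f"{sid}_processed.csv",
                   config.start_time_iso)
        record(outdir / "processed" / f"{sid}_processed.csv")
        sidecar = outdir / "processed" / f"{sid}_calibration.json"
        sidecar.write_text(json.dumps(scr.metadata, indent=1, sort_keys=True))
        record(sidecar)

        # stage 3: consensus annotation (film clock -> room clock) ------
        cons = ann_mod.consensus_frame(sim["annotations"],
                                       config.agreement_fraction)
        cons.index = cons.index + sim["film_start"]
        cons = cons.reindex(scr.data.index, fill_value=0)
        consensus_frames.append(cons)
        _write_csv(cons, outdir / "consensus" / f"{sid}_consensus.csv",
                   config.start_time_iso)
        record(outdir / "consensus" / f"{sid}_consensus.csv")
        truth_frames.append(conc)

    # stage 4: standardize and window -----------------------------------
    std_frames = []
    for scr in screenings:
        std, _state = windows.standardize(scr)
        std.attrs["screening_id"] = scr.screening_id
        std_frames.append(std)

    plan = config.plan(eval_seed)

    # stage 5a: backward prediction + leave-one-mass-out per label ------
    linkage_results = []
    repeat_rows = []
    for label in config.analysis_labels:
        label_tracks = [cons[label] for cons in consensus_frames]
        inst = windows.build_backward_instances(
            std_frames, label_tracks, horizon=config.window_s)
        if len(np.unique(inst.y)) < 2:
            log.warning("label %s has a single class; skipped", label)
            continue
        res = link_mod.leave_one_mass_out(inst, plan)
        linkage_results.append(res)
        for rep, a in enumerate(res.per_repeat_baseline):
            repeat_rows.append({"kind": "backward_auc", "target": label,
                                "repeat": rep, "value": a})

    # stage 5b: forward prediction per chemical channel -----------------
    forward_results = []
    for mass in config.forward_masses:
        inst_f = windows.build_forward_instances(
            std_frames, consensus_frames, target_mass=mass,
            history=config.window_s)
        rs = link_mod.repeated_eval_forward(inst_f, plan)
        forward_results.append(link_mod.ForwardResult(mass, rs))
        for rep, r in enumerate(rs):
            repeat_rows.append({"kind": "forward_r", "target": mass,
                                "repeat": rep, "value": r})

    # stage 5c: forward -> backward coherence on the first label --------
    coherence = None
    if linkage_results:
        label = linkage_results[0].label
        pred_frames = _forward_predicted_frames(
            std_frames, consensus_frames, config, eval_seed)
        inst_meas = windows.build_backward_instances(
            std_frames, [c[label] for c in consensus_frames],
            horizon=config.window_s)
        inst_pred = windows.build_backward_instances(
            pred_frames, [c[label] for c in consensus_frames],
            horizon=config.window_s)
        coherence = link_mod.coherence_check(inst_meas, inst_pred, plan)

    # stage 6: tables ----------------------------------------------------
    table = link_mod.build_linkage_table(
        linkage_results, auc_min=config.auc_min, p_max=config.p_max)
    full_table = link_mod.build_linkage_table(
        linkage_results, auc_min=config.auc_min, p_max=config.p_max,
        keep_filtered=True)
    tables = outdir / "tables"
    table.to_csv(tables / "linkage_table.csv", index=False,
                 float_format="%.6g")
    record(tables / "linkage_table.csv")
    full_table.to_csv(tables / "linkage_table_unfiltered.csv", index=False,
                      float_format="%.6g")
    record(tables / "linkage_table_unfiltered.csv")
    (tables / "linkage_table.json").write_text(
        table.to_json(orient="records", indent=1))
    record(tables / "linkage_table.json")
    pd.DataFrame(repeat_rows).to_csv(tables / "repeat_metrics.csv",
                                     index=False, float_format="%.6g")
    record(tables / "repeat_metrics.csv")
    fw = pd.DataFrame([{"mass": fr.mass, "mean_r": fr.summary_r}
                       for fr in forward_results])
    fw.to_csv(tables / "forward_r.csv", index=False, float_format="%.6g")
    record(tables / "forward_r.csv")
    if coherence is not None:
        (tables / "coherence.json").write_text(json.dumps({
            "label": linkage_results[0].label,
            "auc_measured_mean": float(coherence.auc_measured.mean()),
            "auc_predicted_mean": float(coherence.auc_predicted.mean()),
            "difference": coherence.difference}, indent=1))
        record(tables / "coherence.json")

    # stage 7: figures ----------------------------------------------------
    if config.make_figures:
        _figures(outdir, screenings, repeat_rows, record)

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "evaluation_seed": eval_seed,
        "screening_seeds": scr_seeds[:-1],
        "files": sorted(written),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return {"outdir": outdir, "manifest": manifest,
            "linkage_table": table, "linkage_results": linkage_results,
            "forward_results": forward_results, "coherence": coherence}


def _forward_predicted_frames(std_frames, consensus_frames, config,
                              eval_seed: int) -> list[pd.DataFrame]:
    """Chemistry reconstructed by per-channel forward models.

    Each channel's regressor is trained on instances from every *other*
    screening and predicts the channel over the held-out screening; the
    first history window of each screening keeps the measured values
    (no past to predict from).
    """
    h = int(round(config.window_s / 30.0))
    channels = list(std_frames[0].columns)
    pred_frames = [frame.copy() for frame in std_frames]
    for mass in channels:
        for holdout in range(len(std_frames)):
            train_frames = [f for i, f in enumerate(std_frames)
                            if i != holdout]
            train_labels = [c for i, c in enumerate(consensus_frames)
                            if i != holdout]
            if not train_frames:
                continue
            inst_train = windows.build_forward_instances(
                train_frames, train_labels, target_mass=mass,
                history=config.window_s)
            model = RandomForestRegressor(
                n_estimators=config.n_trees,
                random_state=eval_seed % (2**31 - 1), n_jobs=1)
            model.fit(inst_train.X, inst_train.y)
            inst_hold = windows.build_forward_instances(
                std_frames[holdout], consensus_frames[holdout],
                target_mass=mass, history=config.window_s)
            pred = model.predict(inst_hold.X)
            times = [t for _, t in inst_hold.anchors]
            pred_frames[holdout].loc[times, mass] = pred
    for frame, std in zip(pred_frames, std_frames):
        frame.attrs["screening_id"] = std.attrs.get("screening_id")
    return pred_frames


def _figures(outdir: Path, screenings, repeat_rows, record) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    for scr in screenings:
        t_h = scr.data.index.to_numpy(dtype=float) / 3600.0
        axes[0].plot(t_h, scr.data["co2"], label=scr.screening_id)
        if "m69.070" in scr.data.columns:
            axes[1].plot(t_h, scr.data["m69.070"], label=scr.screening_id)
    axes[0].set_ylabel("CO2 (ppm)")
    axes[1].set_ylabel("isoprene m69.070 (ppb)")
    axes[1].set_xlabel("time (h)")
    axes[0].legend(fontsize=7)
    axes[0].set_title("Synthetic screenings: shark-fin CO2 and isoprene")
    fig.tight_layout()
    path = outdir / "figures" / "timeseries.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    record(path)

    rep = pd.DataFrame(repeat_rows)
    if not rep.empty:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, kind, title in (
                (axes[0], "backward_auc", "backward prediction (AUC)"),
                (axes[1], "forward_r", "forward prediction (Pearson r)")):
            sub = rep[rep["kind"] == kind]
            if sub.empty:
                continue
            groups = [g["value"].to_numpy()
                      for _, g in sub.groupby("target")]
            names = [name for name, _ in sub.groupby("target")]
            ax.boxplot(groups, tick_labels=names)
            ax.set_title(title)
            ax.tick_params(axis="x", rotation=45)
        axes[0].axhline(0.5, color="grey", ls="--", lw=0.8)
        fig.tight_layout()
        path = outdir / "figures" / "evaluation_distributions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        record(path)
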