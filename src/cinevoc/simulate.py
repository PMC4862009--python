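"""Synthetic cinema-air generator.

Emulates the physical and observational chain of a trace-gas study in a
ventilated screening room so that the downstream statistics can be tested
end to end without any measured data:

* a scene script — time-coded label events with realistic slot-coverage
  frequencies;
* an occupancy profile — arrival ramp, constant film plateau, exodus;
* a single well-mixed box model for each chemical species,
  ``dC/dt = lambda * (C_bg - C) + N(t) * E(t) / V``, solved exactly per
  step under piecewise-constant forcing;
* per-person baseline breath emissions, with scene-label-triggered
  transient pulses and an exit spike;
* a PTR-ToF-MS instrument model that converts mixing ratios back into
  raw ion counts with primary-ion / drift-parameter fluctuations and
  Poisson counting noise (the inverse of the normalization applied by
  :mod:`cinevoc.ptrms`);
* independent noisy annotator label tracks.

Concentrations are carried in ppm for CO2 and ppb for VOC channels;
per-person emission rates are in (concentration unit) * m^3 / s so that
``N * E / (lambda * V)`` is directly the equilibrium concentration excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .vocabulary import LABEL_FREQUENCIES, validate_label

__all__ = [
    "RoomScenario",
    "SceneEvent",
    "SceneScript",
    "OccupancyProfile",
    "LabelResponse",
    "ExitSpike",
    "EmissionModel",
    "InstrumentModel",
    "generate_scene_script",
    "occupancy_profile",
    "box_model_concentrations",
    "synthesize_counts",
    "simulate_annotators",
    "default_scenario",
    "default_emissions",
    "default_instrument",
    "simulate_screening",
    "DEFAULT_MASSES",
]

#: default VOC mass channels (protonated m/z -> common identity).
DEFAULT_MASSES: dict[str, str] = {
    "m33.034": "methanol",
    "m45.034": "acetaldehyde",
    "m55.058": "butadiene",
    "m59.049": "acetone",
    "m69.070": "isoprene",
    "m85.028": "2-furanone",
}

CO2 = "co2"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoomScenario:
    """A well-mixed screening room flushed by the ventilation system.

    Parameters
    ----------
    volume:
        Room volume in m^3.
    air_exchanges_per_hour:
        Ventilation rate lambda; the room air is replaced this many times
        per hour (e-fold relaxation time 1/lambda).
    background:
        Ambient concentration per species (ppm for co2, ppb for VOCs).
    time_step:
        Analysis grid step in seconds.
    """

    volume: float = 800.0
    air_exchanges_per_hour: float = 6.0
    background: dict[str, float] = field(
        default_factory=lambda: {CO2: 400.0, **{m: 0.2 for m in DEFAULT_MASSES}}
    )
    time_step: float = 30.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("room volume must be positive")
        if self.air_exchanges_per_hour <= 0:
            raise ValueError("air exchange rate must be positive")
        if self.time_step <= 0:
            raise ValueError("time step must be positive")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background concentrations must be non-negative")

    @property
    def lam(self) -> float:
        """Air exchange rate in s^-1."""
        return self.air_exchanges_per_hour / 3600.0

    @property
    def species(self) -> list[str]:
        return list(self.background)


@dataclass(frozen=True)
class SceneEvent:
    start: float
    end: float
    label: str
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad event interval [{self.start}, {self.end})")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("event intensity must lie in [0, 1]")


@dataclass(frozen=True)
class SceneScript:
    """Time-coded label events over one screening."""

    events: tuple[SceneEvent, ...]
    duration: float

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.end > self.duration:
                raise ValueError(f"event {ev} extends past duration {self.duration}")

    @property
    def labels(self) -> list[str]:
        return sorted({ev.label for ev in self.events})

    def slot_coverage(self, grid_step: float = 30.0,
                      labels: list[str] | None = None) -> pd.DataFrame:
        """Binary per-label coverage on the slot grid.

        A slot ``[t, t + grid_step)`` is covered by a label when any of
        the label's events overlaps it.
        """
        n_slots = int(round(self.duration / grid_step))
        times = np.arange(n_slots) * grid_step
        cols = labels if labels is not None else self.labels
        out = pd.DataFrame(0, index=pd.Index(times, name="time_s"),
                           columns=cols, dtype=int)
        for ev in self.events:
            if ev.label not in out.columns:
                continue
            first = int(math.floor(ev.start / grid_step))
            last = int(math.ceil(ev.end / grid_step))
            out.iloc[first:last, out.columns.get_loc(ev.label)] = 1
        return out

    def active(self, label: str, t: float) -> float:
        """Summed intensity of *label* events covering time *t*."""
        return sum(ev.intensity for ev in self.events
                   if ev.label == label and ev.start <= t < ev.end)


@dataclass(frozen=True)
class OccupancyProfile:
    """Number of people present on the analysis grid."""

    times: np.ndarray
    occupancy: np.ndarray
    capacity: int = 230

    def __post_init__(self) -> None:
        if len(self.times) != len(self.occupancy):
            raise ValueError("times and occupancy must have equal length")
        if (self.occupancy < 0).any():
            raise ValueError("occupancy must be non-negative")
        if (self.occupancy > self.capacity).any():
            raise ValueError("occupancy exceeds room capacity")

    def as_series(self) -> pd.Series:
        return pd.Series(self.occupancy,
                         index=pd.Index(self.times, name="time_s"),
                         name="occupancy")


@dataclass(frozen=True)
class LabelResponse:
    """Scene-label-triggered emission pulse on one species.

    While a pulse is active the per-person emission of *species* is
    multiplied by ``1 + gain * intensity``.  The pulse starts ``lag``
    seconds after the event onset and lasts ``duration`` seconds.
    """

    species: str
    gain: float
    lag: float = 0.0
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("pulse gain must be non-negative")
        if self.lag < 0:
            raise ValueError("pulse lag must be non-negative")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass(frozen=True)
class ExitSpike:
    """Emission burst during the exodus (limb movement after sitting)."""

    species: str
    gain: float
    duration: float = 300.0


# exhaled air is circa 4 % CO2 -> 40 000 ppm
EXHALED_CO2_PPM = 40_000.0
#: resting minute ventilation of a seated adult, m^3/s (10 L/min)
BREATHING_RATE_M3_S = 10e-3 / 60.0


@dataclass(frozen=True)
class EmissionModel:
    """Per-person source strengths and their scene-label modulation.

    ``baseline_per_person`` maps species to an emission rate in
    (concentration unit) * m^3 / s per person; the CO2 default is the
    breathing rate times the exhaled-air CO2 mixing ratio.
    """

    baseline_per_person: dict[str, float] = field(
        default_factory=lambda: {
            CO2: BREATHING_RATE_M3_S * EXHALED_CO2_PPM,  # ppm m^3/s
            "m33.034": 0.020,
            "m45.034": 0.015,
            "m55.058": 0.004,
            "m59.049": 0.057,   # audience acetone plateau of a few ppb
            "m69.070": 0.036,
            "m85.028": 0.003,
        }
    )
    label_responses: dict[str, tuple[LabelResponse, ...]] = field(
        default_factory=lambda: {
            "suspense": (LabelResponse("m69.070", gain=1.5, lag=30.0,
                                       duration=90.0),),
            "comedy": (LabelResponse("m59.049", gain=1.0, lag=30.0,
                                     duration=90.0),),
        }
    )
    exit_spike: ExitSpike | None = ExitSpike("m69.070", gain=2.0,
                                             duration=300.0)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.baseline_per_person.values()):
            raise ValueError("baseline emissions must be non-negative")
        for label, responses in self.label_responses.items():
            for resp in responses:
                if resp.species not in self.baseline_per_person:
                    raise ValueError(
                        f"label {label!r} drives unknown species "
                        f"{resp.species!r}"
                    )
        if (self.exit_spike is not None
                and self.exit_spike.species not in self.baseline_per_person):
            raise ValueError("exit spike targets unknown species")

    def rate(self, species: str, t: float, script: SceneScript,
             exodus_start: float | None = None) -> float:
        """Per-person emission rate of *species* at time *t*."""
        base = self.baseline_per_person.get(species, 0.0)
        if base == 0.0:
            return 0.0
        mult = 1.0
        for label, responses in self.label_responses.items():
            for resp in responses:
                if resp.species != species:
                    continue
                for ev in script.events:
                    if ev.label != label:
                        continue
                    if ev.start + resp.lag <= t < ev.start + resp.lag + resp.duration:
                        mult += resp.gain * ev.intensity
        if (self.exit_spike is not None and self.exit_spike.species == species
                and exodus_start is not None
                and exodus_start <= t < exodus_start + self.exit_spike.duration):
            mult += self.exit_spike.gain
        return base * mult


@dataclass(frozen=True)
class InstrumentModel:
    """PTR-ToF-MS observation model (the inverse of the normalization).

    ``sensitivity`` is in normalized counts per second per ppb.  Primary
    ions are represented by their unsaturated 18-O isotopologue channels
    m21 (H3O+) and m39 (first water cluster); their true intensities are
    recovered downstream by fixed isotopic scale-up factors.
    """

    sensitivity: dict[str, float] = field(
        default_factory=lambda: {m: 20.0 for m in DEFAULT_MASSES}
    )
    m21_baseline: float = 6000.0       # cps
    m39_baseline: float = 3000.0       # cps
    primary_drift: float = 0.03        # relative slow drift amplitude
    drift_temperature: float = 298.15  # K nominal
    temperature_jitter: float = 0.5    # K
    drift_pressure: float = 2.20       # hPa nominal
    pressure_jitter: float = 0.01      # hPa
    counting_noise: bool = True
    dwell_s: float = 30.0              # integration time per record
    co2_sigma: float = 0.0             # ppm gaussian noise on the CO2 channel
    iso_factor_m21: float = 500.0
    iso_factor_m39: float = 250.0
    t_ref: float = 298.15
    p_ref: float = 2.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sensitivity.values()):
            raise ValueError("sensitivities must be positive")
        if self.m21_baseline <= 0 or self.m39_baseline <= 0:
            raise ValueError("primary-ion baselines must be positive")
        if self.drift_pressure <= 0 or self.drift_temperature <= 0:
            raise ValueError("nominal drift pressure/temperature must be positive")


def default_scenario(**overrides) -> RoomScenario:
    return RoomScenario(**overrides)


def default_emissions(**overrides) -> EmissionModel:
    return EmissionModel(**overrides)


def default_instrument(**overrides) -> InstrumentModel:
    return InstrumentModel(**overrides)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_scene_script(label_frequencies: dict[str, float],
                          duration: float,
                          mean_event_length: float = 60.0,
                          rng_seed: int | np.random.Generator = 0,
                          vocabulary: dict[str, float] | None = None,
                          grid_step: float = 30.0) -> SceneScript:
    """Place label events so each label's long-run slot coverage matches
    its requested frequency.

    Each label is an independent stationary two-state Markov chain on
    the slot grid: mean on-run length ``mean_event_length`` (at least
    one slot) and off-to-on hazard chosen so the stationary on-fraction
    equals the requested frequency.  Generating directly on the grid
    makes the covered-slot count an unbiased estimate of the frequency
    (partial slots never over-count).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    vocab = LABEL_FREQUENCIES if vocabulary is None else vocabulary
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n_slots = int(math.ceil(duration / grid_step))
    events: list[SceneEvent] = []
    for label in sorted(label_frequencies):
        freq = label_frequencies[label]
        if label not in vocab:
            raise KeyError(f"unknown scene label {label!r}")
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"frequency for {label!r} outside [0, 1]: {freq}")
        if freq == 0.0:
            continue
        if freq == 1.0:
            events.append(SceneEvent(0.0, duration, label))
            continue
        mean_run = max(1.0, mean_event_length / grid_step)  # slots
        p_off = 1.0 / mean_run                   # on -> off per slot
        p_on = p_off * freq / (1.0 - freq)       # off -> on per slot
        on = rng.random() < freq                 # stationary start
        start: int | None = 0 if on else None
        for slot in range(1, n_slots + 1):
            if slot < n_slots:
                flip = rng.random() < (p_off if on else p_on)
                nxt = (not on) if flip else on
            else:
                nxt = False  # close any open run at the end
            if on and not nxt:
                events.append(SceneEvent(start * grid_step,
                                         min(slot * grid_step, duration),
                                         label))
                start = None
            elif not on and nxt:
                start = slot
            on = nxt
    events.sort(key=lambda ev: (ev.start, ev.label))
    return SceneScript(tuple(events), duration)


def occupancy_profile(audience_size: int,
                      film_start: float,
                      film_end: float,
                      arrival_ramp: float = 600.0,
                      exodus_ramp: float = 300.0,
                      grid: float = 30.0,
                      capacity: int = 230,
                      duration: float | None = None) -> OccupancyProfile:
    """Trapezoidal occupancy: linear arrival ramp into ``film_start``, a
    constant plateau at ``audience_size`` during the film, and a linear
    exodus ramp after ``film_end``."""
    if audience_size < 0:
        raise ValueError("audience size must be non-negative")
    if audience_size > capacity:
        raise ValueError(
            f"audience {audience_size} exceeds room capacity {capacity}")
    if film_start - arrival_ramp < 0:
        raise ValueError("arrival ramp starts before time zero")
    if duration is None:
        duration = film_end + exodus_ramp
    times = np.arange(0.0, duration + grid / 2, grid)
    n = np.zeros_like(times)
    if audience_size > 0:
        arrive0 = film_start - arrival_ramp
        rising = (times >= arrive0) & (times < film_start)
        if arrival_ramp > 0:
            n[rising] = audience_size * (times[rising] - arrive0) / arrival_ramp
        plateau = (times >= film_start) & (times <= film_end)
        n[plateau] = audience_size
        leaving = (times > film_end) & (times < film_end + exodus_ramp)
        if exodus_ramp > 0:
            n[leaving] = audience_size * (1 - (times[leaving] - film_end) / exodus_ramp)
    return OccupancyProfile(times=times, occupancy=np.round(n).astype(int),
                            capacity=capacity)


def box_model_concentrations(scenario: RoomScenario,
                             occupancy: OccupancyProfile,
                             script: SceneScript,
                             emissions: EmissionModel,
                             exodus_start: float | None = None,
                             initial: dict[str, float] | None = None,
                             ) -> pd.DataFrame:
    """Exact per-step solution of the well-mixed room balance.

    Within each grid step the forcing ``S = N * E / V`` is held constant,
    giving the closed-form update::

        C(t + dt) = C_eq + (C(t) - C_eq) * exp(-lambda * dt)
        C_eq      = C_bg + N * E / (lambda * V)

    Returns a DataFrame indexed by grid time with one column per species.
    """
    times = occupancy.times
    dt = float(times[1] - times[0]) if len(times) > 1 else scenario.time_step
    if abs(dt - scenario.time_step) > 1e-9:
        raise ValueError(
            f"occupancy grid step {dt} s does not match scenario grid "
            f"{scenario.time_step} s")
    lam = scenario.lam
    decay = math.exp(-lam * dt)
    out = np.empty((len(times), len(scenario.species)))
    for j, sp in enumerate(scenario.species):
        c_bg = scenario.background[sp]
        c = c_bg if initial is None else initial.get(sp, c_bg)
        for i, t in enumerate(times):
            out[i, j] = c
            n_people = occupancy.occupancy[i]
            rate = emissions.rate(sp, float(t), script, exodus_start)
            c_eq = c_bg + n_people * rate / (lam * scenario.volume)
            c = c_eq + (c - c_eq) * decay
    return pd.DataFrame(out, index=pd.Index(times, name="time_s"),
                        columns=scenario.species)


def synthesize_counts(concentrations: pd.DataFrame,
                      instrument: InstrumentModel,
                      rng_seed: int | np.random.Generator = 0,
                      ) -> pd.DataFrame:
    """Convert mixing ratios into a raw instrument record.

    Inverts the primary-ion normalization: per mass,
    ``raw = ncps * (f21*m21 + f39*m39) / 1e6 * (P/P_ref) * (T_ref/T)``
    with ``ncps = concentration * sensitivity``.  Primary-ion intensities
    and drift temperature/pressure carry slow sinusoidal drift plus
    jitter; raw counts optionally receive Poisson counting noise.  The
    CO2 channel bypasses the mass spectrometer (infrared analyzer) and
    only receives optional Gaussian noise.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    times = concentrations.index.to_numpy(dtype=float)
    n = len(times)
    phase = 2 * np.pi * times / 3600.0

    def drifted(baseline: float, rel: float, jitter_rel: float) -> np.ndarray:
        series = baseline * (1.0 + rel * np.sin(phase))
        if jitter_rel > 0:
            series = series * (1.0 + jitter_rel * rng.standard_normal(n))
        return series

    m21 = drifted(instrument.m21_baseline, instrument.primary_drift,
                  0.005 if instrument.counting_noise else 0.0)
    m39 = drifted(instrument.m39_baseline, instrument.primary_drift,
                  0.005 if instrument.counting_noise else 0.0)
    temp = instrument.drift_temperature + (
        instrument.temperature_jitter * np.sin(phase / 3.0)
        if instrument.temperature_jitter else 0.0)
    pres = instrument.drift_pressure + (
        instrument.pressure_jitter * np.sin(phase / 2.0)
        if instrument.pressure_jitter else 0.0)

    denom = (instrument.iso_factor_m21 * m21
             + instrument.iso_factor_m39 * m39)
    # inverse of the normalization factor, computed first so that the
    # reference-condition round trip is the exact identity
    inv_factor = (denom / 1e6 * (pres / instrument.p_ref)
                  * (instrument.t_ref / temp))
    out = pd.DataFrame(index=concentrations.index.copy())
    for mass, sens in instrument.sensitivity.items():
        if mass not in concentrations.columns:
            continue
        ncps = concentrations[mass].to_numpy(dtype=float) * sens
        raw = ncps * inv_factor
        if instrument.counting_noise:
            counts = rng.poisson(np.clip(raw, 0, None) * instrument.dwell_s)
            raw = counts / instrument.dwell_s
        out[mass] = raw
    out["m21"] = m21
    out["m39"] = m39
    out["p_drift_hPa"] = pres
    out["t_drift_K"] = temp
    if CO2 in concentrations.columns:
        co2 = concentrations[CO2].to_numpy(dtype=float)
        if instrument.co2_sigma > 0:
            co2 = co2 + instrument.co2_sigma * rng.standard_normal(n)
        out[CO2] = co2
    return out


def simulate_annotators(script: SceneScript,
                        n_annotators: int = 10,
                        miss_rate: float = 0.05,
                        false_rate: float = 0.01,
                        jitter: float = 15.0,
                        rng_seed: int | np.random.Generator = 0,
                        grid_step: float = 30.0,
                        labels: list[str] | None = None,
                        with_scales: bool = True) -> AnnotationSet:
    """Independent noisy annotator tracks for one screening.

    Each annotator perceives every event with its boundaries jittered by
    a centered Gaussian of SD ``jitter`` seconds, then misses covered
    slots with probability ``miss_rate`` and spuriously marks uncovered
    slots with probability ``false_rate``.  Affect scales are a coarse
    function of the active genre labels plus +/-1 annotator noise.
    """
    if n_annotators < 1:
        raise ValueError("need at least one annotator")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    cols = labels if labels is not None else script.labels
    tracks: dict[str, pd.DataFrame] = {}
    scales: dict[str, pd.DataFrame] = {}
    n_slots = int(round(script.duration / grid_step))
    slot_times = np.arange(n_slots) * grid_step
    noiseless = miss_rate == 0 and false_rate == 0 and jitter == 0
    for a in range(n_annotators):
        if noiseless:
            perceived = script
        else:
            evs = []
            for ev in script.events:
                s = ev.start + rng.normal(0.0, jitter) if jitter else ev.start
                e = ev.end + rng.normal(0.0, jitter) if jitter else ev.end
                s = min(max(s, 0.0), script.duration)
                e = min(max(e, 0.0), script.duration)
                if e > s:
                    evs.append(SceneEvent(s, e, ev.label, ev.intensity))
            perceived = SceneScript(tuple(evs), script.duration)
        frame = perceived.slot_coverage(grid_step, labels=cols)
        if not noiseless:
            vals = frame.to_numpy()
            flip_off = rng.random(vals.shape) < miss_rate
            flip_on = rng.random(vals.shape) < false_rate
            vals = np.where(vals == 1, np.where(flip_off, 0, 1),
                            np.where(flip_on, 1, 0))
            frame = pd.DataFrame(vals, index=frame.index,
                                 columns=frame.columns)
        tracks[f"annotator_{a:02d}"] = frame
        if with_scales:
            happy = np.full(n_slots, 3.0)
            excited = np.full(n_slots, 3.0)
            for i, t in enumerate(slot_times):
                if script.active("comedy", t):
                    happy[i] -= 1.5
                if script.active("crying", t) or script.active("death", t):
                    happy[i] += 1.5
                if script.active("suspense", t) or script.active("action", t):
                    excited[i] -= 1.5
            if not noiseless:
                happy = happy + rng.integers(-1, 2, n_slots)
                excited = excited + rng.integers(-1, 2, n_slots)
            scales[f"annotator_{a:02d}"] = pd.DataFrame(
                {"happy_sad": np.clip(np.round(happy), 1, 5).astype(int),
                 "excited_calm": np.clip(np.round(excited), 1, 5).astype(int)},
                index=frame.index)
    return AnnotationSet(tracks=tracks, scales=scales if with_scales else None)


# ---------------------------------------------------------------------------
# one-call screening synthesis
# ---------------------------------------------------------------------------

def simulate_screening(audience_size: int,
                       film_duration: float = 7200.0,
                       scenario: RoomScenario | None = None,
                       emissions: EmissionModel | None = None,
                       instrument: InstrumentModel | None = None,
                       label_frequencies: dict[str, float] | None = None,
                       arrival_ramp: float = 600.0,
                       exodus_ramp: float = 300.0,
                       n_annotators: int = 10,
                       annotator_noise: dict | None = None,
                       rng_seed: int = 0,
                       ) -> dict:
    """Generate one full synthetic screening.

    Returns a dict with keys ``script``, ``occupancy``, ``concentrations``
    (truth on the grid), ``raw`` (instrument record) and ``annotations``.
    The script clock starts at the film start; occupancy and chemistry
    extend over the arrival ramp and the exodus.
    """
    scenario = scenario or default_scenario()
    emissions = emissions or default_emissions()
    instrument = instrument or default_instrument()
    if label_frequencies is None:
        label_frequencies = {
            lab: LABEL_FREQUENCIES[lab]
            for lab in ("conversation", "suspense", "comedy", "injury")
        }
    seeds = np.random.SeedSequence(rng_seed).spawn(3)
    script = generate_scene_script(
        label_frequencies, duration=film_duration,
        rng_seed=np.random.default_rng(seeds[0]))
    film_start = arrival_ramp
    film_end = film_start + film_duration
    occ = occupancy_profile(audience_size, film_start, film_end,
                            arrival_ramp, exodus_ramp,
                            grid=scenario.time_step)
    # shift the script onto the room clock (events are film-relative)
    shifted = SceneScript(
        tuple(SceneEvent(ev.start + film_start, ev.end + film_start,
                         ev.label, ev.intensity) for ev in script.events),
        duration=film_end + exodus_ramp)
    conc = box_model_concentrations(scenario, occ, shifted, emissions,
                                    exodus_start=film_end)
    raw = synthesize_counts(conc, instrument,
                            rng_seed=np.random.default_rng(seeds[1]))
    noise = annotator_noise or {}
    ann = simulate_annotators(script, n_annotators=n_annotators,
                              rng_seed=np.random.default_rng(seeds[2]),
                              grid_step=scenario.time_step,
                              labels=sorted(label_frequencies),
                              **noise)
    return {"script": script, "script_room_clock": shifted,
            "occupancy": occ, "concentrations": conc, "raw": raw,
            "annotations": ann, "film_start": film_start,
            "film_end": film_end}
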