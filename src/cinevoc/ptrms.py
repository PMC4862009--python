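"""PTR-ToF-MS signal processing.

Raw per-mass ion count rates are normalized to the primary-ion signal
(H3O+ and its first water cluster, observed through their unsaturated
18-O isotopologues m21 and m39) and to reference drift conditions of
298.15 K and 2 mbar:

    ncps = R * 1e6 / (f21 * [m21] + f39 * [m39]) * (P_ref / P) * (T / T_ref)

Normalized counts are converted to mixing ratios by per-mass calibration
sensitivities, values below the 3-sigma detection limit are flagged (but
retained), and everything is resampled onto the 30 s analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationEntry",
    "CalibrationTable",
    "ScreeningTimeSeries",
    "normalize_counts",
    "counts_to_mixing_ratio",
    "flag_below_detection",
    "resample_to_grid",
    "process_screening",
    "RESERVED_COLUMNS",
]

#: raw-record columns that are not analyte mass channels
RESERVED_COLUMNS = ("m21", "m39", "p_drift_hPa", "t_drift_K", "co2",
                    "occupancy")

T_REF_K = 298.15
P_REF_HPA = 2.0  # 2 mbar
ISO_FACTOR_M21 = 500.0  # 18-O abundance scale-up, H3O+
ISO_FACTOR_M39 = 250.0  # 18-O abundance scale-up, first water cluster


@dataclass(frozen=True)
class CalibrationEntry:
    """Calibration for one mass channel.

    sensitivity in ncps/ppb; detection_limit in ppb (3 sigma of the
    blank noise); relative_uncertainty as a fraction of the value.
    """

    sensitivity: float
    detection_limit: float = 0.0
    relative_uncertainty: float = 0.15
    identity: str = ""
    formula: str = ""

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be non-negative")


class CalibrationTable(dict):
    """Mapping mass id -> :class:`CalibrationEntry`."""

    @classmethod
    def uniform(cls, masses, sensitivity: float = 20.0,
                detection_limit: float = 0.05,
                relative_uncertainty: float = 0.15) -> "CalibrationTable":
        return cls({m: CalibrationEntry(sensitivity, detection_limit,
                                        relative_uncertainty)
                    for m in masses})

    def to_metadata(self) -> dict:
        return {m: {"sensitivity_ncps_per_ppb": e.sensitivity,
                    "detection_limit_ppb": e.detection_limit,
                    "relative_uncertainty": e.relative_uncertainty,
                    "identity": e.identity,
                    "formula": e.formula}
                for m, e in self.items()}


@dataclass
class ScreeningTimeSeries:
    """Processed per-screening record on the uniform analysis grid.

    ``data`` is indexed by time in seconds (strictly increasing, uniform)
    and holds one column per mass channel (ppb), plus ``co2`` (ppm) and
    optionally ``occupancy``.  ``below_dl`` flags sub-detection-limit
    values channel-wise; flagged values are retained, never zeroed.
    """

    screening_id: str
    data: pd.DataFrame
    film_name: str = ""
    below_dl: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data.index.to_numpy(dtype=float)
        if len(t) >= 2:
            steps = np.diff(t)
            if (steps <= 0).any():
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("time grid must be uniformly spaced")
        if self.below_dl is not None and len(self.below_dl) != len(self.data):
            raise ValueError("below_dl flags must match the data length")

    @property
    def grid_step(self) -> float:
        t = self.data.index.to_numpy(dtype=float)
        return float(t[1] - t[0]) if len(t) >= 2 else float("nan")

    @property
    def mass_channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def channels(self) -> list[str]:
        """Analysis channels: mass channels plus CO2 when present."""
        cols = self.mass_channels
        if "co2" in self.data.columns:
            cols = cols + ["co2"]
        return cols


def _mass_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c not in RESERVED_COLUMNS]


def normalize_counts(record: pd.DataFrame,
                     iso_factor_m21: float = ISO_FACTOR_M21,
                     iso_factor_m39: float = ISO_FACTOR_M39,
                     t_ref: float = T_REF_K,
                     p_ref: float = P_REF_HPA) -> pd.DataFrame:
    """Primary-ion and drift-condition normalization of raw count rates.

    Homogeneous of degree +1 in the analyte counts and -1 in the
    primary-ion denominator; raises on non-positive primary-ion counts,
    naming the first offending timestamp.
    """
    for col in ("m21", "m39", "p_drift_hPa", "t_drift_K"):
        if col not in record.columns:
            raise ValueError(f"raw record lacks required column {col!r}")
    m21 = record["m21"].to_numpy(dtype=float)
    m39 = record["m39"].to_numpy(dtype=float)
    for name, arr in (("m21", m21), ("m39", m39)):
        bad = arr <= 0
        if bad.any():
            t_bad = record.index[bad][0]
            raise ValueError(
                f"non-positive primary-ion counts ({name}) at t={t_bad}")
    pres = record["p_drift_hPa"].to_numpy(dtype=float)
    temp = record["t_drift_K"].to_numpy(dtype=float)
    if (pres <= 0).any() or (temp <= 0).any():
        raise ValueError("drift pressure/temperature must be positive")
    denom = iso_factor_m21 * m21 + iso_factor_m39 * m39
    factor = 1e6 / denom * (p_ref / pres) * (temp / t_ref)
    out = pd.DataFrame(index=record.index.copy())
    for col in _mass_columns(record):
        out[col] = record[col].to_numpy(dtype=float) * factor
    return out


def counts_to_mixing_ratio(ncps: pd.DataFrame,
                           calibration: CalibrationTable,
                           missing: str = "error",
                           ) -> tuple[pd.DataFrame, dict]:
    """ncps -> ppb via per-mass sensitivities.

    ``missing`` controls masses absent from the calibration table:
    ``"error"`` raises, ``"passthrough"`` keeps the channel in ncps and
    flags it in the metadata.  Returned metadata records per-mass units
    and the propagated relative uncertainty (multiplicative calibration,
    so the relative uncertainty transfers unchanged).
    """
    if missing not in ("error", "passthrough"):
        raise ValueError("missing must be 'error' or 'passthrough'")
    out = pd.DataFrame(index=ncps.index.copy())
    meta: dict[str, dict] = {}
    for col in _mass_columns(ncps):
        entry = calibration.get(col)
        if entry is None:
            if missing == "error":
                raise KeyError(f"mass {col!r} missing from calibration table")
            out[col] = ncps[col]
            meta[col] = {"unit": "ncps", "calibrated": False}
            continue
        out[col] = ncps[col] / entry.sensitivity
        meta[col] = {"unit": "ppb", "calibrated": True,
                     "relative_uncertainty": entry.relative_uncertainty}
    return out, meta


def flag_below_detection(series: pd.DataFrame,
                         calibration: CalibrationTable) -> pd.DataFrame:
    """Boolean frame: True where a value sits below its channel's
    detection limit.  Values are retained upstream, never zeroed."""
    out = pd.DataFrame(False, index=series.index,
                       columns=_mass_columns(series))
    for col in out.columns:
        entry = calibration.get(col)
        if entry is not None and entry.detection_limit > 0:
            out[col] = series[col] < entry.detection_limit
    return out


def resample_to_grid(series: pd.DataFrame | pd.Series,
                     grid_step: float = 30.0,
                     aggregator: str = "mean") -> pd.DataFrame:
    """Aggregate onto the uniform analysis grid.

    Output slot t holds the aggregator (default mean) of input samples
    with timestamps in [t, t + grid_step); slots without samples are
    NaN (missing, never interpolated).
    """
    frame = series.to_frame() if isinstance(series, pd.Series) else series
    t = frame.index.to_numpy(dtype=float)
    if len(t) >= 2 and (np.diff(t) <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    slots = np.floor(t / grid_step) * grid_step
    grouped = frame.groupby(slots).agg(aggregator)
    full = np.arange(slots.min(), slots.max() + grid_step / 2, grid_step)
    out = grouped.reindex(full)
    out.index.name = "time_s"
    return out


def process_screening(raw: pd.DataFrame,
                      calibration: CalibrationTable,
                      screening_id: str = "screening",
                      film_name: str = "",
                      grid_step: float = 30.0,
                      occupancy: pd.Series | None = None,
                      missing: str = "error",
                      iso_factor_m21: float = ISO_FACTOR_M21,
                      iso_factor_m39: float = ISO_FACTOR_M39,
                      t_ref: float = T_REF_K,
                      p_ref: float = P_REF_HPA) -> ScreeningTimeSeries:
    """Full chain raw record -> :class:`ScreeningTimeSeries`:
    normalize, calibrate, flag detection limits, resample to the grid."""
    ncps = normalize_counts(raw, iso_factor_m21, iso_factor_m39,
                            t_ref, p_ref)
    ppb, meta = counts_to_mixing_ratio(ncps, calibration, missing=missing)
    if "co2" in raw.columns:
        ppb["co2"] = raw["co2"]
    gridded = resample_to_grid(ppb, grid_step)
    flags = flag_below_detection(gridded, calibration)
    if occupancy is not None:
        occ = resample_to_grid(occupancy, grid_step)
        gridded["occupancy"] = occ.iloc[:, 0].reindex(gridded.index)
    return ScreeningTimeSeries(
        screening_id=screening_id, film_name=film_name, data=gridded,
        below_dl=flags,
        metadata={"calibration": calibration.to_metadata(),
                  "channels": meta, "grid_step_s": grid_step})
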