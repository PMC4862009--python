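"""Windowed supervised instances from screening time series.

Two directions around an anchor slot t on the 30 s grid:

* backward prediction — classify the scene label *at* t from the
  chemical channels in the strictly-future 5-minute window
  [t + 30 s, t + 5 min];
* forward prediction — regress one chemical channel at t on all
  chemical channels and all labels in the past window
  [t - 5 min, t - 30 s] (the target's own past included:
  autoregression).

Channels are z-scored per screening beforehand (zero-variance channels
dropped), instances never span a screening boundary, and instances
containing missing values are dropped rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ptrms import ScreeningTimeSeries

__all__ = [
    "NormalizationState",
    "WindowedInstances",
    "standardize",
    "build_backward_instances",
    "build_forward_instances",
]


@dataclass
class NormalizationState:
    """Per-channel center/scale used for z-scoring one screening.

    Population standard-deviation convention (ddof=0); channels with
    zero variance are dropped and listed in ``dropped``.
    """

    center: dict[str, float]
    scale: dict[str, float]
    dropped: tuple[str, ...] = ()

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col in out.columns:
            if col in self.center:
                out[col] = out[col] * self.scale[col] + self.center[col]
        return out


@dataclass
class WindowedInstances:
    """Flat supervised instances with full provenance.

    ``X`` has one column per (channel, lag-offset) pair, offsets counted
    in 30 s grid steps (positive = future, negative = past);
    ``feature_names`` gives the ordered pairs; ``anchors`` records
    (screening_id, anchor time) per row.
    """

    direction: str                      # "backward" | "forward"
    target: str                         # label name or mass id
    X: np.ndarray
    y: np.ndarray
    feature_names: list[tuple[str, int]]
    anchors: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("backward", "forward"):
            raise ValueError("direction must be 'backward' or 'forward'")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for ch, _ in self.feature_names:
            if ch not in seen:
                seen.append(ch)
        return seen

    def columns_for(self, channel: str) -> np.ndarray:
        """Indices of every lag column belonging to *channel*."""
        return np.array([i for i, (ch, _) in enumerate(self.feature_names)
                         if ch == channel], dtype=int)

    def without_channel(self, channel: str) -> "WindowedInstances":
        """Copy with all of *channel*'s lag columns removed."""
        drop = set(self.columns_for(channel).tolist())
        if not drop:
            raise KeyError(f"channel {channel!r} not among features")
        keep = [i for i in range(self.X.shape[1]) if i not in drop]
        return WindowedInstances(
            direction=self.direction, target=self.target,
            X=self.X[:, keep], y=self.y,
            feature_names=[self.feature_names[i] for i in keep],
            anchors=list(self.anchors))

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV-ready table: provenance, features, target."""
        cols = {f"{ch}@{off:+d}": self.X[:, i]
                for i, (ch, off) in enumerate(self.feature_names)}
        frame = pd.DataFrame(cols)
        frame.insert(0, "screening_id", [a[0] for a in self.anchors])
        frame.insert(1, "anchor_time_s", [a[1] for a in self.anchors])
        frame["target"] = self.y
        return frame


def standardize(series: ScreeningTimeSeries | pd.DataFrame,
                columns: list[str] | None = None,
                ) -> tuple[pd.DataFrame, NormalizationState]:
    """z-score each channel within one screening.

    Returns the standardized frame (zero-variance channels dropped, with
    a warning) and the invertible :class:`NormalizationState`.
    """
    frame = series.data[series.channels] if isinstance(
        series, ScreeningTimeSeries) else series
    if columns is not None:
        frame = frame[columns]
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    dropped: list[str] = []
    out = {}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        mu = float(np.nanmean(vals))
        sd = float(np.nanstd(vals))  # population convention
        if sd == 0 or not np.isfinite(sd):
            dropped.append(col)
            continue
        center[col] = mu
        scale[col] = sd
        out[col] = (vals - mu) / sd
    if dropped:
        warnings.warn(
            f"dropped zero-variance channel(s): {dropped}", stacklevel=2)
    return (pd.DataFrame(out, index=frame.index),
            NormalizationState(center, scale, tuple(dropped)))


def _steps(horizon: float, grid_step: float) -> int:
    k = horizon / grid_step
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"window of {horizon} s is not a positive multiple of the "
            f"{grid_step} s grid step")
    return int(round(k))


def _as_screening_list(series, labels):
    if isinstance(series, (list, tuple)):
        return list(zip(series, labels))
    return [(series, labels)]


def _check_alignment(frame: pd.DataFrame, labels) -> None:
    if not frame.index.equals(labels.index):
        raise ValueError("series and labels do not share the time grid")


def build_backward_instances(series, labels, horizon: float = 300.0,
                             grid_step: float = 30.0,
                             include_anchor: bool = False,
                             target_label: str | None = None,
                             ) -> WindowedInstances:
    """Backward-prediction instances: label at t from future chemistry.

    Parameters
    ----------
    series:
        Standardized channel DataFrame (index: grid time) or a list of
        them (one per screening); cross-screening windows are never
        formed.
    labels:
        Aligned label Series (binary target) or DataFrame with a
        ``target_label`` column — one per screening if ``series`` is a
        list.
    horizon:
        Future half-window length; must be a multiple of the grid step.
    include_anchor:
        When True the anchor slot t itself joins the window (offsets
        0..H); default is the strictly-future window (offsets 1..H).
    """
    h = _steps(horizon, grid_step)
    offsets = list(range(0 if include_anchor else 1, h + 1))
    pairs = _as_screening_list(series, labels)
    X_parts, y_parts, anchors = [], [], []
    feature_names: list[tuple[str, int]] | None = None
    target_name: str | None = target_label
    for s_idx, (frame, lab) in enumerate(pairs):
        sid = frame.attrs.get("screening_id", f"screening_{s_idx}")
        if isinstance(lab, pd.DataFrame):
            if target_label is None:
                raise ValueError("target_label required with a label frame")
            lab = lab[target_label]
        if target_name is None:
            target_name = lab.name
        _check_alignment(frame, lab)
        chans = list(frame.columns)
        names = [(ch, off) for ch in chans for off in offsets]
        if feature_names is None:
            feature_names = names
        elif names != feature_names:
            raise ValueError("screenings disagree on channels")
        vals = frame.to_numpy(dtype=float)
        yv = lab.to_numpy(dtype=float)
        n = len(frame)
        for i in range(n - h):
            window = vals[i + offsets[0]: i + h + 1, :]  # rows: offsets
            row = window.T.reshape(-1)                   # channel-major
            if np.isnan(row).any() or np.isnan(yv[i]):
                continue
            X_parts.append(row)
            y_parts.append(yv[i])
            anchors.append((sid, float(frame.index[i])))
    return WindowedInstances(
        direction="backward", target=str(target_name or "label"),
        X=np.array(X_parts) if X_parts else np.empty((0, len(feature_names or []))),
        y=np.array(y_parts), feature_names=feature_names or [],
        anchors=anchors)


def build_forward_instances(series, labels, target_mass: str,
                            history: float = 300.0,
                            grid_step: float = 30.0) -> WindowedInstances:
    """Forward-prediction instances: one chemical channel at t from all
    channels *and* all labels over the past window (the target's own
    lagged values included)."""
    h = _steps(history, grid_step)
    offsets = list(range(-h, 0))
    pairs = _as_screening_list(series, labels)
    X_parts, y_parts, anchors = [], [], []
    feature_names: list[tuple[str, int]] | None = None
    for s_idx, (frame, lab) in enumerate(pairs):
        sid = frame.attrs.get("screening_id", f"screening_{s_idx}")
        if isinstance(lab, pd.Series):
            lab = lab.to_frame()
        _check_alignment(frame, lab)
        if target_mass not in frame.columns:
            raise KeyError(f"target channel {target_mass!r} not in series")
        chans = list(frame.columns)
        lab_cols = list(lab.columns)
        names = ([(ch, off) for ch in chans for off in offsets]
                 + [(lb, off) for lb in lab_cols for off in offsets])
        if feature_names is None:
            feature_names = names
        elif names != feature_names:
            raise ValueError("screenings disagree on channels/labels")
        vals = frame.to_numpy(dtype=float)
        labv = lab.to_numpy(dtype=float)
        yv = frame[target_mass].to_numpy(dtype=float)
        n = len(frame)
        for i in range(h, n):
            w_chan = vals[i - h: i, :].T.reshape(-1)
            w_lab = labv[i - h: i, :].T.reshape(-1)
            row = np.concatenate([w_chan, w_lab])
            if np.isnan(row).any() or np.isnan(yv[i]):
                continue
            X_parts.append(row)
            y_parts.append(yv[i])
            anchors.append((sid, float(frame.index[i])))
    return WindowedInstances(
        direction="forward", target=target_mass,
        X=np.array(X_parts) if X_parts else np.empty((0, len(feature_names or []))),
        y=np.array(y_parts), feature_names=feature_names or [],
        anchors=anchors)
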