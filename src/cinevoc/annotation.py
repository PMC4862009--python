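"""Consensus over multi-annotator, time-coded scene labels.

Several volunteers independently mark binary scene labels (and two
1-5 ordinal affect scales) on a common 30 s slot grid.  A label is
accepted for a slot only when at least a configurable fraction of the
annotators agree (default two thirds, with a ceiling rule: 10 annotators
require 7 agreeing); affect scales are averaged instead.  Sub-labels can
optionally be OR-rolled-up into their parent label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocabulary import AFFECT_SCALES, DEFAULT_HIERARCHY

__all__ = [
    "AnnotationSet",
    "LabelTrack",
    "consensus_labels",
    "consensus_frame",
    "average_scales",
    "rollup_hierarchy",
    "binarize_scale",
    "required_agreement",
]


@dataclass
class AnnotationSet:
    """Per-annotator label tracks on a shared slot grid.

    ``tracks`` maps annotator id to a binary DataFrame (index: slot time
    in seconds, columns: label names, values in {0, 1}; NaN marks slots
    the annotator did not annotate).  ``scales`` optionally maps
    annotator id to a DataFrame with the two ordinal affect columns.
    """

    tracks: dict[str, pd.DataFrame]
    scales: dict[str, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("annotation set needs at least one annotator")
        grids = [tuple(frame.index) for frame in self.tracks.values()]
        if len(set(grids)) != 1:
            raise ValueError("annotator tracks do not share one slot grid")
        for aid, frame in self.tracks.items():
            vals = frame.to_numpy(dtype=float)
            ok = np.isnan(vals) | (vals == 0) | (vals == 1)
            if not ok.all():
                raise ValueError(f"annotator {aid!r} has non-binary values")
        if self.scales:
            for aid, frame in self.scales.items():
                vals = frame[list(AFFECT_SCALES)].to_numpy(dtype=float)
                ok = np.isnan(vals) | ((vals >= 1) & (vals <= 5))
                if not ok.all():
                    raise ValueError(
                        f"annotator {aid!r} has affect values outside 1..5")

    @property
    def grid(self) -> pd.Index:
        return next(iter(self.tracks.values())).index

    @property
    def n_annotators(self) -> int:
        return len(self.tracks)

    @property
    def labels(self) -> list[str]:
        names: set[str] = set()
        for frame in self.tracks.values():
            names.update(frame.columns)
        return sorted(names)


@dataclass
class LabelTrack:
    """One consensus (binary) or averaged (real) label on the slot grid."""

    name: str
    values: pd.Series
    support: pd.Series = field(default=None)  # annotators contributing/slot


def required_agreement(agreement_fraction: float, n_annotators: int) -> int:
    """Smallest count satisfying "at least the given fraction agree".

    Implements ceil(fraction * n) with a guard against floating-point
    representation of fractions like 2/3 (so 9 annotators need 6, not 7).
    """
    return max(1, math.ceil(agreement_fraction * n_annotators - 1e-9))


def consensus_labels(annotations: AnnotationSet,
                     agreement_fraction: float = 2.0 / 3.0,
                     ) -> dict[str, LabelTrack]:
    """Consensus binary track per label.

    A slot is on iff the number of annotators marking the label is at
    least ``ceil(agreement_fraction * n_annotators)``; the number of
    annotators contributing (non-missing) per slot is recorded as
    support.
    """
    n = annotations.n_annotators
    need = required_agreement(agreement_fraction, n)
    out: dict[str, LabelTrack] = {}
    for label in annotations.labels:
        stack = pd.concat(
            [frame[label] if label in frame.columns
             else pd.Series(np.nan, index=annotations.grid)
             for frame in annotations.tracks.values()], axis=1)
        votes = stack.sum(axis=1, skipna=True)
        support = stack.notna().sum(axis=1)
        values = (votes >= need).astype(int)
        values.name = label
        out[label] = LabelTrack(label, values, support)
    return out


def consensus_frame(annotations: AnnotationSet,
                    agreement_fraction: float = 2.0 / 3.0) -> pd.DataFrame:
    """Consensus tracks as one DataFrame (index: slot, columns: labels)."""
    tracks = consensus_labels(annotations, agreement_fraction)
    return pd.DataFrame({name: tr.values for name, tr in tracks.items()})


def average_scales(annotations: AnnotationSet,
                   ) -> tuple[LabelTrack, LabelTrack]:
    """Per-slot arithmetic mean of the two affect scales over annotators.

    Slots no annotator scored are missing (NaN).
    """
    if not annotations.scales:
        raise ValueError("annotation set carries no affect scales")
    out = []
    for scale in AFFECT_SCALES:
        stack = pd.concat([frame[scale]
                           for frame in annotations.scales.values()], axis=1)
        mean = stack.mean(axis=1, skipna=True)
        mean.name = scale
        out.append(LabelTrack(scale, mean, stack.notna().sum(axis=1)))
    return out[0], out[1]


def rollup_hierarchy(tracks: pd.DataFrame,
                     hierarchy: dict[str, tuple[str, ...]] | None = None,
                     ) -> pd.DataFrame:
    """OR sub-labels into their parent: parent := max(parent, children).

    Idempotent; labels absent from the frame are ignored.
    """
    hier = DEFAULT_HIERARCHY if hierarchy is None else hierarchy
    # reject cycles / multiple parents
    seen_children: set[str] = set()
    for parent, children in hier.items():
        for child in children:
            if child in seen_children:
                raise ValueError(f"label {child!r} has more than one parent")
            seen_children.add(child)
        if parent in seen_children:
            raise ValueError("hierarchy must be acyclic (one level deep)")
    out = tracks.copy()
    for parent, children in hier.items():
        present = [c for c in children if c in out.columns]
        if parent in out.columns and present:
            out[parent] = out[[parent, *present]].max(axis=1)
    return out


def binarize_scale(track: LabelTrack | pd.Series, cut: float = 4.0) -> pd.Series:
    """Binary version of an averaged ordinal scale: 1 iff value >= cut
    (default: top two points of the 1-5 scale)."""
    values = track.values if isinstance(track, LabelTrack) else track
    out = (values >= cut).astype(int)
    out[values.isna()] = 0
    return out
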