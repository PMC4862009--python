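"""Scene-label vocabulary for time-coded film annotation.

Labels come in two families: *content* labels describing what is on
screen (conversation, running, injury, ...) and *genre* labels describing
the register of a scene (suspense, comedy, mystery, ...).  Some labels
are sub-labels of a parent (e.g. "chase" under "suspense"); two ordinal
affect scales (happy--sad, excited--calm, each 1-5) complement the binary
labels.  The relative frequency attached to each label is the long-run
fraction of 30 s time slots the label covers in a typical feature film,
and parameterises the synthetic scene-script generator.
"""

from __future__ import annotations

# label -> long-run fraction of 30 s slots covered
CONTENT_LABEL_FREQUENCIES: dict[str, float] = {
    "everyday_life": 0.025,
    "dream": 0.016,
    "landscape": 0.040,
    "conversation": 0.680,
    "aggressive": 0.008,
    "conv_main_actor": 0.321,
    "action": 0.141,
    "death": 0.022,
    "running": 0.031,
    "recovery": 0.001,
    "laughter": 0.004,
    "sleeping": 0.001,
    "blood": 0.028,
    "sex": 0.003,
    "kissing": 0.009,
    "crying": 0.007,
    "main_char_cry": 0.006,
    "injury": 0.008,
    "sudden_shock": 0.026,
}

GENRE_LABEL_FREQUENCIES: dict[str, float] = {
    "suspense": 0.283,
    "chase": 0.002,
    "hidden_threat": 0.005,
    "hiding": 0.002,
    "comedy": 0.054,
    "romantic_comedy": 0.002,
    "mystery": 0.002,
    "romance": 0.014,
    "drama": 0.019,
}

LABEL_FREQUENCIES: dict[str, float] = {
    **CONTENT_LABEL_FREQUENCIES,
    **GENRE_LABEL_FREQUENCIES,
}

#: parent -> children, following the sub-label indentation of the
#: annotation scheme.  Roll-up over this map is optional downstream.
DEFAULT_HIERARCHY: dict[str, tuple[str, ...]] = {
    "conversation": ("aggressive", "conv_main_actor"),
    "crying": ("main_char_cry",),
    "suspense": ("chase", "hidden_threat", "hiding"),
}

AFFECT_SCALES: tuple[str, str] = ("happy_sad", "excited_calm")


def validate_label(name: str) -> str:
    """Return *name* if it is a registered label, else raise KeyError."""
    if name not in LABEL_FREQUENCIES:
        raise KeyError(
            f"unknown scene label {name!r}; registered labels: "
            f"{sorted(LABEL_FREQUENCIES)}"
        )
    return name
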