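"""Diary item vocabulary and composite definitions.

The once-daily diary carries four sleep fields (bed time, rise time, sleep
duration in hours, sleep quality on 1-5) and fourteen symptom items rated on a
1-7 Likert scale.  Six summary psychopathology variables are derived as
arithmetic means of item subsets; hallucinations is a single-item copy.
"""

from __future__ import annotations

MOOD_ITEMS: list[str] = [
    "cheerful",
    "anxious",
    "relaxed",
    "irritable",
    "sad",
    "in_control",
    "stressed",
]

PSYCHOSIS_COGNITION_ITEMS: list[str] = [
    "suspicious",
    "trouble_concentrating",
    "preoccupied_by_thoughts",
    "others_dislike_me",
    "confused",
    "others_influence_thoughts",
    "unusual_sights_sounds",
]

SYMPTOM_ITEMS: list[str] = MOOD_ITEMS + PSYCHOSIS_COGNITION_ITEMS

#: composite name -> constituent items (arithmetic mean; single item = copy)
COMPOSITES: dict[str, list[str]] = {
    "positive_affect": ["cheerful", "relaxed", "in_control"],
    "negative_affect": ["anxious", "irritable", "sad", "stressed"],
    "cognitive": ["trouble_concentrating", "confused"],
    "psychosis": [
        "suspicious",
        "preoccupied_by_thoughts",
        "others_dislike_me",
        "others_influence_thoughts",
        "unusual_sights_sounds",
    ],
    "paranoia": ["suspicious", "others_dislike_me"],
    "hallucinations": ["unusual_sights_sounds"],
}

SLEEP_FIELDS: list[str] = ["sleep_duration", "sleep_quality"]

#: variables entering the lag analyses (after person-standardization)
ANALYSIS_VARIABLES: list[str] = SLEEP_FIELDS + list(COMPOSITES)

#: optional clock-time passthrough fields (never analysed)
TIME_FIELDS: list[str] = ["time_into_bed", "time_out_of_bed"]

#: inclusive numeric ranges used by the reader's row validation
VALUE_RANGES: dict[str, tuple[float, float]] = {
    "sleep_quality": (1, 5),
    "sleep_duration": (0.0, 16.0),
    **{item: (1, 7) for item in SYMPTOM_ITEMS},
}

#: Likert level counts on the raw diary scale
LIKERT_LEVELS: dict[str, int] = {
    "sleep_quality": 5,
    **{item: 7 for item in SYMPTOM_ITEMS},
}


class EsmlagError(Exception):
    """Base class for errors raised by this package."""


class SimulationError(EsmlagError, ValueError):
    """Invalid or non-stationary simulation configuration."""


class IngestError(EsmlagError, ValueError):
    """Unreadable or structurally invalid diary input."""


class FitError(EsmlagError, RuntimeError):
    """Model estimation failed (no usable rows, singular fit, ...)."""
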