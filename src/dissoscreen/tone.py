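"""Tone-of-voice valence banding.

Maps the five spoken-emotion labels produced by a speech emotion
recognizer (joy, boredom, anger, sadness, neutral) onto the trinary
valence band (+1 positive, 0 neutral, -1 negative) that the text
channels also use, so the three channels can be compared.  Audio itself
is out of scope: emotion labels (or bands directly) come in as data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["ToneBandMap", "DEFAULT_BAND_MAP", "RECOGNIZED_EMOTIONS",
           "map_emotion"]

RECOGNIZED_EMOTIONS = frozenset({"joy", "boredom", "anger", "sadness",
                                 "neutral"})

# joy is the only positively valenced label in the set and neutral the
# only neutral one; boredom is treated as negative (low-arousal negative
# valence), alongside anger and sadness.
DEFAULT_BAND_MAP: dict[str, int] = {
    "joy": 1,
    "neutral": 0,
    "anger": -1,
    "sadness": -1,
    "boredom": -1,
}


@dataclass(frozen=True)
class ToneBandMap:
    """Total mapping from recognized emotion names to valence bands."""

    mapping: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BAND_MAP))

    def __post_init__(self) -> None:
        keys = {k.lower() for k in self.mapping}
        if keys != RECOGNIZED_EMOTIONS:
            raise ValueError(
                f"band map must cover exactly {sorted(RECOGNIZED_EMOTIONS)}, "
                f"got {sorted(keys)}"
            )
        bad = {k: v for k, v in self.mapping.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"bands must be -1, 0 or +1; got {bad}")

    def band(self, label: str) -> int:
        return map_emotion(label, self)


def map_emotion(label: str, band_map: ToneBandMap | None = None) -> int:
    """Return the valence band of an emotion label (case-insensitive)."""
    band_map = band_map or ToneBandMap()
    key = label.strip().lower()
    lowered = {k.lower(): v for k, v in band_map.mapping.items()}
    if key not in lowered:
        raise ValueError(
            f"unrecognized emotion {label!r}; expected one of "
            f"{sorted(RECOGNIZED_EMOTIONS)}"
        )
    return lowered[key]
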