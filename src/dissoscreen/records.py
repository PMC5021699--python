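"""The per-phrase training record and its CSV round-trip.

One record per phrase holds the class label and the three channel
values: the signed polarity scalar, the semantic-orientation code, and
the tone band.  The CSV layout uses the conventional column order
``class,polarity,pmi,emotion``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .polarity import polarity_trinary

__all__ = ["TrainingRecord", "CHANNELS", "write_training_csv",
           "read_training_csv"]

TRAINING_COLUMNS = ["class", "polarity", "pmi", "emotion"]


@dataclass(frozen=True)
class TrainingRecord:
    """Class label plus the three channel values for one phrase."""

    class_label: str
    polarity: int
    so_code: int
    tone_code: int

    def __post_init__(self) -> None:
        if not (1 <= abs(self.polarity) <= 5):
            raise ValueError(
                f"polarity must be in [-5,-1] or [1,5], got {self.polarity}")
        if self.so_code not in (-1, 0, 1):
            raise ValueError(f"so_code must be -1/0/1, got {self.so_code}")
        if self.tone_code not in (-1, 0, 1):
            raise ValueError(f"tone_code must be -1/0/1, got {self.tone_code}")


# trinary level extractors for the three channels; polarity collapses
# through its tie convention (+1 == neutral band)
CHANNELS: dict[str, Callable[[TrainingRecord], int]] = {
    "polarity_sign": lambda r: polarity_trinary(r.polarity),
    "so_code": lambda r: r.so_code,
    "tone_code": lambda r: r.tone_code,
}


def write_training_csv(records: Iterable[TrainingRecord],
                       path: str | Path) -> None:
    """Write records as ``class,polarity,pmi,emotion`` CSV."""
    df = pd.DataFrame(
        [(r.class_label, r.polarity, r.so_code, r.tone_code)
         for r in records],
        columns=TRAINING_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_training_csv(path: str | Path) -> list[TrainingRecord]:
    """Read a training CSV back into records (exact round-trip)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAINING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        TrainingRecord(str(row["class"]), int(row["polarity"]),
                       int(row["pmi"]), int(row["emotion"]))
        for _, row in df.iterrows()
    ]
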