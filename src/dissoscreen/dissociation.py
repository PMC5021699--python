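"""Chi-square association between channels, per patient group.

The screening hypothesis is that in cognitively healthy speakers the
text channels (polarity, semantic orientation) and the tone-of-voice
channel agree — they are statistically associated — while in impaired
speakers they decouple (dissociate).  This module quantifies that with
Pearson chi-square tests of independence on channel-pair contingency
tables within each group, plus a per-phrase concordance rate, and
assembles both into a per-group report.

By default the text channel of each pair is collapsed to its sign
(neutral band dropped), giving 2 x 3 tables with 2 degrees of freedom;
a flag keeps the full trinary x trinary (df 4) layout instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .records import CHANNELS, TrainingRecord

__all__ = ["ContingencyResult", "DissociationReport", "channel_association",
           "concordance_rate", "dissociation_report", "CHANNEL_PAIRS"]

# the two text-vs-tone pairs the screening procedure reports per group
CHANNEL_PAIRS = [("polarity_sign", "tone_code"), ("so_code", "tone_code")]


@dataclass(frozen=True)
class ContingencyResult:
    """A chi-square test of independence and its underlying table."""

    table: np.ndarray
    row_levels: tuple[int, ...]
    col_levels: tuple[int, ...]
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        r, c = self.table.shape
        assert self.df == (r - 1) * (c - 1)
        assert (self.table >= 0).all()
        assert 0.0 <= self.p_value <= 1.0

    def to_dict(self) -> dict:
        return {
            "table": self.table.astype(int).tolist(),
            "row_levels": list(self.row_levels),
            "col_levels": list(self.col_levels),
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
        }


def _contingency(a: np.ndarray, b: np.ndarray) -> ContingencyResult:
    row_levels = tuple(sorted(set(a.tolist())))
    col_levels = tuple(sorted(set(b.tolist())))
    if len(row_levels) < 2 or len(col_levels) < 2:
        raise ValueError(
            "degenerate contingency table: each channel needs at least two "
            f"observed levels (rows {row_levels}, cols {col_levels})"
        )
    table = np.zeros((len(row_levels), len(col_levels)), dtype=int)
    for i, ra in enumerate(row_levels):
        for j, cb in enumerate(col_levels):
            table[i, j] = int(np.sum((a == ra) & (b == cb)))
    res = sstats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            "chi-square approximation may be unreliable: some expected "
            "cell counts are below 5",
            stacklevel=3,
        )
    return ContingencyResult(table, row_levels, col_levels,
                             float(res.statistic), int(res.dof),
                             float(res.pvalue))


def channel_association(
    records: Sequence[TrainingRecord],
    group: str,
    channel_a: str,
    channel_b: str,
    collapse: bool = True,
) -> ContingencyResult:
    """Chi-square independence test between two channels within a group.

    ``channel_a``/``channel_b`` are among ``polarity_sign``, ``so_code``
    and ``tone_code``.  With ``collapse`` (default), channel A is
    binarized by sign and its neutral phrases are dropped, so a fully
    observed pair yields a 2 x 3 table with 2 degrees of freedom.
    """
    for name in (channel_a, channel_b):
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}; "
                             f"expected one of {sorted(CHANNELS)}")
    subset = [r for r in records if r.class_label == group]
    if not subset:
        raise ValueError(f"no records for group {group!r}")
    a = np.array([CHANNELS[channel_a](r) for r in subset])
    b = np.array([CHANNELS[channel_b](r) for r in subset])
    if collapse:
        keep = a != 0
        a, b = a[keep], b[keep]
        if a.size == 0:
            raise ValueError(
                f"channel {channel_a!r} is entirely neutral in group "
                f"{group!r} after collapsing"
            )
    return _contingency(a, b)


def concordance_rate(records: Sequence[TrainingRecord]) -> float:
    """Fraction of phrases whose three channels agree.

    A phrase is concordant when the polarity band, the semantic
    orientation code and the tone band are all the same nonzero sign,
    or all neutral.
    """
    if not records:
        raise ValueError("concordance_rate requires at least one record")
    n_conc = 0
    for r in records:
        levels = (CHANNELS["polarity_sign"](r), r.so_code, r.tone_code)
        if levels[0] == levels[1] == levels[2]:
            n_conc += 1
    return n_conc / len(records)


@dataclass
class DissociationReport:
    """Per-group channel-pair chi-square results and concordance rates.

    ``per_group[group][pair]`` maps a channel pair (joined with ``:``)
    to its :class:`ContingencyResult`; ``channel_vs_class`` holds the
    complementary tests of each channel against the class label (only
    meaningful with two or more groups).
    """

    per_group: dict[str, dict[str, ContingencyResult]]
    concordance: dict[str, float]
    group_sizes: dict[str, int]
    channel_vs_class: dict[str, ContingencyResult] = field(
        default_factory=dict)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "group_sizes": dict(self.group_sizes),
            "concordance": {g: float(v) for g, v in self.concordance.items()},
            "per_group": {
                g: {pair: res.to_dict() for pair, res in pairs.items()}
                for g, pairs in self.per_group.items()
            },
            "channel_vs_class": {
                ch: res.to_dict() for ch, res in self.channel_vs_class.items()
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        """Compact per-group p-value table (one row per group)."""
        pairs = sorted({p for d in self.per_group.values() for p in d})
        width = max([len(p) for p in pairs] + [12])
        head = "group".ljust(12) + "".join(p.rjust(width + 2) for p in pairs)
        head += "concordance".rjust(14)
        lines = [head]
        for g in sorted(self.per_group):
            row = g.ljust(12)
            for p in pairs:
                res = self.per_group[g].get(p)
                row += (f"{res.p_value:.3g}".rjust(width + 2)
                        if res else "-".rjust(width + 2))
            row += f"{self.concordance[g]:.3f}".rjust(14)
            lines.append(row)
        return "\n".join(lines)


def dissociation_report(
    records: Sequence[TrainingRecord],
    alpha: float = 0.05,
    collapse: bool = True,
) -> DissociationReport:
    """Run every per-group channel-pair test and summarize.

    For each group the two text-vs-tone pairs are tested; with at least
    two groups, each channel is additionally tested against the class
    label.  Degenerate tables raise, as from
    :func:`channel_association`.
    """
    if not records:
        raise ValueError("dissociation_report requires records")
    groups = sorted({r.class_label for r in records})
    per_group: dict[str, dict[str, ContingencyResult]] = {}
    concordance: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for g in groups:
        subset = [r for r in records if r.class_label == g]
        sizes[g] = len(subset)
        concordance[g] = concordance_rate(subset)
        per_group[g] = {
            f"{a}:{b}": channel_association(records, g, a, b,
                                            collapse=collapse)
            for a, b in CHANNEL_PAIRS
        }
    channel_vs_class: dict[str, ContingencyResult] = {}
    if len(groups) >= 2:
        group_idx = {g: i for i, g in enumerate(groups)}
        cls = np.array([group_idx[r.class_label] for r in records])
        for name, extract in CHANNELS.items():
            vals = np.array([extract(r) for r in records])
            channel_vs_class[name] = _contingency(vals, cls)
    return DissociationReport(per_group, concordance, sizes,
                              channel_vs_class, alpha)
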