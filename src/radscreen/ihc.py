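"""Semiquantitative gamma-H2AX immunohistochemistry scoring.

Staining extent per spheroid region (center, margin, periphery) is binned
into a plus-sign category — no expression (-), 1-25% of cells (+), 26-50%
(++), 51-75% (+++), 76-100% (++++) — and staining intensity is graded 1
(low) to 4 (very high). The weighted score adds the plus count to the
intensity; a region with no expression carries no intensity and scores 0, so
the attainable range is {0} union [2, 8].

Inputs are human- or tool-supplied extent/intensity readings; image
segmentation is out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Region",
    "IhcObservation",
    "IhcScore",
    "plus_category",
    "plus_notation",
    "weighted_score",
    "score_observation",
    "score_ihc_table",
]

PLUS_BREAKPOINTS = (0.0, 25.0, 50.0, 75.0)


class Region(str, enum.Enum):
    CENTER = "center"
    MARGIN = "margin"  # between the center and periphery
    PERIPHERY = "periphery"


@dataclass(frozen=True)
class IhcObservation:
    sample: str
    region: Region
    percent_positive: float  # 0-100
    intensity: int  # 1-4
    n_spheroids: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError(f"percent_positive must be in [0, 100], got {self.percent_positive}")
        if self.intensity not in (1, 2, 3, 4):
            raise ValueError(f"intensity must be 1-4, got {self.intensity}")
        if self.n_spheroids < 1:
            raise ValueError("n_spheroids must be >= 1")


@dataclass(frozen=True)
class IhcScore:
    plus_count: int  # 0-4
    intensity: int  # 1-4
    weighted: int  # 0, or plus_count + intensity in [2, 8]


def plus_category(percent_positive: float) -> int:
    """Map percent of positive cells to the plus-sign count.

    0 -> 0 (-); (0, 25] -> 1 (+); (25, 50] -> 2 (++); (50, 75] -> 3 (+++);
    (75, 100] -> 4 (++++). Half-open bins reproduce the integer-percent
    convention (1-25%, 26-50%, ...) exactly at integer inputs.
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError(f"percent_positive must be in [0, 100], got {percent_positive}")
    count = 0
    for edge in PLUS_BREAKPOINTS:
        if percent_positive > edge:
            count += 1
    return count


def plus_notation(plus_count: int) -> str:
    if plus_count not in (0, 1, 2, 3, 4):
        raise ValueError(f"plus_count must be 0-4, got {plus_count}")
    return "-" if plus_count == 0 else "+" * plus_count


def weighted_score(plus_count: int, intensity: int) -> int:
    """Plus count added to the intensity grade; 0 when there is no
    expression (a region without staining has no intensity)."""
    if plus_count not in (0, 1, 2, 3, 4):
        raise ValueError(f"plus_count must be 0-4, got {plus_count}")
    if intensity not in (1, 2, 3, 4):
        raise ValueError(f"intensity must be 1-4, got {intensity}")
    if plus_count == 0:
        return 0
    return plus_count + intensity


def score_observation(obs: IhcObservation) -> IhcScore:
    count = plus_category(obs.percent_positive)
    return IhcScore(
        plus_count=count,
        intensity=obs.intensity,
        weighted=weighted_score(count, obs.intensity),
    )


def score_ihc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a table with columns sample, region, percent_positive, intensity.

    Returns the input annotated with plus notation and the weighted score,
    one row per (sample, region) observation.
    """
    required = {"sample", "region", "percent_positive", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    scores = [
        score_observation(
            IhcObservation(
                sample=str(row.sample),
                region=Region(row.region),
                percent_positive=float(row.percent_positive),
                intensity=int(row.intensity),
            )
        )
        for row in table.itertuples(index=False)
    ]
    out["plus_count"] = [s.plus_count for s in scores]
    out["extent"] = [plus_notation(s.plus_count) for s in scores]
    out["weighted_score"] = [s.weighted for s in scores]
    return out
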