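"""Appropriateness classification of panel rating vectors.

The 9-point scale is split into three sections (tertiles): 1-3
(inappropriate), 4-6 (uncertain) and 7-9 (appropriate).  For a 16-member
panel the standard decision rules are:

* **agreement** — at least 12 of the 16 ratings fall in the same section;
* **disagreement** — at least 5 panellists rate in section 1-3 *and* at
  least 5 rate in section 7-9;
* **category** — *appropriate* if the median rating lies in 7-9 without
  disagreement, *inappropriate* if it lies in 1-3 without disagreement,
  otherwise *uncertain*.

For even panels the median is the midpoint of the two central order
statistics and may be a half-integer; a median such as 3.5 or 6.5 lies in
no section and therefore classifies as uncertain.  Thresholds scale to
other panel sizes as ``A = ceil(0.75 P)`` and ``D = max(2, round(0.3125 P))``
capped at P (the 12/16 and 5/16 fractions), and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ratings_io import RatingTable, rating_vectors
from .scenario_space import ScenarioSpace

CATEGORIES = ("inappropriate", "uncertain", "appropriate")
DEFAULT_BANDS = ((1, 3), (4, 6), (7, 9))  # (low, mid, high), inclusive


def default_agreement_min(panel_size: int) -> int:
    return math.ceil(0.75 * panel_size)


def default_disagreement_min(panel_size: int) -> int:
    # 5/16 fraction, floored at 2, capped at the panel size for tiny panels
    return min(panel_size, max(2, round(0.3125 * panel_size)))


@dataclass(frozen=True)
class PanelConfig:
    """Panel size and the agreement/disagreement thresholds."""

    panel_size: int = 16
    agreement_min: int | None = None
    disagreement_min: int | None = None
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.agreement_min is None:
            object.__setattr__(
                self, "agreement_min", default_agreement_min(self.panel_size)
            )
        if self.disagreement_min is None:
            object.__setattr__(
                self, "disagreement_min", default_disagreement_min(self.panel_size)
            )
        if not (1 <= self.agreement_min <= self.panel_size):
            raise ValueError("agreement_min must be in 1..panel_size")
        if not (1 <= self.disagreement_min <= self.panel_size):
            raise ValueError("disagreement_min must be in 1..panel_size")
        covered = [x for lo, hi in self.bands for x in range(lo, hi + 1)]
        if len(self.bands) != 3 or covered != list(range(1, 10)):
            raise ValueError("bands must be three inclusive intervals partitioning 1..9")

    @property
    def low_band(self) -> tuple[int, int]:
        return self.bands[0]

    @property
    def high_band(self) -> tuple[int, int]:
        return self.bands[2]


@dataclass(frozen=True)
class ClassificationResult:
    median: float
    agreement: bool
    disagreement: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _check_vector(v: Sequence[int], cfg: PanelConfig | None = None) -> list[int]:
    vals = [int(x) for x in v]
    if not vals:
        raise ValueError("rating vector is empty")
    if any(x < 1 or x > 9 for x in vals):
        raise ValueError("ratings must lie in 1..9")
    if cfg is not None and len(vals) != cfg.panel_size:
        raise ValueError(
            f"vector length {len(vals)} != panel size {cfg.panel_size}"
        )
    return vals


def median_rating(v: Sequence[int]) -> float:
    """Order-statistic median; midpoint of the central pair for even panels."""
    vals = sorted(_check_vector(v))
    n = len(vals)
    if n % 2:
        return float(vals[n // 2])
    return (vals[n // 2 - 1] + vals[n // 2]) / 2.0


def has_agreement(v: Sequence[int], cfg: PanelConfig) -> bool:
    """True iff some section contains at least ``agreement_min`` ratings."""
    vals = _check_vector(v, cfg)
    counts = [sum(lo <= x <= hi for x in vals) for lo, hi in cfg.bands]
    return max(counts) >= cfg.agreement_min


def has_disagreement(v: Sequence[int], cfg: PanelConfig) -> bool:
    """True iff both extreme sections hold at least ``disagreement_min`` ratings."""
    vals = _check_vector(v, cfg)
    lo_lo, lo_hi = cfg.low_band
    hi_lo, hi_hi = cfg.high_band
    n_low = sum(lo_lo <= x <= lo_hi for x in vals)
    n_high = sum(hi_lo <= x <= hi_hi for x in vals)
    return n_low >= cfg.disagreement_min and n_high >= cfg.disagreement_min


def classify(v: Sequence[int], cfg: PanelConfig) -> ClassificationResult:
    """Median, agreement/disagreement flags and category for one vector."""
    vals = _check_vector(v, cfg)
    med = median_rating(vals)
    agree = has_agreement(vals, cfg)
    disagree = has_disagreement(vals, cfg)
    lo_lo, lo_hi = cfg.low_band
    hi_lo, hi_hi = cfg.high_band
    if hi_lo <= med <= hi_hi and not disagree:
        category = "appropriate"
    elif lo_lo <= med <= lo_hi and not disagree:
        category = "inappropriate"
    else:
        category = "uncertain"
    return ClassificationResult(med, agree, disagree, category)


def classify_all(
    table_or_vectors: RatingTable | Mapping[tuple[str, str], Sequence[int]],
    cfg: PanelConfig | None = None,
    space: ScenarioSpace | None = None,
    round_no: int | None = None,
) -> dict[tuple[str, str], ClassificationResult]:
    """Classify every indication of a complete table (or vector mapping)."""
    if isinstance(table_or_vectors, RatingTable):
        vectors = rating_vectors(table_or_vectors, space=space, round_no=round_no)
        if cfg is None:
            cfg = PanelConfig(panel_size=table_or_vectors.panel_size)
    else:
        vectors = dict(table_or_vectors)
        if cfg is None:
            sizes = {len(v) for v in vectors.values()}
            if len(sizes) != 1:
                raise ValueError("mixed vector lengths; pass an explicit PanelConfig")
            cfg = PanelConfig(panel_size=sizes.pop())
    return {key: classify(v, cfg) for key, v in vectors.items()}


def results_to_frame(
    results: Mapping[tuple[str, str], ClassificationResult]
) -> pd.DataFrame:
    """Flat frame: scenario_id, treatment, median, agreement, disagreement, category."""
    rows = [
        (sid, t, r.median, r.agreement, r.disagreement, r.category)
        for (sid, t), r in results.items()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scenario_id", "treatment", "median", "agreement", "disagreement", "category",
        ],
    )


def results_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], ClassificationResult]:
    out = {}
    for row in frame.itertuples(index=False):
        out[(row.scenario_id, row.treatment)] = ClassificationResult(
            float(row.median), bool(row.agreement), bool(row.disagreement), row.category
        )
    return out
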