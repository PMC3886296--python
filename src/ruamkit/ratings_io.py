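"""Reading, validating and writing panel-rating tables.

Ratings travel in a long format, one row per (rater, scenario, treatment,
round), with integer ratings on the 9-point appropriateness scale
(1 = inappropriate, 5 = uncertain, 9 = appropriate).  The canonical CSV
schema is::

    rater_id,scenario_id,treatment,rating,round

Missing ratings are a hard error when per-indication vectors are
assembled: panel analyses assume every voting panellist rated every
indication, and no imputation rule is defined for this kind of study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scenario_space import Indication, ScenarioSpace

CSV_COLUMNS = ["rater_id", "scenario_id", "treatment", "rating", "round"]


class RatingValidationError(ValueError):
    """A rating record violates the schema or the scenario space."""


class CompletenessError(ValueError):
    """The table does not contain one rating per rater per indication."""


@dataclass(frozen=True)
class RatingRecord:
    rater_id: str
    scenario_id: str
    treatment: str
    rating: int
    round: int = 2

    def __post_init__(self) -> None:
        if not (isinstance(self.rating, (int, np.integer)) and 1 <= self.rating <= 9):
            raise RatingValidationError(
                f"rating must be an integer in 1..9, got {self.rating!r} "
                f"(rater {self.rater_id!r}, scenario {self.scenario_id!r}, "
                f"treatment {self.treatment!r})"
            )
        if self.round < 1:
            raise RatingValidationError(f"round must be >= 1, got {self.round}")


@dataclass
class RatingTable:
    """A validated long-format table of panel ratings.

    ``panel`` fixes the rater order used when rating vectors are
    assembled; by default it is the sorted set of rater ids present.
    """

    frame: pd.DataFrame
    panel: list[str]
    space: ScenarioSpace | None = field(default=None, compare=False)

    @property
    def panel_size(self) -> int:
        return len(self.panel)

    @property
    def rounds(self) -> list[int]:
        return sorted(self.frame["round"].unique().tolist())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingTable):
            return NotImplemented
        return self.panel == other.panel and _canonical(self.frame).equals(
            _canonical(other.frame)
        )


def _canonical(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame[CSV_COLUMNS].astype(
        {"rater_id": str, "scenario_id": str, "treatment": str, "rating": int, "round": int}
    )
    return out.sort_values(CSV_COLUMNS, kind="mergesort").reset_index(drop=True)


def make_table(
    records: Iterable[RatingRecord] | pd.DataFrame,
    space: ScenarioSpace | None = None,
    panel: Sequence[str] | None = None,
) -> RatingTable:
    """Assemble and validate a :class:`RatingTable` from records or a frame."""
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise RatingValidationError(f"missing columns: {missing}")
    else:
        rows = [
            (r.rater_id, r.scenario_id, r.treatment, r.rating, r.round)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    if frame.empty:
        frame = pd.DataFrame(columns=CSV_COLUMNS)
    frame = _validate_frame(frame, space)
    if panel is None:
        inferred = sorted(frame["rater_id"].unique().tolist())
    else:
        inferred = list(panel)
        unknown = sorted(set(frame["rater_id"]) - set(inferred))
        if unknown:
            raise RatingValidationError(
                f"records from raters outside the declared panel: {unknown}"
            )
    return RatingTable(frame=_canonical(frame), panel=inferred, space=space)


def _validate_frame(frame: pd.DataFrame, space: ScenarioSpace | None) -> pd.DataFrame:
    frame = frame[CSV_COLUMNS].copy()
    if len(frame):
        rating_num = pd.to_numeric(frame["rating"], errors="coerce")
        bad = rating_num.isna() | (rating_num != np.floor(rating_num))
        bad |= (rating_num < 1) | (rating_num > 9)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = frame.iloc[i]
            raise RatingValidationError(
                f"row {i}: rating must be an integer in 1..9, got "
                f"{row['rating']!r} (rater {row['rater_id']!r}, "
                f"scenario {row['scenario_id']!r}, treatment {row['treatment']!r})"
            )
        frame["rating"] = rating_num.astype(int)
        frame["round"] = pd.to_numeric(frame["round"], errors="raise").astype(int)
        frame["rater_id"] = frame["rater_id"].astype(str)
        frame["scenario_id"] = frame["scenario_id"].astype(str)
        frame["treatment"] = frame["treatment"].astype(str)
    else:
        frame = frame.astype(
            {"rater_id": str, "scenario_id": str, "treatment": str}
        )
        frame["rating"] = frame["rating"].astype(int) if len(frame) else pd.Series(dtype=int)
        frame["round"] = pd.Series(dtype=int)

    dup = frame.duplicated(subset=["rater_id", "scenario_id", "treatment", "round"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        row = frame.iloc[i]
        raise RatingValidationError(
            f"duplicate rating key: rater {row['rater_id']!r}, scenario "
            f"{row['scenario_id']!r}, treatment {row['treatment']!r}, round {row['round']}"
        )

    if space is not None and len(frame):
        valid_keys = {ind.key for ind in space.enumerate_indications()}
        keys = list(zip(frame["scenario_id"], frame["treatment"]))
        bad_rows = [i for i, k in enumerate(keys) if k not in valid_keys]
        if bad_rows:
            row = frame.iloc[bad_rows[0]]
            raise RatingValidationError(
                f"row {bad_rows[0]}: unknown indication (scenario "
                f"{row['scenario_id']!r}, treatment {row['treatment']!r}) "
                f"for the given space"
            )
    return frame


# -- I/O -----------------------------------------------------------------


def read_ratings(
    path: str | Path,
    space: ScenarioSpace | None = None,
    panel: Sequence[str] | None = None,
) -> RatingTable:
    """Read a ratings CSV (or JSON list of records) and validate it."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        frame = pd.DataFrame(data, columns=CSV_COLUMNS)
    else:
        frame = pd.read_csv(path, dtype=str)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise RatingValidationError(
                f"{path.name}: missing columns {missing}; expected {CSV_COLUMNS}"
            )
    if frame.empty:
        frame = pd.DataFrame(columns=CSV_COLUMNS)
    return make_table(frame, space=space, panel=panel)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    """Write a table to CSV (canonical row and column order) or JSON."""
    path = Path(path)
    frame = _canonical(table.frame)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2) + "\n",
            encoding="utf-8",
        )
    else:
        frame.to_csv(path, index=False, lineterminator="\n")


# -- vector assembly -----------------------------------------------------


def completeness_gaps(
    table: RatingTable, space: ScenarioSpace, round_no: int
) -> list[tuple[str, tuple[str, str]]]:
    """(rater, indication-key) pairs missing from the given round."""
    sub = table.frame[table.frame["round"] == round_no]
    have = set(zip(sub["rater_id"], sub["scenario_id"], sub["treatment"]))
    gaps = []
    for ind in space.enumerate_indications():
        sid, t = ind.key
        for rater in table.panel:
            if (rater, sid, t) not in have:
                gaps.append((rater, (sid, t)))
    return gaps


def rating_vectors(
    table: RatingTable,
    space: ScenarioSpace | None = None,
    round_no: int | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """One integer vector per indication, raters in panel order.

    Raises :class:`CompletenessError` listing the first gaps if any
    (rater, indication) rating is absent.
    """
    space = space if space is not None else table.space
    if space is None:
        raise ValueError("a scenario space is required to assemble vectors")
    if round_no is None:
        rounds = table.rounds
        if len(rounds) != 1:
            raise ValueError(
                f"table contains rounds {rounds}; specify round_no explicitly"
            )
        round_no = rounds[0]
    if not table.panel:
        raise CompletenessError("table has an empty panel; no ratings present")
    gaps = completeness_gaps(table, space, round_no)
    if gaps:
        shown = ", ".join(f"rater {r!r} @ {k}" for r, k in gaps[:5])
        more = "" if len(gaps) <= 5 else f" (+{len(gaps) - 5} more)"
        raise CompletenessError(
            f"{len(gaps)} missing rating(s) in round {round_no}: {shown}{more}"
        )
    sub = table.frame[table.frame["round"] == round_no]
    rater_pos = {r: i for i, r in enumerate(table.panel)}
    vectors: dict[tuple[str, str], np.ndarray] = {}
    for ind in space.enumerate_indications():
        vectors[ind.key] = np.empty(len(table.panel), dtype=int)
    for rater, sid, t, rating in zip(
        sub["rater_id"], sub["scenario_id"], sub["treatment"], sub["rating"]
    ):
        vectors[(sid, t)][rater_pos[rater]] = rating
    return vectors


def records_from_arrays(
    indications: Sequence[Indication] | Sequence[tuple[str, str]],
    ratings: np.ndarray,
    panel: Sequence[str],
    round_no: int = 2,
) -> pd.DataFrame:
    """Long-format frame from an (n_indications, P) integer array."""
    ratings = np.asarray(ratings)
    keys = [
        ind.key if isinstance(ind, Indication) else tuple(ind) for ind in indications
    ]
    if ratings.shape != (len(keys), len(panel)):
        raise ValueError(
            f"ratings shape {ratings.shape} != ({len(keys)}, {len(panel)})"
        )
    rows = {
        "rater_id": np.repeat([str(p) for p in panel], len(keys)),
        "scenario_id": np.tile([k[0] for k in keys], len(panel)),
        "treatment": np.tile([k[1] for k in keys], len(panel)),
        "rating": ratings.T.reshape(-1),
        "round": round_no,
    }
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
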