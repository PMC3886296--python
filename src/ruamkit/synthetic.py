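"""Synthetic panel-rating rounds with planted ground truth.

Real panel ratings from appropriateness studies are rarely deposited, so
every downstream stage here is exercised against simulated rounds whose
true labels are known.  The generative model is deliberately transparent:

* each indication gets a latent appropriateness score θ at the midpoint of
  its planted category's section (appropriate → 8, uncertain → 5,
  inappropriate → 2);
* "split" indications model a polarised panel: a fixed fraction of raters
  scores around an opposed latent value (2 vs 8), which triggers the
  disagreement rule and therefore an uncertain classification;
* each individual rating is ``clamp(round(θ + bias_r + ε), 1, 9)`` with
  rater bias (default 0) and Gaussian noise ε ~ N(0, σ²).

With σ = 0 and no bias the classifier recovers every non-split planted
label exactly; recovery degrades monotonically as σ grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ClassificationResult
from .ratings_io import RatingTable, make_table, records_from_arrays
from .scenario_space import ScenarioSpace

PLANT_KINDS = ("appropriate", "uncertain", "inappropriate", "split")
CATEGORY_CENTERS = {"appropriate": 8.0, "uncertain": 5.0, "inappropriate": 2.0}
SPLIT_CENTERS = (2.0, 8.0)  # (theta, opposed theta')


@dataclass(frozen=True)
class RaterModel:
    """Noise and bias structure of the simulated raters."""

    noise_sd: float = 0.0
    bias: Sequence[float] | float = 0.0
    split_fraction: float = 5.0 / 16.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.split_fraction <= 1.0):
            raise ValueError("split_fraction must lie in [0, 1]")

    def bias_vector(self, panel_size: int) -> np.ndarray:
        if np.isscalar(self.bias):
            return np.full(panel_size, float(self.bias))
        b = np.asarray(self.bias, dtype=float)
        if b.shape != (panel_size,):
            raise ValueError(f"bias must be scalar or length {panel_size}")
        return b


@dataclass(frozen=True)
class PlantedIndication:
    theta: float
    intended_category: str  # the label the classifier should recover
    kind: str  # one of PLANT_KINDS
    theta_alt: float | None = None  # opposed latent for split indications


@dataclass
class PlantedTruth:
    """Latent appropriateness and intended label per indication."""

    entries: dict[tuple[str, str], PlantedIndication]
    space: ScenarioSpace = field(repr=False)

    def kind_counts(self) -> dict[str, int]:
        out = {k: 0 for k in PLANT_KINDS}
        for e in self.entries.values():
            out[e.kind] += 1
        return out


def plant_truth(
    space: ScenarioSpace,
    seed: int,
    category_mix: Sequence[float] = (0.4, 0.3, 0.25, 0.05),
) -> PlantedTruth:
    """Draw a planted category per indication.

    ``category_mix`` gives the proportions of (appropriate, uncertain,
    inappropriate, split) indications and must sum to 1.  Split plants are
    intended to classify as uncertain via the disagreement rule.
    """
    mix = np.asarray(category_mix, dtype=float)
    if mix.shape != (4,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(
            "category_mix must be 4 non-negative proportions summing to 1 "
            "(appropriate, uncertain, inappropriate, split)"
        )
    rng = np.random.default_rng(seed)
    indications = space.enumerate_indications()
    kinds = rng.choice(len(PLANT_KINDS), size=len(indications), p=mix)
    entries = {}
    for ind, ki in zip(indications, kinds):
        kind = PLANT_KINDS[ki]
        if kind == "split":
            entries[ind.key] = PlantedIndication(
                theta=SPLIT_CENTERS[0],
                theta_alt=SPLIT_CENTERS[1],
                intended_category="uncertain",
                kind="split",
            )
        else:
            entries[ind.key] = PlantedIndication(
                theta=CATEGORY_CENTERS[kind], intended_category=kind, kind=kind
            )
    return PlantedTruth(entries=entries, space=space)


def generate_ratings(
    truth: PlantedTruth,
    model: RaterModel,
    panel_size: int = 16,
    seed: int = 0,
    round_no: int = 2,
) -> RatingTable:
    """Simulate one complete rating round.

    Deterministic given (truth, model, panel_size, seed); a single RNG
    stream drives rater assignment for split indications and the Gaussian
    noise.  For split indications exactly ``round(split_fraction * P)``
    raters (chosen at random per indication) score around the opposed
    latent value.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    rng = np.random.default_rng(seed)
    keys = [ind.key for ind in truth.space.enumerate_indications()]
    n = len(keys)
    theta = np.empty((n, panel_size))
    for i, key in enumerate(keys):
        e = truth.entries[key]
        theta[i, :] = e.theta
        if e.kind == "split":
            k = int(round(model.split_fraction * panel_size))
            opposed = rng.permutation(panel_size)[:k]
            theta[i, opposed] = e.theta_alt
    noise = (
        rng.normal(0.0, model.noise_sd, size=(n, panel_size))
        if model.noise_sd > 0
        else np.zeros((n, panel_size))
    )
    raw = theta + model.bias_vector(panel_size)[None, :] + noise
    ratings = np.clip(np.rint(raw), 1, 9).astype(int)
    width = max(2, len(str(panel_size)))
    panel = [f"r{j + 1:0{width}d}" for j in range(panel_size)]
    frame = records_from_arrays(keys, ratings, panel, round_no=round_no)
    return make_table(frame, space=truth.space, panel=panel)


@dataclass(frozen=True)
class RecoveryReport:
    """How well classification recovered the planted labels."""

    confusion: pd.DataFrame  # planted kind (rows) x classified category (cols)
    recovery_rate: float  # percent, all indications
    recovery_rate_non_split: float  # percent, excluding split plants

    def __str__(self) -> str:  # pragma: no cover - convenience
        return (
            f"recovery {self.recovery_rate:.1f}% "
            f"(non-split {self.recovery_rate_non_split:.1f}%)\n{self.confusion}"
        )


def recovery_report(
    truth: PlantedTruth,
    classified: Mapping[tuple[str, str], ClassificationResult],
) -> RecoveryReport:
    """Confusion counts and the fraction of recovered planted labels."""
    if set(truth.entries) != set(classified):
        raise ValueError("truth and classified results cover different indications")
    rows = []
    for key, e in truth.entries.items():
        rows.append((e.kind, e.intended_category, classified[key].category))
    frame = pd.DataFrame(rows, columns=["kind", "intended", "classified"])
    confusion = (
        frame.pivot_table(
            index="kind", columns="classified", aggfunc="size", fill_value=0
        )
        .reindex(index=[k for k in PLANT_KINDS if k in set(frame["kind"])])
    )
    hit = frame["intended"] == frame["classified"]
    recovery = 100.0 * hit.mean()
    non_split = frame["kind"] != "split"
    recovery_ns = 100.0 * hit[non_split].mean() if non_split.any() else float("nan")
    return RecoveryReport(confusion, float(recovery), float(recovery_ns))


def simulate_round(
    space: ScenarioSpace,
    seed: int,
    panel_size: int = 16,
    noise_sd: float = 0.0,
    category_mix: Sequence[float] = (0.4, 0.3, 0.25, 0.05),
    split_fraction: float = 5.0 / 16.0,
    round_no: int = 2,
) -> tuple[PlantedTruth, RatingTable]:
    """Convenience wrapper: plant a truth and generate one round from it.

    Two independent seeds are derived from ``seed`` for the plant and the
    ratings so varying the noise model never reshuffles the plant.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_ratings = ss.spawn(2)
    truth = plant_truth(space, seed=int(s_truth.generate_state(1)[0] % 2**31),
                        category_mix=category_mix)
    model = RaterModel(noise_sd=noise_sd, split_fraction=split_fraction)
    table = generate_ratings(
        truth, model, panel_size=panel_size,
        seed=int(s_ratings.generate_state(1)[0] % 2**31), round_no=round_no,
    )
    return truth, table
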