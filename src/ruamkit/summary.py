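"""Summary analytics over classified indications.

Mirrors the descriptive outputs a panel report presents: the per-treatment
appropriateness distribution (percent inappropriate / uncertain /
appropriate, rows summing to 100), overall agreement and disagreement
rates, per-scenario counts of appropriate options, preferred-option shares,
and a matched-pair discriminativeness score per clinical variable.

The discriminativeness score of a variable is the fraction of
(scenario-pair, treatment) comparisons — over all scenario pairs that
differ in exactly that variable — whose categories differ.  It is a
scale-free operationalisation of the cross-tabulations panels use to ask
which patient characteristics actually move the recommendation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .engine import CATEGORIES, ClassificationResult
from .scenario_space import ScenarioSpace

PREFERRED_RULES = ("highest_median_among_appropriate", "unique_appropriate")


def _check_complete(
    results: Mapping[tuple[str, str], ClassificationResult], space: ScenarioSpace
) -> None:
    expected = {ind.key for ind in space.enumerate_indications()}
    missing = expected - set(results)
    if missing:
        example = sorted(missing)[:3]
        raise ValueError(
            f"results missing {len(missing)} indication(s), e.g. {example}"
        )


def appropriateness_distribution(
    results: Mapping[tuple[str, str], ClassificationResult],
    space: ScenarioSpace,
) -> pd.DataFrame:
    """Percent of scenarios per category, one row per (population, treatment).

    Percentages are exact (unrounded); every row sums to 100.  Use
    :func:`distribution_display` for a whole-percent view.
    """
    _check_complete(results, space)
    rows = []
    for pop in space.populations:
        scenarios = space.enumerate_scenarios(pop)
        n = len(scenarios)
        for t in space.treatment_names(pop):
            counts = {c: 0 for c in CATEGORIES}
            for scen in scenarios:
                counts[results[(scen.id, t)].category] += 1
            # cumulative differences keep the row sum exactly 100.0 in
            # floating point; each entry is the exact percentage to 1 ulp
            p_in = 100.0 * counts["inappropriate"] / n
            p_unc = 100.0 * (counts["inappropriate"] + counts["uncertain"]) / n - p_in
            p_app = 100.0 - p_in - p_unc
            rows.append(
                {
                    "population": pop,
                    "treatment": t,
                    "inappropriate": p_in,
                    "uncertain": p_unc,
                    "appropriate": p_app,
                }
            )
    return pd.DataFrame(rows).set_index(["population", "treatment"])


def distribution_display(distribution: pd.DataFrame) -> pd.DataFrame:
    """Whole-percent rendering of the distribution (internal values stay exact)."""
    return distribution.round(0).astype(int)


def agreement_rate(results: Mapping[tuple[str, str], ClassificationResult]) -> float:
    """Percent of indications with panel agreement."""
    if not results:
        raise ValueError("no classification results")
    return 100.0 * sum(r.agreement for r in results.values()) / len(results)


def disagreement_rate(results: Mapping[tuple[str, str], ClassificationResult]) -> float:
    """Percent of indications with panel disagreement."""
    if not results:
        raise ValueError("no classification results")
    return 100.0 * sum(r.disagreement for r in results.values()) / len(results)


@dataclass(frozen=True)
class ScenarioOptionSummary:
    """Per-scenario counts of appropriate options plus the aggregate shares."""

    counts: dict[str, int]  # scenario_id -> number of appropriate treatments
    share_at_least_one: float  # percent of scenarios
    share_exactly_one: float  # percent of scenarios


def scenario_option_counts(
    results: Mapping[tuple[str, str], ClassificationResult],
    space: ScenarioSpace,
) -> ScenarioOptionSummary:
    _check_complete(results, space)
    counts: dict[str, int] = {}
    for pop in space.populations:
        tnames = space.treatment_names(pop)
        for scen in space.enumerate_scenarios(pop):
            counts[scen.id] = sum(
                results[(scen.id, t)].category == "appropriate" for t in tnames
            )
    n = len(counts)
    at_least = 100.0 * sum(c >= 1 for c in counts.values()) / n
    exactly = 100.0 * sum(c == 1 for c in counts.values()) / n
    return ScenarioOptionSummary(counts, at_least, exactly)


@dataclass(frozen=True)
class PreferredOptionShare:
    """Preferred-option shares per population; ties surfaced, never broken."""

    rule: str
    shares: pd.DataFrame  # index (population, treatment), column share (percent)
    tie_share: dict[str, float]  # population -> percent of scenarios tied
    preferred: dict[str, str | None]  # scenario_id -> treatment, "<tie>" or None


def preferred_option_share(
    results: Mapping[tuple[str, str], ClassificationResult],
    space: ScenarioSpace,
    rule: str = "highest_median_among_appropriate",
) -> PreferredOptionShare:
    """Share of scenarios (per population) in which each treatment is preferred.

    ``highest_median_among_appropriate`` (default): the appropriate
    treatment with the strictly highest median; a tied maximum yields no
    single preferred option and is reported in ``tie_share``.
    ``unique_appropriate``: preferred only when exactly one treatment is
    appropriate.
    """
    if rule not in PREFERRED_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {PREFERRED_RULES}")
    _check_complete(results, space)
    preferred: dict[str, str | None] = {}
    rows = []
    tie_share: dict[str, float] = {}
    for pop in space.populations:
        tnames = space.treatment_names(pop)
        scenarios = space.enumerate_scenarios(pop)
        n = len(scenarios)
        wins = {t: 0 for t in tnames}
        ties = 0
        for scen in scenarios:
            appropriate = [
                t for t in tnames if results[(scen.id, t)].category == "appropriate"
            ]
            choice: str | None
            if rule == "unique_appropriate":
                choice = appropriate[0] if len(appropriate) == 1 else None
            else:
                if not appropriate:
                    choice = None
                else:
                    best = max(results[(scen.id, t)].median for t in appropriate)
                    top = [
                        t for t in appropriate if results[(scen.id, t)].median == best
                    ]
                    if len(top) == 1:
                        choice = top[0]
                    else:
                        choice = "<tie>"
                        ties += 1
            preferred[scen.id] = choice
            if choice is not None and choice != "<tie>":
                wins[choice] += 1
        for t in tnames:
            rows.append(
                {"population": pop, "treatment": t, "share": 100.0 * wins[t] / n}
            )
        tie_share[pop] = 100.0 * ties / n
    shares = pd.DataFrame(rows).set_index(["population", "treatment"])
    return PreferredOptionShare(rule, shares, tie_share, preferred)


def discriminativeness(
    results: Mapping[tuple[str, str], ClassificationResult],
    space: ScenarioSpace,
) -> pd.DataFrame:
    """Matched-pair category-change score per (population, variable).

    For every pair of scenarios differing in exactly one variable and
    every applicable treatment, count whether the two categories differ;
    the score is the differing fraction, in [0, 1].  Variables with a
    single level have no comparable pairs and get a null score.  Rows are
    ranked by descending score within each population.
    """
    _check_complete(results, space)
    rows = []
    for pop in space.populations:
        tnames = space.treatment_names(pop)
        scenarios = space.enumerate_scenarios(pop)
        var_names = [v.name for v in space.variables[pop]]
        for var in var_names:
            others = [w for w in var_names if w != var]
            groups: dict[tuple, list] = {}
            for scen in scenarios:
                a = scen.assignment_dict
                groups.setdefault(tuple(a[w] for w in others), []).append(scen)
            n_pairs = 0
            n_diff = 0
            for members in groups.values():
                for s1, s2 in itertools.combinations(members, 2):
                    for t in tnames:
                        n_pairs += 1
                        if (
                            results[(s1.id, t)].category
                            != results[(s2.id, t)].category
                        ):
                            n_diff += 1
            score = (n_diff / n_pairs) if n_pairs else None
            rows.append(
                {
                    "population": pop,
                    "variable": var,
                    "score": score,
                    "n_comparisons": n_pairs,
                }
            )
    frame = pd.DataFrame(rows)
    frame["rank"] = frame.groupby("population")["score"].rank(
        ascending=False, method="min"
    )
    return frame.set_index(["population", "variable"]).sort_values(
        ["population", "score"], ascending=[True, False]
    )
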