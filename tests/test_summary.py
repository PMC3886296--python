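"""Summary analytics: distributions, rates, option counts, discriminativeness."""

import pytest

import ruamkit as rk
from ruamkit.engine import ClassificationResult


def make_result(category, median=None):
    med = {"appropriate": 8.0, "uncertain": 5.0, "inappropriate": 2.0}[category]
    return ClassificationResult(
        median if median is not None else med, True, False, category
    )


@pytest.fixture(scope="module")
def toy_results(toy_space):
    """Hand-assigned categories on the 6-scenario toy space.

    Categories depend only on variable ``a`` for t1 (a1 -> appropriate,
    a2 -> inappropriate) and are constant appropriate for t2.
    """
    results = {}
    for scen in toy_space.all_scenarios():
        cat = "appropriate" if scen.assignment_dict["a"] == "a1" else "inappropriate"
        results[(scen.id, "t1")] = make_result(cat)
        results[(scen.id, "t2")] = make_result("appropriate")
    return results


class TestDistribution:
    def test_hand_counted_percentages(self, toy_results, toy_space):
        dist = rk.appropriateness_distribution(toy_results, toy_space)
        t1 = dist.loc[("IDA", "t1")]
        assert (t1["inappropriate"], t1["uncertain"], t1["appropriate"]) == (50, 0, 50)
        t2 = dist.loc[("IDA", "t2")]
        assert (t2["inappropriate"], t2["uncertain"], t2["appropriate"]) == (0, 0, 100)

    def test_rows_sum_to_100_exactly(self, classified_round, round2_space):
        _, _, results = classified_round
        dist = rk.appropriateness_distribution(results, round2_space)
        assert (dist.sum(axis=1) == 100.0).all()

    def test_display_rounding_is_integer(self, classified_round, round2_space):
        _, _, results = classified_round
        shown = rk.distribution_display(
            rk.appropriateness_distribution(results, round2_space)
        )
        assert (shown.dtypes == int).all()

    def test_missing_results_error(self, toy_results, toy_space):
        partial = dict(toy_results)
        partial.pop(next(iter(partial)))
        with pytest.raises(ValueError, match="missing"):
            rk.appropriateness_distribution(partial, toy_space)


class TestRates:
    def test_all_agreement(self, toy_results):
        assert rk.agreement_rate(toy_results) == 100.0
        assert rk.disagreement_rate(toy_results) == 0.0

    def test_planted_half_and_half(self):
        results = {}
        for i in range(10):
            agree = i < 5
            results[(f"s{i}", "t")] = ClassificationResult(5.0, agree, False, "uncertain")
        assert rk.agreement_rate(results) == 50.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rk.agreement_rate({})

    def test_flag_sets_disjoint_under_defaults(self, classified_round):
        _, _, results = classified_round
        assert not any(r.agreement and r.disagreement for r in results.values())
        assert 0 <= rk.agreement_rate(results) <= 100
        assert 0 <= rk.disagreement_rate(results) <= 100


class TestOptionCounts:
    def test_hand_counted_toy(self, toy_results, toy_space):
        summary = rk.scenario_option_counts(toy_results, toy_space)
        # a1 scenarios: t1+t2 appropriate (2); a2 scenarios: only t2 (1)
        assert sorted(summary.counts.values()) == [1, 1, 1, 2, 2, 2]
        assert summary.share_at_least_one == 100.0
        assert summary.share_exactly_one == 50.0

    def test_zero_appropriate_counted_in_neither_share(self, toy_space):
        results = {
            (scen.id, t): make_result("inappropriate")
            for scen in toy_space.all_scenarios()
            for t in ("t1", "t2")
        }
        summary = rk.scenario_option_counts(results, toy_space)
        assert summary.share_at_least_one == 0.0
        assert summary.share_exactly_one == 0.0


class TestPreferredOption:
    def test_single_appropriate_preferred_under_both_rules(self, toy_results, toy_space):
        for rule in ("highest_median_among_appropriate", "unique_appropriate"):
            share = rk.preferred_option_share(toy_results, toy_space, rule=rule)
            if rule == "unique_appropriate":
                # a1 scenarios have two appropriate options -> no unique one
                assert share.shares.loc[("IDA", "t2"), "share"] == 50.0
                assert share.shares.loc[("IDA", "t1"), "share"] == 0.0

    def test_highest_median_wins(self, toy_space):
        results = {}
        for scen in toy_space.all_scenarios():
            results[(scen.id, "t1")] = make_result("appropriate", median=8.0)
            results[(scen.id, "t2")] = make_result("appropriate", median=9.0)
        share = rk.preferred_option_share(results, toy_space)
        assert share.shares.loc[("IDA", "t2"), "share"] == 100.0
        assert share.tie_share["IDA"] == 0.0

    def test_ties_surfaced_not_broken(self, toy_space):
        results = {
            (scen.id, t): make_result("appropriate", median=8.0)
            for scen in toy_space.all_scenarios()
            for t in ("t1", "t2")
        }
        share = rk.preferred_option_share(results, toy_space)
        assert share.tie_share["IDA"] == 100.0
        assert (share.shares["share"] == 0).all()
        assert set(share.preferred.values()) == {"<tie>"}

    def test_shares_bounded(self, classified_round, round2_space):
        _, _, results = classified_round
        share = rk.preferred_option_share(results, round2_space)
        for pop in round2_space.populations:
            total = share.shares.xs(pop)["share"].sum() + share.tie_share[pop]
            assert 0 <= total <= 100 + 1e-9

    def test_unknown_rule_errors(self, toy_results, toy_space):
        with pytest.raises(ValueError, match="rule"):
            rk.preferred_option_share(toy_results, toy_space, rule="nope")


class TestDiscriminativeness:
    def test_category_depends_only_on_one_variable(self, toy_results, toy_space):
        report = rk.discriminativeness(toy_results, toy_space)
        # t1 flips with a, t2 never flips: a-pairs differ for half the
        # treatments, b-pairs never differ
        assert report.loc[("IDA", "a"), "score"] == 0.5
        assert report.loc[("IDA", "b"), "score"] == 0.0
        assert report.loc[("IDA", "a"), "rank"] == 1

    def test_constant_categories_score_zero(self, toy_space):
        results = {
            (scen.id, t): make_result("uncertain")
            for scen in toy_space.all_scenarios()
            for t in ("t1", "t2")
        }
        report = rk.discriminativeness(results, toy_space)
        assert (report["score"] == 0).all()

    def test_single_level_variable_undefined(self):
        space = rk.build_scenario_space(
            {
                "version": "one-level",
                "populations": {
                    "NAID": {
                        "variables": [
                            {"name": "fixed", "levels": ["only"]},
                            {"name": "x", "levels": ["x1", "x2"]},
                        ],
                        "treatments": [{"name": "t"}],
                    }
                },
            }
        )
        results = {
            (scen.id, "t"): make_result(
                "appropriate" if scen.assignment_dict["x"] == "x1" else "inappropriate"
            )
            for scen in space.all_scenarios()
        }
        report = rk.discriminativeness(results, space)
        assert report.loc[("NAID", "fixed"), "n_comparisons"] == 0
        assert report.loc[("NAID", "fixed"), "score"] is None or (
            report.loc[("NAID", "fixed"), "score"] != report.loc[("NAID", "fixed"), "score"]
        )
        assert report.loc[("NAID", "x"), "score"] == 1.0

    def test_matches_bruteforce_pair_oracle(self, toy_results, toy_space):
        """Exhaustive pair enumeration oracle on the toy space."""
        import itertools

        report = rk.discriminativeness(toy_results, toy_space)
        scenarios = toy_space.all_scenarios()
        for var in ("a", "b"):
            n_pairs = n_diff = 0
            for s1, s2 in itertools.combinations(scenarios, 2):
                d1, d2 = s1.assignment_dict, s2.assignment_dict
                differing = [k for k in d1 if d1[k] != d2[k]]
                if differing != [var]:
                    continue
                for t in ("t1", "t2"):
                    n_pairs += 1
                    n_diff += (
                        toy_results[(s1.id, t)].category
                        != toy_results[(s2.id, t)].category
                    )
            assert report.loc[("IDA", var), "n_comparisons"] == n_pairs
            assert report.loc[("IDA", var), "score"] == n_diff / n_pairs
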