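"""Rubric scoring, PMC index, ratings, ranking and group summaries."""

import itertools
from decimal import ROUND_HALF_UP, Decimal

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmcpolicy import (
    EvaluationSchema,
    FirstLevelVariable,
    GroupLabel,
    PMCResult,
    PolicyCoding,
    SecondLevelCriterion,
    classify_rating,
    compute_pmc_index,
    evaluate_policies,
    evaluate_policy,
    rank_policies,
    round_half_up,
    score_first_level,
    summarize_group,
    weighted_overall_mean,
)
from pmcpolicy.pmc_scoring import GroupSummary

G11 = GroupLabel(batch=1, phase=1)


def small_schema(*counts: int, leaf: bool = False) -> EvaluationSchema:
    """Reduced rubric with the given per-variable criterion counts."""
    variables = [
        FirstLevelVariable(
            id=f"X{i + 1}",
            criteria=tuple(
                SecondLevelCriterion(id=f"X{i + 1}-{j + 1}") for j in range(n)
            ),
        )
        for i, n in enumerate(counts)
    ]
    if leaf:
        variables.append(FirstLevelVariable(id=f"X{len(counts) + 1}", criteria=()))
    return EvaluationSchema(variables=tuple(variables))


def naive_variable_mean(bits: list[int]) -> float:
    """Independent oracle: per-criterion summation then exact decimal rounding."""
    total = 0
    for b in bits:
        total += b
    return float(
        (Decimal(total) / Decimal(len(bits))).quantize(
            Decimal("0.001"), rounding=ROUND_HALF_UP
        )
    )


class TestScoreFirstLevel:
    def test_five_of_six_criteria(self, schema):
        values = {c: 0 for c in schema.criterion_ids}
        for j in range(1, 6):
            values[f"X1-{j}"] = 1
        coding = PolicyCoding(
            policy_id=1, group=G11, values=values, leaf_values={"X10": 1}
        )
        assert score_first_level(coding, schema)["X1"] == 0.833

    def test_all_zero(self, schema):
        coding = PolicyCoding(
            policy_id=1,
            group=G11,
            values={c: 0 for c in schema.criterion_ids},
            leaf_values={"X10": 0},
        )
        scores = score_first_level(coding, schema)
        assert all(s == 0.0 for s in scores.values())

    @given(bits=st.lists(st.integers(0, 1), min_size=7, max_size=7))
    def test_matches_naive_mean_oracle(self, bits):
        sch = small_schema(7)
        coding = PolicyCoding(
            policy_id=1,
            group=G11,
            values={f"X1-{j + 1}": b for j, b in enumerate(bits)},
        )
        assert score_first_level(coding, sch)["X1"] == naive_variable_mean(bits)

    def test_leaf_variable_passthrough(self, schema):
        coding = PolicyCoding(
            policy_id=1,
            group=G11,
            values={c: 1 for c in schema.criterion_ids},
            leaf_values={"X10": 0},
        )
        assert score_first_level(coding, schema)["X10"] == 0.0


class TestComputeIndex:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((0.833, 0.250, 0.750, 0.857, 1, 1, 0.857, 1, 1, 1), 8.547),
            ((0.500, 0.250, 0.500, 0.571, 1, 1, 0.143, 0.400, 1, 1), 6.364),
            ((1,) * 10, 10.000),
        ],
    )
    def test_worked_examples(self, scores, expected, schema):
        score_map = {f"X{i + 1}": s for i, s in enumerate(scores)}
        assert compute_pmc_index(score_map, schema) == expected

    def test_missing_variable_rejected(self, schema):
        with pytest.raises(KeyError, match="X10"):
            compute_pmc_index({f"X{i}": 1.0 for i in range(1, 10)}, schema)


class TestClassifyRating:
    @pytest.mark.parametrize(
        "pmc, rating",
        [
            (9.107, "perfect"),
            (9.000, "perfect"),
            (8.999, "good"),
            (7.000, "good"),
            (6.364, "acceptable"),
            (5.000, "acceptable"),
            (4.564, "poor"),
            (0.0, "poor"),
            (10.0, "perfect"),
        ],
    )
    def test_thresholds(self, pmc, rating):
        assert classify_rating(pmc) == rating

    @pytest.mark.parametrize("bad", [-0.1, 10.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_rating(bad)


class TestRanking:
    def test_fixture_subset_order_matches_printed_ranks(self, fixture_results, fixture_set):
        printed_order = list(fixture_set.table6.sort_values("ranking")["policy_id"])
        computed_order = [
            r.policy_id for r in sorted(fixture_results, key=lambda r: r.rank)
        ]
        assert computed_order == printed_order
        by_id = {r.policy_id: r for r in fixture_results}
        assert by_id[20].rank == 1
        assert by_id[16].rank == 2

    def test_single_policy(self):
        r = PMCResult(policy_id=3, group=G11, variable_scores={}, pmc_index=5.0, rating="acceptable")
        assert rank_policies([r])[0].rank == 1

    def test_ties_break_by_policy_id(self):
        results = [
            PMCResult(policy_id=9, group=G11, variable_scores={}, pmc_index=7.0, rating="good"),
            PMCResult(policy_id=2, group=G11, variable_scores={}, pmc_index=7.0, rating="good"),
        ]
        ranked = rank_policies(results)
        assert [(r.policy_id, r.rank) for r in ranked] == [(2, 1), (9, 2)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_policies([])

    def test_ranks_contiguous(self, fixture_results):
        assert sorted(r.rank for r in fixture_results) == list(range(1, 16))


class TestGroupSummary:
    def test_first_five_fixture_rows_mean(self, fixture_results):
        subset = [r for r in fixture_results if r.policy_id <= 5]
        summary = summarize_group(subset, G11)
        # hand sum of the printed indices
        expected = round_half_up((8.547 + 7.987 + 7.726 + 8.714 + 6.364) / 5)
        assert summary.mean_pmc == expected
        assert summary.n_policies == 5
        assert sum(summary.rating_counts.values()) == 5

    def test_single_policy_summary_equals_policy(self, fixture_results):
        r = next(x for x in fixture_results if x.policy_id == 1)
        summary = summarize_group([r], r.group)
        assert summary.mean_pmc == r.pmc_index
        assert summary.mean_variable_scores == r.variable_scores
        assert summary.rating_counts["good"] == 1

    def test_wrong_group_rejected(self, fixture_results):
        with pytest.raises(ValueError, match="belong"):
            summarize_group(fixture_results, GroupLabel(batch=1, phase=2))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], G11)


class TestWeightedOverallMean:
    def test_published_group_means(self):
        summaries = [
            GroupSummary(group=None, n_policies=35, mean_pmc=7.683, mean_variable_scores={}),
            GroupSummary(group=None, n_policies=14, mean_pmc=7.577, mean_variable_scores={}),
            GroupSummary(group=None, n_policies=30, mean_pmc=7.781, mean_variable_scores={}),
        ]
        assert weighted_overall_mean(summaries) == 7.701

    def test_single_group_is_identity(self):
        s = GroupSummary(group=None, n_policies=7, mean_pmc=6.5, mean_variable_scores={})
        assert weighted_overall_mean([s]) == 6.5

    def test_equal_means_are_invariant(self):
        summaries = [
            GroupSummary(group=None, n_policies=n, mean_pmc=7.25, mean_variable_scores={})
            for n in (3, 11, 29)
        ]
        assert weighted_overall_mean(summaries) == 7.25

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            weighted_overall_mean([])


class TestProperties:
    def test_oracle_equivalence_exhaustive_small_schema(self):
        """Pipeline index equals naive per-criterion summation for all codings."""
        counts = (5, 4, 3)
        sch = small_schema(*counts)
        crit_ids = sch.criterion_ids
        for bits in itertools.product((0, 1), repeat=sum(counts)):
            coding = PolicyCoding(
                policy_id=1, group=G11, values=dict(zip(crit_ids, bits))
            )
            result = evaluate_policy(coding, sch)
            # independent oracle: slice criteria per variable, naive mean, sum
            offset, oracle = 0, Decimal(0)
            for n in counts:
                oracle += Decimal(
                    repr(naive_variable_mean(list(bits[offset : offset + n])))
                )
                offset += n
            assert result.pmc_index == float(oracle)

    @given(
        bits=st.lists(st.integers(0, 1), min_size=47, max_size=47),
        flip=st.integers(0, 46),
    )
    def test_monotone_under_upward_flips(self, bits, flip, schema):
        """Flipping any second-level value 0 -> 1 never decreases the index."""
        names = schema.criterion_ids + ["X10"]
        base = dict(zip(names, bits))
        flipped = dict(base)
        flipped[names[flip]] = 1

        def make(vals):
            return PolicyCoding(
                policy_id=1,
                group=G11,
                values={k: v for k, v in vals.items() if k != "X10"},
                leaf_values={"X10": vals["X10"]},
            )

        low = evaluate_policy(make(base), schema)
        high = evaluate_policy(make(flipped), schema)
        assert high.pmc_index >= low.pmc_index

    @given(bits=st.lists(st.integers(0, 1), min_size=47, max_size=47))
    def test_range_and_rating_partition(self, bits, schema):
        """Scores in [0,1], index in [0,10], exactly one rating assigned."""
        coding = PolicyCoding(
            policy_id=1,
            group=G11,
            values=dict(zip(schema.criterion_ids, bits[:46])),
            leaf_values={"X10": bits[46]},
        )
        result = evaluate_policy(coding, schema)
        assert all(0.0 <= s <= 1.0 for s in result.variable_scores.values())
        assert 0.0 <= result.pmc_index <= 10.0
        assert result.rating in ("perfect", "good", "acceptable", "poor")

    def test_rating_counts_partition_fixture_set(self, fixture_results):
        summary = summarize_group(fixture_results)
        assert sum(summary.rating_counts.values()) == len(fixture_results)
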