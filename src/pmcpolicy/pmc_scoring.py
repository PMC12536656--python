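"""Policy Modeling Consistency (PMC) index computation.

Each first-level variable X_t scores the mean of its binary second-level
criteria, X_t = (Σ_j X_tj) / T(X_tj); zero-criterion variables take their 0/1
leaf value directly.  Variable scores are rounded half-up to three decimals
*before* summation, and the PMC index is their sum over the ten variables
(range 0–10).  Policies are classified perfect (9–10), good (7–8.999),
acceptable (5–6.999) or poor (below 5), and ranked by descending index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .schema_model import EvaluationSchema, GroupLabel, PolicyCoding

RATINGS = ("perfect", "good", "acceptable", "poor")

#: Lower bound of each rating class; intervals are closed on the left.
RATING_THRESHOLDS = (("perfect", 9.0), ("good", 7.0), ("acceptable", 5.0), ("poor", 0.0))


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PMCResult:
    """Per-policy scores, index, rating and (once ranked) rank."""

    policy_id: int
    group: GroupLabel
    variable_scores: dict[str, float]
    pmc_index: float
    rating: str
    rank: Optional[int] = None


@dataclass
class GroupSummary:
    """Mean index, mean variable scores and rating tallies of one group."""

    group: Optional[GroupLabel]
    n_policies: int
    mean_pmc: float
    mean_variable_scores: dict[str, float]
    rating_counts: dict[str, int] = field(default_factory=dict)


def score_first_level(
    coding: PolicyCoding, schema: EvaluationSchema
) -> dict[str, float]:
    """Score every first-level variable of ``coding`` under ``schema``.

    Criterion-bearing variables score the mean of their binary criteria,
    rounded half-up to 3 decimals; leaf variables return their 0/1 value.
    SUMMARY codings pass their pre-aggregated scores through (re-rounded).
    """
    coding.validate_against(schema)
    if coding.is_summary:
        return {v: round_half_up(s) for v, s in coding.summary_scores.items()}
    scores: dict[str, float] = {}
    for var in schema.variables:
        if var.criteria:
            total = sum(coding.values[c.id] for c in var.criteria)
            exact = Decimal(total) / Decimal(var.n_criteria)
            scores[var.id] = float(
                exact.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
            )
        else:
            scores[var.id] = float(coding.leaf_values[var.id])
    return scores


def compute_pmc_index(
    scores: Mapping[str, float], schema: EvaluationSchema | None = None
) -> float:
    """Sum the (already rounded) first-level scores into the PMC index.

    When ``schema`` is given, the score map must cover its variable set
    exactly.  Reported to three decimals.
    """
    if schema is not None:
        missing = set(schema.variable_ids) - set(scores)
        extra = set(scores) - set(schema.variable_ids)
        if missing or extra:
            raise KeyError(
                f"score map mismatches schema (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
    total = sum(Decimal(repr(s)) for s in scores.values())
    return float(total.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def classify_rating(pmc: float) -> str:
    """Map a PMC index to its rating class (intervals closed on the left)."""
    if not 0.0 <= pmc <= 10.0:
        raise ValueError(f"PMC index {pmc} outside [0, 10]")
    for rating, lower in RATING_THRESHOLDS:
        if pmc >= lower:
            return rating
    raise AssertionError("unreachable")  # pragma: no cover


def evaluate_policy(coding: PolicyCoding, schema: EvaluationSchema) -> PMCResult:
    """Score one policy end to end (no rank until ranked within a set)."""
    scores = score_first_level(coding, schema)
    pmc = compute_pmc_index(scores, schema)
    return PMCResult(
        policy_id=coding.policy_id,
        group=coding.group,
        variable_scores=scores,
        pmc_index=pmc,
        rating=classify_rating(pmc),
    )


def rank_policies(results: Sequence[PMCResult]) -> list[PMCResult]:
    """Assign ranks 1..n by descending index, ties by ascending policy id."""
    if not results:
        raise ValueError("cannot rank an empty result set")
    ordered = sorted(results, key=lambda r: (-r.pmc_index, r.policy_id))
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def evaluate_policies(
    codings: Iterable[PolicyCoding], schema: EvaluationSchema
) -> list[PMCResult]:
    """Score and rank a set of policies; returned in rank order."""
    return rank_policies([evaluate_policy(c, schema) for c in codings])


def summarize_group(
    results: Sequence[PMCResult], group: GroupLabel | None = None
) -> GroupSummary:
    """Arithmetic group means (3 decimals) and rating tallies.

    With ``group`` given, all results must carry that label; otherwise the
    summary spans whatever set was passed (e.g. all 79 policies).
    """
    if not results:
        raise ValueError("cannot summarize an empty group")
    if group is not None:
        stray = [r.policy_id for r in results if r.group != group]
        if stray:
            raise ValueError(f"policies {stray} do not belong to group {group.key}")
    n = len(results)
    mean_pmc = round_half_up(sum(r.pmc_index for r in results) / n)
    var_ids = list(results[0].variable_scores)
    mean_scores = {
        v: round_half_up(sum(r.variable_scores[v] for r in results) / n)
        for v in var_ids
    }
    counts = {rating: 0 for rating in RATINGS}
    for r in results:
        counts[r.rating] += 1
    return GroupSummary(
        group=group,
        n_policies=n,
        mean_pmc=mean_pmc,
        mean_variable_scores=mean_scores,
        rating_counts=counts,
    )


def weighted_overall_mean(summaries: Sequence[GroupSummary]) -> float:
    """Size-weighted mean PMC index across groups, to 3 decimals."""
    total_n = sum(s.n_policies for s in summaries)
    if total_n == 0:
        raise ValueError("no policies across groups")
    weighted = sum(s.n_policies * s.mean_pmc for s in summaries)
    return round_half_up(weighted / total_n)


def results_table(results: Sequence[PMCResult]) -> pd.DataFrame:
    """Results as a table mirroring the printed layout: policy, X1..X10, index, ranking, rating."""
    if not results:
        return pd.DataFrame()
    var_ids = list(results[0].variable_scores)
    rows = []
    for r in sorted(results, key=lambda r: r.policy_id):
        row = {"policy_id": r.policy_id, "batch": r.group.batch, "phase": r.group.phase}
        row.update({v: r.variable_scores[v] for v in var_ids})
        row["pmc_index"] = r.pmc_index
        row["ranking"] = r.rank
        row["rating"] = r.rating
        rows.append(row)
    return pd.DataFrame(rows)


def save_results(results: Sequence[PMCResult], path: str | Path) -> None:
    results_table(results).to_csv(path, index=False)
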