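"""Policy-instrument frequency analysis and rating × category cross-analysis.

Coding units are tallied by sub-tool and category per analysis group, with
percentages against the group's grand total of units.  The two-dimensional
cross-analysis re-partitions the same units by the rating of the policy they
belong to; percentages again use the group grand total (the convention that
reconciles the printed per-rating figures with the per-group tool totals),
and environment/supply and environment/demand usage ratios are reported per
rating class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .pmc_scoring import round_half_up
from .schema_model import GroupLabel, ToolCorpus, ToolTaxonomy

logger = logging.getLogger("pmcpolicy")


def _percentage(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total)


@dataclass
class FrequencyTable:
    """Sub-tool counts and percentages of one group, with category subtotals."""

    group: GroupLabel
    table: pd.DataFrame  # columns: category, sub_tool, frequency, percentage
    category_totals: dict[str, int]
    category_percentages: dict[str, float]
    grand_total: int

    def frequency(self, sub_tool: str) -> int:
        rows = self.table[self.table["sub_tool"] == sub_tool]
        if rows.empty:
            raise KeyError(sub_tool)
        return int(rows["frequency"].iloc[0])

    def percentage(self, sub_tool: str) -> float:
        rows = self.table[self.table["sub_tool"] == sub_tool]
        if rows.empty:
            raise KeyError(sub_tool)
        return float(rows["percentage"].iloc[0])


@dataclass
class CrossTab:
    """Unit counts per (rating, category), percentages of the group total."""

    group: GroupLabel
    frequencies: dict[tuple[str, str], int]  # (rating, category id) -> count
    percentages: dict[tuple[str, str], float]
    group_total: int
    categories: tuple[str, ...] = ("supply", "environment", "demand")
    ratings: tuple[str, ...] = ()


@dataclass(frozen=True)
class RatioSet:
    """Environment-to-supply and environment-to-demand usage ratios.

    A ratio whose denominator count is zero is undefined and reported as
    ``None`` (never infinity).
    """

    env_supply: Optional[float]
    env_demand: Optional[float]


def tabulate_tools(corpus: ToolCorpus, taxonomy: ToolTaxonomy) -> FrequencyTable:
    """Count units per sub-tool; percentages against the group grand total."""
    corpus.validate_against(taxonomy)
    grand = len(corpus)
    if grand == 0:
        logger.warning("empty corpus for group %s: zero frequency table", corpus.group.key)
    counts: dict[str, int] = {t: 0 for t in taxonomy.sub_tools}
    for u in corpus.units:
        counts[u.sub_tool] += 1
    rows = []
    cat_totals: dict[str, int] = {}
    cat_pcts: dict[str, float] = {}
    for cat in taxonomy.categories:
        subtotal = 0
        for tool in cat.sub_tools:
            c = counts[tool]
            subtotal += c
            rows.append(
                {
                    "category": cat.id,
                    "sub_tool": tool,
                    "frequency": c,
                    "percentage": _percentage(c, grand),
                }
            )
        cat_totals[cat.id] = subtotal
        cat_pcts[cat.id] = _percentage(subtotal, grand)
    return FrequencyTable(
        group=corpus.group,
        table=pd.DataFrame(rows),
        category_totals=cat_totals,
        category_percentages=cat_pcts,
        grand_total=grand,
    )


def frequency_table_frame(table: FrequencyTable) -> pd.DataFrame:
    """Printed layout: sub-tool rows plus category subtotal and grand-total rows."""
    parts = []
    for cat in table.category_totals:
        block = table.table[table.table["category"] == cat].copy()
        parts.append(block)
        parts.append(
            pd.DataFrame(
                [
                    {
                        "category": cat,
                        "sub_tool": "Total",
                        "frequency": table.category_totals[cat],
                        "percentage": table.category_percentages[cat],
                    }
                ]
            )
        )
    parts.append(
        pd.DataFrame(
            [
                {
                    "category": "all",
                    "sub_tool": "Total",
                    "frequency": table.grand_total,
                    "percentage": 100.0 if table.grand_total else 0.0,
                }
            ]
        )
    )
    return pd.concat(parts, ignore_index=True)


def save_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    frequency_table_frame(table).to_csv(path, index=False)


def compare_phases(tables: Sequence[FrequencyTable]) -> pd.DataFrame:
    """Side-by-side sub-tool percentages across groups with deltas.

    The delta column is last-group minus first-group percentage per sub-tool.
    All tables must share the same taxonomy (identical sub-tool rows).
    """
    if len(tables) < 2:
        raise ValueError("need at least two frequency tables to compare")
    base_tools = list(tables[0].table["sub_tool"])
    for t in tables[1:]:
        if list(t.table["sub_tool"]) != base_tools:
            raise ValueError("frequency tables built over different taxonomies")
    out = tables[0].table[["category", "sub_tool"]].copy()
    for t in tables:
        out[f"pct_{t.group.key}"] = t.table["percentage"].to_numpy()
    first = out[f"pct_{tables[0].group.key}"]
    last = out[f"pct_{tables[-1].group.key}"]
    out["delta"] = (last - first).map(lambda d: round_half_up(float(d)))
    return out


def cross_tabulate(
    corpus: ToolCorpus,
    ratings: Mapping[int, str],
    group_total: int | None = None,
    taxonomy: ToolTaxonomy | None = None,
) -> CrossTab:
    """Partition a group's units by the rating of their policy.

    ``ratings`` maps every policy id appearing in the corpus to its rating
    class.  Percentages are computed against ``group_total`` (defaulting to
    the corpus size — the group's grand total of coding units).
    """
    if taxonomy is None:
        from .schema_model import default_taxonomy

        taxonomy = default_taxonomy()
    corpus.validate_against(taxonomy)
    total = len(corpus) if group_total is None else group_total
    freqs: dict[tuple[str, str], int] = {}
    seen_ratings: list[str] = []
    for u in corpus.units:
        if u.policy_id not in ratings:
            raise ValueError(f"unit {u.unit_id}: policy {u.policy_id} has no rating")
        rating = ratings[u.policy_id]
        if rating not in seen_ratings:
            seen_ratings.append(rating)
        cat = taxonomy.category_of(u.sub_tool)
        freqs[(rating, cat)] = freqs.get((rating, cat), 0) + 1
    cats = tuple(c.id for c in taxonomy.categories)
    for rating in seen_ratings:
        for cat in cats:
            freqs.setdefault((rating, cat), 0)
    pcts = {key: _percentage(c, total) for key, c in freqs.items()}
    return CrossTab(
        group=corpus.group,
        frequencies=freqs,
        percentages=pcts,
        group_total=total,
        categories=cats,
        ratings=tuple(seen_ratings),
    )


def ratio_set(crosstab: CrossTab, rating: str) -> RatioSet:
    """Environment/supply and environment/demand ratios for one rating, 2 dp."""
    if rating not in crosstab.ratings:
        raise ValueError(f"rating {rating!r} not present in cross-tab")
    env = crosstab.frequencies[(rating, "environment")]
    sup = crosstab.frequencies[(rating, "supply")]
    dem = crosstab.frequencies[(rating, "demand")]
    return RatioSet(
        env_supply=None if sup == 0 else round_half_up(env / sup, 2),
        env_demand=None if dem == 0 else round_half_up(env / dem, 2),
    )


def crosstab_frame(crosstab: CrossTab) -> pd.DataFrame:
    rows = []
    for rating in crosstab.ratings:
        for cat in crosstab.categories:
            rows.append(
                {
                    "rating": rating,
                    "category": cat,
                    "frequency": crosstab.frequencies[(rating, cat)],
                    "percentage": crosstab.percentages[(rating, cat)],
                }
            )
    return pd.DataFrame(rows)


def save_crosstab(crosstab: CrossTab, path: str | Path) -> None:
    crosstab_frame(crosstab).to_csv(path, index=False)
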