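"""Synthetic coded corpora and embedded worked-example fixtures.

The generator emulates the statistical structure of the pilot-city study:
three analysis groups of 35, 14 and 30 policies, independent Bernoulli
second-level codings whose per-criterion probabilities are calibrated so
each first-level variable's expected score equals a target mean, and
multinomial sub-tool mixes per group calibrated to the published frequency
table.  Criteria within a variable are treated as exchangeable and
independent; no within-variable correlation is modeled.

The fixture set embeds every printed worked-example value — the 15 published
per-policy score rows, the full sub-tool frequency table, group means,
rating tallies and headline usage ratios — so every pipeline stage is
testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .schema_model import (
    ANALYSIS_GROUPS,
    CodingUnit,
    EvaluationSchema,
    GroupLabel,
    PolicyCoding,
    ToolCorpus,
    ToolTaxonomy,
    default_schema,
    default_taxonomy,
)

G11 = GroupLabel(batch=1, phase=1)
G12 = GroupLabel(batch=1, phase=2)
G22 = GroupLabel(batch=2, phase=2)

#: Policies per analysis group in the study corpus.
GROUP_SIZES: dict[GroupLabel, int] = {G11: 35, G12: 14, G22: 30}

#: Published mean first-level scores, overall and per group.
VARIABLE_MEANS_ALL = {
    "X1": 0.840, "X2": 0.307, "X3": 0.563, "X4": 0.808, "X5": 0.937,
    "X6": 0.924, "X7": 0.539, "X8": 0.873, "X9": 0.910, "X10": 1.0,
}
VARIABLE_MEANS_BY_GROUP: dict[GroupLabel, dict[str, float]] = {
    G11: {"X1": 0.795, "X2": 0.300, "X3": 0.579, "X4": 0.832, "X5": 0.933,
          "X6": 0.919, "X7": 0.588, "X8": 0.834, "X9": 0.903, "X10": 1.0},
    G12: {"X1": 0.869, "X2": 0.268, "X3": 0.536, "X4": 0.837, "X5": 0.905,
          "X6": 0.940, "X7": 0.480, "X8": 0.829, "X9": 0.914, "X10": 1.0},
    G22: {"X1": 0.879, "X2": 0.333, "X3": 0.558, "X4": 0.766, "X5": 0.956,
          "X6": 0.922, "X7": 0.509, "X8": 0.940, "X9": 0.917, "X10": 1.0},
}

#: Published mean PMC index per group and overall.
GROUP_MEAN_PMC = {G11: 7.683, G12: 7.577, G22: 7.781}
OVERALL_MEAN_PMC = 7.701

#: Published rating tallies per group.
GROUP_RATING_COUNTS = {
    G11: {"perfect": 3, "good": 21, "acceptable": 11, "poor": 0},
    G12: {"perfect": 0, "good": 11, "acceptable": 2, "poor": 1},
    G22: {"perfect": 0, "good": 23, "acceptable": 6, "poor": 1},
}

# The 15 published per-policy rows: scores X1..X10, index, global rank, rating.
_TABLE6 = [
    # policy, X1,    X2,    X3,    X4,    X5,  X6,    X7,    X8,  X9,  X10, PMC,  rank, rating
    (1,  0.833, 0.250, 0.750, 0.857, 1.0, 1.000, 0.857, 1.0, 1.0, 1.0, 8.547, 12, "good"),
    (2,  0.833, 0.250, 0.500, 0.857, 1.0, 0.833, 0.714, 1.0, 1.0, 1.0, 7.987, 40, "good"),
    (3,  0.833, 0.250, 0.500, 0.857, 1.0, 1.000, 0.286, 1.0, 1.0, 1.0, 7.726, 51, "good"),
    (4,  1.000, 0.250, 0.750, 1.000, 1.0, 1.000, 0.714, 1.0, 1.0, 1.0, 8.714, 4, "good"),
    (5,  0.500, 0.250, 0.500, 0.571, 1.0, 1.000, 0.143, 0.4, 1.0, 1.0, 6.364, 72, "acceptable"),
    (16, 1.000, 0.500, 0.500, 1.000, 1.0, 1.000, 1.000, 1.0, 1.0, 1.0, 9.000, 2, "perfect"),
    (17, 0.500, 0.250, 0.500, 0.857, 1.0, 0.667, 0.286, 0.4, 0.5, 1.0, 5.960, 76, "acceptable"),
    (18, 0.500, 0.250, 0.500, 0.857, 1.0, 1.000, 0.429, 0.4, 0.5, 1.0, 6.436, 71, "acceptable"),
    (19, 0.833, 0.500, 0.500, 0.857, 1.0, 0.833, 1.000, 1.0, 1.0, 1.0, 8.523, 15, "good"),
    (20, 1.000, 0.500, 0.750, 1.000, 1.0, 1.000, 0.857, 1.0, 1.0, 1.0, 9.107, 1, "perfect"),
    (75, 1.000, 0.250, 0.500, 0.857, 1.0, 1.000, 0.571, 1.0, 1.0, 1.0, 8.178, 29, "good"),
    (76, 1.000, 0.500, 0.500, 0.857, 1.0, 1.000, 0.429, 1.0, 1.0, 1.0, 8.286, 23, "good"),
    (77, 0.333, 0.250, 0.500, 0.429, 0.333, 0.333, 0.286, 0.6, 0.5, 1.0, 4.564, 78, "poor"),
    (78, 1.000, 0.250, 0.500, 1.000, 1.0, 1.000, 0.571, 1.0, 1.0, 1.0, 8.321, 22, "good"),
    (79, 1.000, 0.500, 0.500, 1.000, 1.0, 1.000, 0.571, 1.0, 1.0, 1.0, 8.571, 8, "good"),
]

# Full published sub-tool frequency table: counts per analysis group.
_TABLE5 = [
    # category,    sub-tool,                    n(b1p1), n(b1p2), n(b2p2)
    ("supply", "Infrastructure construction", 48, 15, 54),
    ("supply", "Technology support", 1, 0, 8),
    ("supply", "Talent development", 37, 10, 44),
    ("supply", "Information support", 36, 8, 23),
    ("supply", "Financial support", 42, 18, 42),
    ("environment", "Tax incentives", 5, 1, 2),
    ("environment", "Strategic measures", 803, 289, 601),
    ("environment", "Regulatory control", 35, 20, 22),
    ("environment", "Institution building", 99, 35, 52),
    ("environment", "Target planning", 99, 39, 92),
    ("environment", "Policy publicity", 10, 7, 16),
    ("demand", "Government purchasing", 10, 2, 4),
    ("demand", "Policy subsidies", 15, 6, 14),
    ("demand", "Service outsourcing", 43, 19, 25),
    ("demand", "Market cultivation", 18, 5, 15),
    ("demand", "Demonstration pilots", 53, 19, 53),
]

#: Coding units per analysis group (frequency-table grand totals).
UNITS_PER_GROUP = {G11: 1354, G12: 493, G22: 1067}

#: Perfect-rated unit counts in the first-batch/first-phase group and their
#: published environment/supply and environment/demand usage ratios.
PERFECT_TOOL_COUNTS = {"supply": 12, "environment": 75, "demand": 17}
PERFECT_RATIOS = (6.25, 4.41)
#: Policies of that group rated perfect.
PERFECT_POLICY_IDS = (14, 16, 20)

#: Published environment-category percentages by rating for the
#: first-batch/first-phase group (denominator: the group's 1354 units).
ENV_PCT_BY_RATING_G11 = {"good": 52.511, "acceptable": 19.572, "poor": 0.0}


@dataclass(frozen=True)
class FixtureSet:
    """Embedded printed worked-example values; treat as immutable."""

    table6: pd.DataFrame
    table5: pd.DataFrame
    group_sizes: dict[GroupLabel, int]
    units_per_group: dict[GroupLabel, int]
    variable_means: dict[GroupLabel, dict[str, float]]
    variable_means_all: dict[str, float]
    group_mean_pmc: dict[GroupLabel, float]
    overall_mean_pmc: float
    group_rating_counts: dict[GroupLabel, dict[str, int]]
    perfect_tool_counts: dict[str, int]
    perfect_ratios: tuple[float, float]


def fixtures() -> FixtureSet:
    """The embedded printed values as dataframes and mappings."""
    var_cols = [f"X{i}" for i in range(1, 11)]
    table6 = pd.DataFrame(
        _TABLE6, columns=["policy_id", *var_cols, "pmc_index", "ranking", "rating"]
    )
    table6["batch"] = np.where(table6["policy_id"] >= 50, 2, 1)
    table6["phase"] = np.where(table6["policy_id"] >= 36, 2, 1)
    table5 = pd.DataFrame(
        _TABLE5,
        columns=["category", "sub_tool", "freq_batch1-phase1", "freq_batch1-phase2",
                 "freq_batch2-phase2"],
    )
    return FixtureSet(
        table6=table6,
        table5=table5,
        group_sizes=dict(GROUP_SIZES),
        units_per_group=dict(UNITS_PER_GROUP),
        variable_means={g: dict(m) for g, m in VARIABLE_MEANS_BY_GROUP.items()},
        variable_means_all=dict(VARIABLE_MEANS_ALL),
        group_mean_pmc=dict(GROUP_MEAN_PMC),
        overall_mean_pmc=OVERALL_MEAN_PMC,
        group_rating_counts={g: dict(c) for g, c in GROUP_RATING_COUNTS.items()},
        perfect_tool_counts=dict(PERFECT_TOOL_COUNTS),
        perfect_ratios=PERFECT_RATIOS,
    )


def fixture_codings() -> list[PolicyCoding]:
    """The 15 published policy rows as SUMMARY-dialect codings."""
    fx = fixtures()
    codings = []
    for _, row in fx.table6.iterrows():
        codings.append(
            PolicyCoding(
                policy_id=int(row["policy_id"]),
                group=GroupLabel(batch=int(row["batch"]), phase=int(row["phase"])),
                summary_scores={f"X{i}": float(row[f"X{i}"]) for i in range(1, 11)},
            )
        )
    return codings


def fixture_tool_mix(group: GroupLabel, taxonomy: ToolTaxonomy | None = None) -> dict[str, float]:
    """Sub-tool mix of one group as proportions of its grand total."""
    if taxonomy is None:
        taxonomy = default_taxonomy()
    fx = fixtures()
    col = f"freq_{group.key}"
    if col not in fx.table5.columns:
        raise KeyError(f"no published tool mix for group {group.key}")
    counts = dict(zip(fx.table5["sub_tool"], fx.table5[col]))
    total = sum(counts.values())
    return {t: counts[t] / total for t in taxonomy.sub_tools}


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Seeded configuration for synthetic codings and corpora.

    ``criterion_probs`` maps every criterion id (and every leaf variable id)
    to its Bernoulli success probability; ``group_criterion_probs`` may
    override it per group so each group tracks its own calibration targets.
    ``tool_mix`` gives each group's multinomial sub-tool distribution.
    """

    seed: int = 20160701
    group_sizes: dict[GroupLabel, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    criterion_probs: dict[str, float] = field(default_factory=dict)
    group_criterion_probs: dict[GroupLabel, dict[str, float]] | None = None
    units_per_group: dict[GroupLabel, int] = field(default_factory=lambda: dict(UNITS_PER_GROUP))
    tool_mix: dict[GroupLabel, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group size for {g.key} must be positive")
            if g.batch == 2 and g.phase == 1:
                raise ValueError("group (batch 2, phase 1) does not exist in the corpus layout")
        for probs in [self.criterion_probs, *(self.group_criterion_probs or {}).values()]:
            bad = {k: p for k, p in probs.items() if not 0.0 <= p <= 1.0}
            if bad:
                raise ValueError(f"probabilities outside [0,1]: {bad}")
        for g, mix in self.tool_mix.items():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"tool mix for {g.key} sums to {s}, not 1")

    def probs_for(self, group: GroupLabel) -> dict[str, float]:
        if self.group_criterion_probs and group in self.group_criterion_probs:
            return self.group_criterion_probs[group]
        return self.criterion_probs


def calibrate_probs(
    target_variable_means: Mapping[str, float], schema: EvaluationSchema
) -> dict[str, float]:
    """Per-criterion Bernoulli probabilities hitting target variable means.

    Criteria under a variable are exchangeable, so each gets the variable's
    target mean as its probability; the expected variable score then equals
    the target.  Leaf variables get the target directly as their 0/1 rate.
    """
    probs: dict[str, float] = {}
    for var in schema.variables:
        if var.id not in target_variable_means:
            raise KeyError(f"no target mean for variable {var.id}")
        p = float(target_variable_means[var.id])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"target mean for {var.id} outside [0,1]: {p}")
        if var.criteria:
            for c in var.criteria:
                probs[c.id] = p
        else:
            probs[var.id] = p
    return probs


def study_config(seed: int = 20160701, schema: EvaluationSchema | None = None) -> GeneratorConfig:
    """Generator configuration emulating the study corpus.

    Group sizes 35/14/30, per-group criterion probabilities calibrated to
    the published group variable means, and per-group sub-tool mixes
    proportional to the published frequency table.
    """
    if schema is None:
        schema = default_schema()
    taxonomy = default_taxonomy()
    return GeneratorConfig(
        seed=seed,
        group_sizes=dict(GROUP_SIZES),
        criterion_probs=calibrate_probs(VARIABLE_MEANS_ALL, schema),
        group_criterion_probs={
            g: calibrate_probs(means, schema)
            for g, means in VARIABLE_MEANS_BY_GROUP.items()
        },
        units_per_group=dict(UNITS_PER_GROUP),
        tool_mix={g: fixture_tool_mix(g, taxonomy) for g in ANALYSIS_GROUPS},
    )


def _ordered_groups(config: GeneratorConfig) -> list[GroupLabel]:
    known = [g for g in ANALYSIS_GROUPS if g in config.group_sizes]
    extra = [g for g in config.group_sizes if g not in known]
    return known + extra


def policy_ids_for_group(config: GeneratorConfig, group: GroupLabel) -> range:
    """Sequential policy numbering: groups concatenated in corpus order."""
    start = 1
    for g in _ordered_groups(config):
        n = config.group_sizes[g]
        if g == group:
            return range(start, start + n)
        start += n
    raise KeyError(f"group {group.key} not in generator config")


def generate_codings(
    config: GeneratorConfig, schema: EvaluationSchema | None = None
) -> list[PolicyCoding]:
    """Draw independent Bernoulli codings for every policy of every group."""
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(config.seed)
    codings: list[PolicyCoding] = []
    for group in _ordered_groups(config):
        probs = config.probs_for(group)
        missing = (set(schema.criterion_ids) | set(schema.leaf_variable_ids)) - set(probs)
        if missing:
            raise KeyError(f"no probabilities for {sorted(missing)[:5]}…")
        for pid in policy_ids_for_group(config, group):
            values = {
                c: int(rng.random() < probs[c]) for c in schema.criterion_ids
            }
            leaves = {
                v: int(rng.random() < probs[v]) for v in schema.leaf_variable_ids
            }
            codings.append(
                PolicyCoding(
                    policy_id=pid, group=group, values=values, leaf_values=leaves
                )
            )
    return codings


def generate_corpus(
    config: GeneratorConfig,
    group: GroupLabel,
    taxonomy: ToolTaxonomy | None = None,
) -> ToolCorpus:
    """Draw a coding-unit corpus for one group from its multinomial mix.

    Units are assigned to the group's policies uniformly at random and
    numbered sequentially per policy, ten units per synthetic chapter.
    """
    if taxonomy is None:
        taxonomy = default_taxonomy()
    if group not in config.tool_mix:
        raise KeyError(f"no tool mix configured for group {group.key}")
    mix = config.tool_mix[group]
    n = config.units_per_group.get(group, 0)
    # independent stream per group so corpora don't shift with coding draws
    rng = np.random.default_rng([config.seed, group.batch, group.phase])
    tools = list(mix)
    draws = rng.choice(len(tools), size=n, p=[mix[t] for t in tools])
    pids = sorted(policy_ids_for_group(config, group))
    assignment = rng.choice(pids, size=n) if n else np.array([], dtype=int)
    per_policy_count: dict[int, int] = {}
    units = []
    for k in range(n):
        pid = int(assignment[k])
        i = per_policy_count.get(pid, 0)
        per_policy_count[pid] = i + 1
        unit_id = f"{pid}-{i // 10 + 1}-{i % 10 + 1}"
        units.append(
            CodingUnit(unit_id=unit_id, policy_id=pid, sub_tool=tools[int(draws[k])])
        )
    return ToolCorpus(units=tuple(units), group=group)
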