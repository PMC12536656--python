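"""Evaluation schema, instrument taxonomy, policy codings and coding-unit corpora.

The evaluation rubric is a two-level hierarchy: first-level variables
(``X1`` .. ``X10``) each own an ordered list of binary second-level criteria
(``X1-1`` .. ``X1-6`` etc.); a variable may own none, in which case it is
scored directly as a 0/1 leaf.  Policy instruments are classified by a
three-category taxonomy (supply / environment / demand) of named sub-tools.
Content-analysis units carry an identifier ``policy-chapter-unit`` and one
sub-tool label.

This module defines the validated domain types and the CSV/YAML readers and
writers for all of them.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger("pmcpolicy")

CRITERION_ID_RE = re.compile(r"^(X\d+)-(\d+)$")
VARIABLE_ID_RE = re.compile(r"^X(\d+)$")
UNIT_ID_RE = re.compile(r"^(\d+)-(\d+)-(\d+)$")


class SchemaError(ValueError):
    """A schema, taxonomy or config file failed validation.

    Carries ``field`` naming the offending entry where known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message if field is None else f"{field}: {message}")
        self.field = field


class CodingSheetError(ValueError):
    """A coding sheet or coding-unit table failed validation.

    Carries ``row`` (0-based data row) and ``column`` where known.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


# ---------------------------------------------------------------------------
# Evaluation schema
# ---------------------------------------------------------------------------


class SecondLevelCriterion(BaseModel):
    """One binary yes/no criterion, e.g. ``X1-3`` (feedback channel present)."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str = ""
    criterion: str = "with yes 1, no 0"

    @field_validator("id")
    @classmethod
    def _id_format(cls, v: str) -> str:
        if not CRITERION_ID_RE.match(v):
            raise ValueError(f"criterion id {v!r} is not of the form 'Xt-j'")
        return v


class FirstLevelVariable(BaseModel):
    """A rubric dimension (e.g. policy nature) owning binary criteria.

    A variable with an empty criteria list is a leaf scored directly 0/1.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    label: str = ""
    criteria: tuple[SecondLevelCriterion, ...] = ()

    @field_validator("id")
    @classmethod
    def _id_format(cls, v: str) -> str:
        if not VARIABLE_ID_RE.match(v):
            raise ValueError(f"variable id {v!r} is not of the form 'Xt'")
        return v

    @model_validator(mode="after")
    def _criteria_consistent(self) -> "FirstLevelVariable":
        seen: set[str] = set()
        for c in self.criteria:
            if c.id in seen:
                raise ValueError(f"duplicate criterion id {c.id!r} under {self.id}")
            seen.add(c.id)
            prefix = c.id.split("-")[0]
            if prefix != self.id:
                raise ValueError(
                    f"criterion {c.id!r} does not belong to variable {self.id!r}"
                )
        return self

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)


class EvaluationSchema(BaseModel):
    """Ordered set of first-level variables with their binary criteria."""

    model_config = ConfigDict(frozen=True)

    variables: tuple[FirstLevelVariable, ...]
    version: str = "unversioned"

    @model_validator(mode="after")
    def _validate(self) -> "EvaluationSchema":
        if not self.variables:
            raise ValueError("schema defines no variables")
        ids = [v.id for v in self.variables]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variable ids {dupes}")
        numbers = [int(VARIABLE_ID_RE.match(v)[1]) for v in ids]
        if numbers != sorted(numbers):
            raise ValueError(f"variables out of order: {ids}")
        crit_ids = [c.id for v in self.variables for c in v.criteria]
        if len(set(crit_ids)) != len(crit_ids):
            dupes = sorted({i for i in crit_ids if crit_ids.count(i) > 1})
            raise ValueError(f"duplicate criterion ids {dupes}")
        return self

    @property
    def variable_ids(self) -> list[str]:
        return [v.id for v in self.variables]

    @property
    def criterion_ids(self) -> list[str]:
        return [c.id for v in self.variables for c in v.criteria]

    @property
    def leaf_variable_ids(self) -> list[str]:
        """Variables with no criteria, scored directly 0/1."""
        return [v.id for v in self.variables if not v.criteria]

    @property
    def n_criteria(self) -> int:
        return len(self.criterion_ids)

    def variable(self, var_id: str) -> FirstLevelVariable:
        for v in self.variables:
            if v.id == var_id:
                return v
        raise KeyError(var_id)


# ---------------------------------------------------------------------------
# Instrument taxonomy
# ---------------------------------------------------------------------------

CategoryId = Literal["supply", "environment", "demand"]


class ToolCategory(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: CategoryId
    label: str = ""
    sub_tools: tuple[str, ...]

    @field_validator("sub_tools")
    @classmethod
    def _nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("category defines no sub-tools")
        return v


class ToolTaxonomy(BaseModel):
    """Supply / environment / demand instrument classification."""

    model_config = ConfigDict(frozen=True)

    categories: tuple[ToolCategory, ...]

    @model_validator(mode="after")
    def _validate(self) -> "ToolTaxonomy":
        all_tools = [t for c in self.categories for t in c.sub_tools]
        if len(set(all_tools)) != len(all_tools):
            dupes = sorted({t for t in all_tools if all_tools.count(t) > 1})
            raise ValueError(f"sub-tool labels duplicated across categories: {dupes}")
        cat_ids = [c.id for c in self.categories]
        if len(set(cat_ids)) != len(cat_ids):
            raise ValueError("duplicate category ids")
        return self

    @property
    def sub_tools(self) -> list[str]:
        return [t for c in self.categories for t in c.sub_tools]

    def category_of(self, sub_tool: str) -> CategoryId:
        for c in self.categories:
            if sub_tool in c.sub_tools:
                return c.id
        raise KeyError(f"unknown sub-tool {sub_tool!r}")


# ---------------------------------------------------------------------------
# Group labels and policy codings
# ---------------------------------------------------------------------------


class GroupLabel(BaseModel):
    """Pilot batch (1 = 2016 wave, 2 = 2020 wave) and issuance phase.

    The corpus layout has no (batch 2, phase 1) group: second-batch cities
    only issued policies after the second phase opened.  The combination is
    representable (loaders warn) but the generator refuses to produce it.
    """

    model_config = ConfigDict(frozen=True)

    batch: Literal[1, 2]
    phase: Literal[1, 2]

    @property
    def key(self) -> str:
        return f"batch{self.batch}-phase{self.phase}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


#: The three analysis groups of the pilot-city corpus, in presentation order.
ANALYSIS_GROUPS = (
    GroupLabel(batch=1, phase=1),
    GroupLabel(batch=1, phase=2),
    GroupLabel(batch=2, phase=2),
)


class PolicyCoding(BaseModel):
    """One policy's binary rubric assignment.

    Either ``values`` (full 46-column binary coding, plus ``leaf_values`` for
    zero-criterion variables) or ``summary_scores`` (pre-aggregated
    first-level scores, the form worked examples are printed in) is set.
    """

    model_config = ConfigDict(frozen=True)

    policy_id: int = Field(gt=0)
    group: GroupLabel
    values: dict[str, int] = {}
    leaf_values: dict[str, int] = {}
    summary_scores: Optional[dict[str, float]] = None

    @field_validator("values", "leaf_values")
    @classmethod
    def _binary(cls, v: dict[str, int]) -> dict[str, int]:
        bad = {k: x for k, x in v.items() if x not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary coding values: {bad}")
        return v

    @field_validator("summary_scores")
    @classmethod
    def _unit_interval(cls, v):
        if v is not None:
            bad = {k: x for k, x in v.items() if not 0.0 <= x <= 1.0}
            if bad:
                raise ValueError(f"summary scores outside [0,1]: {bad}")
        return v

    @property
    def is_summary(self) -> bool:
        return self.summary_scores is not None

    def validate_against(self, schema: EvaluationSchema) -> None:
        """Check the coding covers the schema exactly; raise SchemaError."""
        if self.is_summary:
            missing = set(schema.variable_ids) - set(self.summary_scores)
            extra = set(self.summary_scores) - set(schema.variable_ids)
            if missing or extra:
                raise SchemaError(
                    f"summary coding for policy {self.policy_id} mismatches schema "
                    f"(missing {sorted(missing)}, extra {sorted(extra)})"
                )
            return
        missing = set(schema.criterion_ids) - set(self.values)
        extra = set(self.values) - set(schema.criterion_ids)
        if missing or extra:
            raise SchemaError(
                f"coding for policy {self.policy_id} mismatches schema criteria "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        leaves = set(schema.leaf_variable_ids)
        if set(self.leaf_values) != leaves:
            raise SchemaError(
                f"coding for policy {self.policy_id} must give leaf values for "
                f"exactly {sorted(leaves)}, got {sorted(self.leaf_values)}"
            )


# ---------------------------------------------------------------------------
# Coding units and corpora
# ---------------------------------------------------------------------------


class CodingUnit(BaseModel):
    """Smallest content-analysis fragment: policy–chapter–unit plus sub-tool."""

    model_config = ConfigDict(frozen=True)

    unit_id: str
    policy_id: int = Field(gt=0)
    sub_tool: str

    @field_validator("unit_id")
    @classmethod
    def _unit_id_format(cls, v: str) -> str:
        m = UNIT_ID_RE.match(v)
        if not m or any(int(part) <= 0 for part in m.groups()):
            raise ValueError(
                f"unit id {v!r} must be 'policy-chapter-unit' with positive integers"
            )
        return v

    @model_validator(mode="after")
    def _policy_matches(self) -> "CodingUnit":
        first = int(self.unit_id.split("-")[0])
        if first != self.policy_id:
            raise ValueError(
                f"unit id {self.unit_id!r} names policy {first}, not {self.policy_id}"
            )
        return self


class ToolCorpus(BaseModel):
    """Coding units of one analysis group, labeled by sub-tool."""

    model_config = ConfigDict(frozen=True)

    units: tuple[CodingUnit, ...]
    group: GroupLabel

    @model_validator(mode="after")
    def _unique_units(self) -> "ToolCorpus":
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit ids: {dupes[:5]}")
        return self

    def __len__(self) -> int:
        return len(self.units)

    def validate_against(self, taxonomy: ToolTaxonomy) -> None:
        known = set(taxonomy.sub_tools)
        for u in self.units:
            if u.sub_tool not in known:
                raise SchemaError(f"unknown sub-tool {u.sub_tool!r} in unit {u.unit_id}")


# ---------------------------------------------------------------------------
# Loaders / writers
# ---------------------------------------------------------------------------


def _schema_from_dict(doc: dict) -> EvaluationSchema:
    try:
        variables = tuple(
            FirstLevelVariable(
                id=v["id"],
                label=v.get("label", ""),
                criteria=tuple(
                    SecondLevelCriterion(
                        id=c["id"],
                        label=c.get("label", ""),
                        criterion=c.get("criterion", "with yes 1, no 0"),
                    )
                    for c in (v.get("criteria") or [])
                ),
            )
            for v in doc.get("variables", [])
        )
        return EvaluationSchema(variables=variables, version=str(doc.get("version", "unversioned")))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema document: {exc}") from exc
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def load_schema(path: str | Path) -> EvaluationSchema:
    """Load and validate an evaluation schema from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"schema file {path} does not contain a mapping")
    return _schema_from_dict(doc)


def save_schema(schema: EvaluationSchema, path: str | Path) -> None:
    doc = {
        "version": schema.version,
        "variables": [
            {
                "id": v.id,
                "label": v.label,
                "criteria": [
                    {"id": c.id, "label": c.label, "criterion": c.criterion}
                    for c in v.criteria
                ],
            }
            for v in schema.variables
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_schema() -> EvaluationSchema:
    """The packaged 10-variable / 46-criterion rubric."""
    text = resources.files("pmcpolicy.data").joinpath("schema.yaml").read_text("utf-8")
    return _schema_from_dict(yaml.safe_load(text))


def _taxonomy_from_dict(doc: dict) -> ToolTaxonomy:
    try:
        cats = tuple(
            ToolCategory(
                id=c["id"], label=c.get("label", ""), sub_tools=tuple(c["sub_tools"])
            )
            for c in doc["categories"]
        )
        return ToolTaxonomy(categories=cats)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed taxonomy document: {exc}") from exc
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def load_taxonomy(path: str | Path) -> ToolTaxonomy:
    """Load and validate an instrument taxonomy from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"taxonomy file {path} does not contain a mapping")
    return _taxonomy_from_dict(doc)


def save_taxonomy(taxonomy: ToolTaxonomy, path: str | Path) -> None:
    doc = {
        "categories": [
            {"id": c.id, "label": c.label, "sub_tools": list(c.sub_tools)}
            for c in taxonomy.categories
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_taxonomy() -> ToolTaxonomy:
    """The packaged 3-category / 16-sub-tool instrument taxonomy."""
    text = resources.files("pmcpolicy.data").joinpath("taxonomy.yaml").read_text("utf-8")
    return _taxonomy_from_dict(yaml.safe_load(text))


_META_COLUMNS = ("policy_id", "batch", "phase")


def _parse_group(row: pd.Series, idx: int) -> GroupLabel:
    try:
        group = GroupLabel(batch=int(row["batch"]), phase=int(row["phase"]))
    except (ValueError, TypeError) as exc:
        raise CodingSheetError(f"invalid group metadata: {exc}", row=idx) from exc
    if group.batch == 2 and group.phase == 1:
        logger.warning(
            "row %d: group (batch 2, phase 1) does not occur in the pilot-city "
            "corpus layout", idx,
        )
    return group


def _parse_binary(cell, idx: int, col: str) -> int:
    try:
        value = float(cell)
    except (ValueError, TypeError) as exc:
        raise CodingSheetError(f"non-numeric cell {cell!r}", row=idx, column=col) from exc
    if value not in (0.0, 1.0):
        raise CodingSheetError(f"non-binary cell {cell!r}", row=idx, column=col)
    return int(value)


def load_codings(
    path: str | Path, schema: EvaluationSchema
) -> list[PolicyCoding]:
    """Load a CSV coding sheet into one :class:`PolicyCoding` per row.

    Two dialects are auto-detected from the header.  FULL sheets carry one
    binary column per second-level criterion plus one per leaf variable;
    SUMMARY sheets carry the ten first-level scores already aggregated (the
    form worked examples are printed in).  Both need ``policy_id``, ``batch``
    and ``phase`` columns.  Unknown extra columns are ignored with a warning.
    """
    df = pd.read_csv(path, dtype=object)
    cols = set(df.columns)
    missing_meta = [c for c in _META_COLUMNS if c not in cols]
    if missing_meta:
        raise CodingSheetError(f"missing metadata columns {missing_meta}")

    crit_cols = set(schema.criterion_ids) | set(schema.leaf_variable_ids)
    var_cols = set(schema.variable_ids)
    if crit_cols <= cols:
        dialect = "full"
        expected = crit_cols
    elif var_cols <= cols:
        dialect = "summary"
        expected = var_cols
    else:
        missing_full = sorted(crit_cols - cols)
        missing_summary = sorted(var_cols - cols)
        raise CodingSheetError(
            "header matches neither dialect: FULL lacks "
            f"{missing_full[:5]}…, SUMMARY lacks {missing_summary[:5]}…"
        )

    extra = cols - expected - set(_META_COLUMNS)
    if extra:
        logger.warning("ignoring unknown columns %s", sorted(extra))

    codings: list[PolicyCoding] = []
    seen_ids: set[int] = set()
    for idx, row in df.iterrows():
        try:
            policy_id = int(row["policy_id"])
        except (ValueError, TypeError) as exc:
            raise CodingSheetError(
                f"invalid policy_id {row['policy_id']!r}", row=idx, column="policy_id"
            ) from exc
        if policy_id in seen_ids:
            raise CodingSheetError(
                f"duplicate policy_id {policy_id}", row=idx, column="policy_id"
            )
        seen_ids.add(policy_id)
        group = _parse_group(row, idx)

        if dialect == "full":
            values = {c: _parse_binary(row[c], idx, c) for c in schema.criterion_ids}
            leaves = {
                v: _parse_binary(row[v], idx, v) for v in schema.leaf_variable_ids
            }
            coding = PolicyCoding(
                policy_id=policy_id, group=group, values=values, leaf_values=leaves
            )
        else:
            scores = {}
            for v in schema.variable_ids:
                try:
                    scores[v] = float(row[v])
                except (ValueError, TypeError) as exc:
                    raise CodingSheetError(
                        f"non-numeric score {row[v]!r}", row=idx, column=v
                    ) from exc
                if not 0.0 <= scores[v] <= 1.0:
                    raise CodingSheetError(
                        f"score {scores[v]} outside [0,1]", row=idx, column=v
                    )
            coding = PolicyCoding(
                policy_id=policy_id, group=group, summary_scores=scores
            )
        coding.validate_against(schema)
        codings.append(coding)
    return codings


def save_codings(
    codings: Iterable[PolicyCoding], schema: EvaluationSchema, path: str | Path
) -> None:
    """Write codings to CSV in the FULL or SUMMARY dialect (auto per content)."""
    codings = list(codings)
    rows = []
    for c in codings:
        row: dict[str, object] = {
            "policy_id": c.policy_id,
            "batch": c.group.batch,
            "phase": c.group.phase,
        }
        if c.is_summary:
            row.update(c.summary_scores)
        else:
            row.update(c.values)
            row.update(c.leaf_values)
        rows.append(row)
    if codings and codings[0].is_summary:
        columns = list(_META_COLUMNS) + schema.variable_ids
    else:
        columns = list(_META_COLUMNS) + schema.criterion_ids + schema.leaf_variable_ids
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def load_corpus(path: str | Path, taxonomy: ToolTaxonomy, group: GroupLabel | None = None) -> ToolCorpus:
    """Load a CSV coding-unit table into a validated :class:`ToolCorpus`.

    Needs ``unit_id`` and ``sub_tool`` columns; ``batch``/``phase`` columns
    (uniform over the file) or the ``group`` argument supply the group label.
    """
    df = pd.read_csv(path, dtype=object)
    for col in ("unit_id", "sub_tool"):
        if col not in df.columns:
            raise CodingSheetError(f"missing column {col!r}")
    if group is None:
        if not {"batch", "phase"} <= set(df.columns):
            raise CodingSheetError("no group argument and no batch/phase columns")
        pairs = set(zip(df["batch"].astype(int), df["phase"].astype(int)))
        if len(pairs) != 1:
            raise CodingSheetError(f"corpus spans multiple groups: {sorted(pairs)}")
        batch, phase = pairs.pop()
        group = GroupLabel(batch=batch, phase=phase)
        if group.batch == 2 and group.phase == 1:
            logger.warning("corpus group (batch 2, phase 1) does not occur in the pilot-city corpus layout")

    known = set(taxonomy.sub_tools)
    units = []
    for idx, row in df.iterrows():
        sub_tool = str(row["sub_tool"])
        if sub_tool not in known:
            raise CodingSheetError(
                f"unknown sub-tool {sub_tool!r}", row=idx, column="sub_tool"
            )
        unit_id = str(row["unit_id"])
        m = UNIT_ID_RE.match(unit_id)
        if not m or any(int(p) <= 0 for p in m.groups()):
            raise CodingSheetError(
                f"malformed unit id {unit_id!r}", row=idx, column="unit_id"
            )
        units.append(
            CodingUnit(unit_id=unit_id, policy_id=int(m[1]), sub_tool=sub_tool)
        )
    try:
        return ToolCorpus(units=tuple(units), group=group)
    except ValueError as exc:
        raise CodingSheetError(str(exc)) from exc


def save_corpus(corpus: ToolCorpus, path: str | Path) -> None:
    n = len(corpus.units)
    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in corpus.units],
            "policy_id": [u.policy_id for u in corpus.units],
            "sub_tool": [u.sub_tool for u in corpus.units],
            "batch": [corpus.group.batch] * n,
            "phase": [corpus.group.phase] * n,
        }
    ).to_csv(path, index=False)
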