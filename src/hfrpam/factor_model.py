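"""Domain types: the two-stage factor hierarchy, expert rating panels, anchors.

The model operates on a fixed graph of eight factors: two primary (stage)
factors, each the parent of three secondary factors.  The ``core`` stage is
X1 with children X2-X4; the ``external`` stage is X5 with children X6-X8.
Panels are rectangular tables of integer Likert ratings in {1..5}, one row
per expert, one column per factor, always canonicalized to X1..X8 order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HierarchyError",
    "PanelValidationError",
    "FactorHierarchy",
    "ExpertPanel",
    "CorrelationAnchors",
    "DEFAULT_HIERARCHY_YAML",
    "load_hierarchy",
    "default_hierarchy",
    "read_panel",
    "write_panel",
]

LIKERT_MIN = 1
LIKERT_MAX = 5

STAGES = ("core", "external")


class HierarchyError(ValueError):
    """Raised when a factor-hierarchy configuration violates an invariant."""


class PanelValidationError(ValueError):
    """Raised when a panel table fails validation (bad shape, value, or cell)."""


#: Built-in default hierarchy: 2 stages x (1 primary + 3 secondary) factors,
#: with the 18 questionnaire item codes partitioned over the secondary factors.
DEFAULT_HIERARCHY_YAML = """\
factors:
  - {code: X1, stage: core}
  - {code: X2, stage: core, parent: X1, items: [PL09, PL15, PL18]}
  - {code: X3, stage: core, parent: X1, items: [PL01, PL06, PL14]}
  - {code: X4, stage: core, parent: X1, items: [PL03, PL10, PL16]}
  - {code: X5, stage: external}
  - {code: X6, stage: external, parent: X5, items: [PL02, PL07, PL08]}
  - {code: X7, stage: external, parent: X5, items: [PL11, PL12, PL13]}
  - {code: X8, stage: external, parent: X5, items: [PL04, PL05, PL17]}
"""


@dataclass(frozen=True)
class FactorHierarchy:
    """The fixed 2-primary / 6-secondary factor graph.

    Attributes
    ----------
    factors
        Ordered tuple of the 8 factor codes.
    stage_of
        Map factor code -> ``"core"`` or ``"external"``.
    parent_of
        Map secondary factor -> its primary (stage) factor.
    items_of
        Map factor -> tuple of questionnaire item codes (may be empty;
        items are metadata only and never enter any computation).
    """

    factors: tuple[str, ...]
    stage_of: dict[str, str]
    parent_of: dict[str, str]
    items_of: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.factors) != len(set(self.factors)):
            raise HierarchyError("duplicate factor code in hierarchy")
        if len(self.factors) != 8:
            raise HierarchyError(f"expected 8 factors, got {len(self.factors)}")
        primaries = [f for f in self.factors if f not in self.parent_of]
        secondaries = [f for f in self.factors if f in self.parent_of]
        if len(primaries) != 2 or len(secondaries) != 6:
            raise HierarchyError(
                f"expected 2 primary and 6 secondary factors, got "
                f"{len(primaries)} primary / {len(secondaries)} secondary"
            )
        for f in self.factors:
            stage = self.stage_of.get(f)
            if stage not in STAGES:
                raise HierarchyError(f"factor {f} has invalid stage {stage!r}")
        for child, parent in self.parent_of.items():
            if parent not in primaries:
                raise HierarchyError(
                    f"secondary factor {child} has non-primary parent {parent!r}"
                )
            if self.stage_of[child] != self.stage_of[parent]:
                raise HierarchyError(
                    f"secondary factor {child} ({self.stage_of[child]}) is "
                    f"parented to {parent} in a different stage "
                    f"({self.stage_of[parent]})"
                )
        seen: set[str] = set()
        for f, items in self.items_of.items():
            for it in items:
                if it in seen:
                    raise HierarchyError(f"item {it} assigned to more than one factor")
                seen.add(it)

    @property
    def primary_factors(self) -> tuple[str, str]:
        """The two stage-level factors, in factor order."""
        return tuple(f for f in self.factors if f not in self.parent_of)  # type: ignore[return-value]

    @property
    def secondary_factors(self) -> tuple[str, ...]:
        return tuple(f for f in self.factors if f in self.parent_of)

    def children_of(self, primary: str) -> tuple[str, ...]:
        return tuple(f for f in self.factors if self.parent_of.get(f) == primary)

    def stage_group(self, factor: str) -> tuple[str, ...]:
        """All 4 factors (primary + its 3 children) in ``factor``'s stage."""
        stage = self.stage_of[factor]
        return tuple(f for f in self.factors if self.stage_of[f] == stage)

    def index_of(self, factor: str) -> int:
        return self.factors.index(factor)


def default_hierarchy() -> FactorHierarchy:
    """The built-in default hierarchy (X1 core over X2-X4, X5 external over X6-X8)."""
    return load_hierarchy(DEFAULT_HIERARCHY_YAML)


def load_hierarchy(config_text: str | None = None) -> FactorHierarchy:
    """Parse a YAML hierarchy configuration; ``None`` yields the default.

    The configuration declares a ``factors`` list of mappings with keys
    ``code``, ``stage``, optional ``parent`` and optional ``items``.
    """
    if config_text is None:
        config_text = DEFAULT_HIERARCHY_YAML
    raw = yaml.safe_load(config_text)
    if not isinstance(raw, dict) or "factors" not in raw:
        raise HierarchyError("hierarchy config must be a mapping with a 'factors' list")
    factors: list[str] = []
    stage_of: dict[str, str] = {}
    parent_of: dict[str, str] = {}
    items_of: dict[str, tuple[str, ...]] = {}
    for entry in raw["factors"]:
        code = str(entry["code"])
        if code in factors:
            raise HierarchyError(f"duplicate factor code {code}")
        factors.append(code)
        stage_of[code] = str(entry.get("stage", ""))
        if "parent" in entry and entry["parent"] is not None:
            parent_of[code] = str(entry["parent"])
        items = entry.get("items") or []
        items_of[code] = tuple(str(i) for i in items)
    for child, parent in parent_of.items():
        if parent not in factors:
            raise HierarchyError(f"factor {child} references unknown parent {parent!r}")
    return FactorHierarchy(
        factors=tuple(factors),
        stage_of=stage_of,
        parent_of=parent_of,
        items_of=items_of,
    )


@dataclass(frozen=True)
class ExpertPanel:
    """A validated n_experts x 8 table of integer Likert ratings in {1..5}."""

    ratings: np.ndarray
    factor_codes: tuple[str, ...]
    expert_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.ndim != 2:
            raise PanelValidationError("ratings must be a 2-D matrix")
        if r.shape[0] < 1:
            raise PanelValidationError("panel must contain at least one expert row")
        if r.shape[1] != len(self.factor_codes):
            raise PanelValidationError(
                f"ratings have {r.shape[1]} columns but {len(self.factor_codes)} "
                "factor codes were given"
            )
        if not np.issubdtype(r.dtype, np.integer):
            raise PanelValidationError("ratings must be integers")
        bad = np.argwhere((r < LIKERT_MIN) | (r > LIKERT_MAX))
        if bad.size:
            i, j = bad[0]
            raise PanelValidationError(
                f"rating {r[i, j]} out of range {{1..5}} at "
                f"(row {i + 1}, column {self.factor_codes[j]})"
            )
        if len(self.expert_ids) != r.shape[0]:
            raise PanelValidationError("expert_ids length does not match row count")
        object.__setattr__(self, "ratings", r)

    @property
    def n_experts(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.ratings.shape[1]

    def column(self, factor: str) -> np.ndarray:
        return self.ratings[:, self.factor_codes.index(factor)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ratings, columns=list(self.factor_codes))
        df.insert(0, "expert_id", list(self.expert_ids))
        return df


@dataclass(frozen=True)
class CorrelationAnchors:
    """Mapping anchors from Likert ratings to low/medium/high correlation levels."""

    low_max: int = 2
    medium_value: int = 3
    high_min: int = 4

    def __post_init__(self) -> None:
        ok = (
            LIKERT_MIN <= self.low_max < self.medium_value < self.high_min <= LIKERT_MAX
        )
        if not ok:
            raise ValueError(
                "anchors must satisfy 1 <= low_max < medium_value < high_min <= 5, "
                f"got ({self.low_max}, {self.medium_value}, {self.high_min})"
            )


def _panel_from_frame(df: pd.DataFrame, hierarchy: FactorHierarchy) -> ExpertPanel:
    cols = list(df.columns)
    if "expert_id" in cols:
        expert_ids = tuple(str(v) for v in df["expert_id"])
        df = df.drop(columns=["expert_id"])
    else:
        expert_ids = tuple(str(i) for i in range(1, len(df) + 1))
    missing = [f for f in hierarchy.factors if f not in df.columns]
    if missing:
        raise PanelValidationError(f"panel is missing factor column(s): {missing}")
    extra = [c for c in df.columns if c not in hierarchy.factors]
    if extra:
        raise PanelValidationError(f"panel has unknown column(s): {extra}")
    # canonicalize column order so downstream stages can index positionally
    df = df[list(hierarchy.factors)]
    ratings = np.empty((len(df), len(hierarchy.factors)), dtype=np.int64)
    for j, code in enumerate(hierarchy.factors):
        col = df[code]
        for i, v in enumerate(col):
            if pd.isna(v):
                raise PanelValidationError(
                    f"missing rating at (row {i + 1}, column {code})"
                )
            fv = float(v)
            if fv != int(fv):
                raise PanelValidationError(
                    f"non-integer rating {v!r} at (row {i + 1}, column {code})"
                )
            ratings[i, j] = int(fv)
    return ExpertPanel(ratings=ratings, factor_codes=hierarchy.factors, expert_ids=expert_ids)


def read_panel(path, hierarchy: FactorHierarchy | None = None) -> ExpertPanel:
    """Read a comma-separated panel table and validate it.

    The file has a header with the 8 factor codes (any order; columns are
    re-aligned to hierarchy order) and an optional leading ``expert_id``
    column.  Every cell must be an integer in {1..5}; violations report the
    offending (row, column) coordinates.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise PanelValidationError(f"could not read panel table: {exc}") from exc
    numeric = df.copy()
    for c in numeric.columns:
        if c == "expert_id":
            continue
        try:
            numeric[c] = pd.to_numeric(numeric[c])
        except (TypeError, ValueError):
            bad = next(
                (i, v)
                for i, v in enumerate(numeric[c])
                if pd.notna(v) and not str(v).strip().lstrip("+-").isdigit()
            )
            raise PanelValidationError(
                f"non-integer rating {bad[1]!r} at (row {bad[0] + 1}, column {c})"
            ) from None
    return _panel_from_frame(numeric, hierarchy)


def write_panel(panel: ExpertPanel, path) -> None:
    """Write a panel as CSV with an ``expert_id`` column (round-trips read_panel)."""
    panel.to_frame().to_csv(path, index=False)


def panel_to_csv_text(panel: ExpertPanel) -> str:
    buf = io.StringIO()
    write_panel(panel, buf)
    return buf.getvalue()
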