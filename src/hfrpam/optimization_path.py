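"""ETTO-style optimization index, activity sequence, and path labeling.

The optimization index of a factor is the plain sum of its sensitivity
value and its risk weight (as a proportion).  Factors are ranked by index
descending (activity sequence), then paired by consecutive ranks
(1,2), (3,4), (5,6), (7,8); each pair is a directed path from the better
rank to the worse, labeled by the stage membership of its endpoints with
core = subjective and external = objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor_model import FactorHierarchy
from .mi_sensitivity import SensitivityVector

__all__ = [
    "PathRecord",
    "OptimizationRecord",
    "optimization_index",
    "activity_sequence",
    "classify_paths",
    "build_optimization_records",
]

_STAGE_WORD = {"core": "subjective", "external": "objective"}


def optimization_index(sv, weights) -> pd.Series:
    """oi(f) = sv(f) + weight(f), weight as a proportion (12.25% -> 0.1225)."""
    sv_s = sv.sv if isinstance(sv, SensitivityVector) else pd.Series(sv)
    w_s = pd.Series(weights)
    if list(sv_s.index) != list(w_s.index):
        w_s = w_s.reindex(sv_s.index)
        if w_s.isna().any():
            raise ValueError("sv and weights must cover the same factors")
    oi = sv_s.astype(float) + w_s.astype(float)
    oi.name = "oi"
    return oi


def activity_sequence(oi: pd.Series) -> pd.Series:
    """Rank 1 = largest index; ties broken by factor (index) order."""
    values = oi.to_numpy(dtype=float)
    order = np.lexsort((np.arange(len(values)), -values))
    rank = np.empty(len(values), dtype=int)
    rank[order] = np.arange(1, len(values) + 1)
    return pd.Series(rank, index=oi.index, name="activity_rank")


@dataclass(frozen=True)
class PathRecord:
    path_id: int  # 1..4
    source: str  # better (smaller) rank
    target: str
    label: str


def _label(src_stage: str, dst_stage: str) -> str:
    if src_stage == dst_stage:
        return f"{_STAGE_WORD[src_stage]} stage"
    return f"{_STAGE_WORD[src_stage]}→{_STAGE_WORD[dst_stage]}"


def classify_paths(
    ranks: pd.Series, hierarchy: FactorHierarchy
) -> list[PathRecord]:
    """Pair consecutive ranks into four labeled source->target paths."""
    k = len(ranks)
    if sorted(ranks) != list(range(1, k + 1)) or k % 2 != 0:
        raise ValueError("ranks must be a complete permutation of 1..k, k even")
    by_rank = {int(r): f for f, r in ranks.items()}
    paths = []
    for pid, start in enumerate(range(1, k + 1, 2), start=1):
        src, dst = by_rank[start], by_rank[start + 1]
        paths.append(
            PathRecord(
                path_id=pid,
                source=src,
                target=dst,
                label=_label(hierarchy.stage_of[src], hierarchy.stage_of[dst]),
            )
        )
    return paths


@dataclass(frozen=True)
class OptimizationRecord:
    factor: str
    sv: float
    weight: float
    oi: float
    activity_rank: int
    path_id: int
    path_role: str  # "source" or "target"
    path_label: str


def build_optimization_records(
    sv: SensitivityVector, weights: pd.Series, hierarchy: FactorHierarchy
) -> list[OptimizationRecord]:
    """Assemble the per-factor optimization table (index, rank, path)."""
    oi = optimization_index(sv, weights)
    ranks = activity_sequence(oi)
    paths = classify_paths(ranks, hierarchy)
    by_factor: dict[str, tuple[PathRecord, str]] = {}
    for p in paths:
        by_factor[p.source] = (p, "source")
        by_factor[p.target] = (p, "target")
    records = []
    for f in oi.index:
        p, role = by_factor[f]
        records.append(
            OptimizationRecord(
                factor=str(f),
                sv=float(sv.sv[f]),
                weight=float(weights[f]),
                oi=float(oi[f]),
                activity_rank=int(ranks[f]),
                path_id=p.path_id,
                path_role=role,
                path_label=p.label,
            )
        )
    return records
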