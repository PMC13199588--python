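"""Counting-based Bayesian risk levels with ISO-31000-style banding.

Ratings are mapped to correlation levels (low <=2, medium =3, high >=4 by
default).  For each factor and level, a prior and a likelihood are formed as
counting ratios over configurable denominator groups, and combined as

    inverse  = 1 - likelihood
    marginal = prior * likelihood + (1 - prior) * inverse
    posterior = prior * likelihood / marginal

which is the scheme as published (not a textbook marginalization over the
level partition; a ``canonical`` option normalizing across levels is
available but off by default).  Posteriors are banded low (p <= 0.4),
medium (0.4 < p < 0.8), high (p >= 0.8); the printed band edges leave
[0.80, 0.81) unlabeled, which this implementation assigns to high so the
bands partition [0, 1].  Factor-level binary calls are risky iff p > 0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factor_model import CorrelationAnchors, ExpertPanel, FactorHierarchy

__all__ = [
    "LEVELS",
    "LevelCounts",
    "PosteriorComputation",
    "RiskBandScheme",
    "DenominatorConfig",
    "RiskAssessment",
    "map_correlation_level",
    "count_levels",
    "posterior_probability",
    "classify_band",
    "assess_risk",
]

logger = logging.getLogger(__name__)

LEVELS = ("low", "medium", "high")
ALL_CAUSE = "ALL"


def map_correlation_level(rating: int, anchors: CorrelationAnchors | None = None) -> str:
    """Map a Likert rating to a correlation level per the anchors."""
    if anchors is None:
        anchors = CorrelationAnchors()
    if not 1 <= rating <= 5:
        raise ValueError(f"rating {rating} outside 1..5")
    if rating < anchors.medium_value:
        return "low"
    if rating == anchors.medium_value:
        return "medium"
    return "high"


@dataclass(frozen=True)
class LevelCounts:
    """Per-factor and pooled tallies of ratings at each correlation level."""

    per_factor: dict[str, dict[str, int]]
    pooled: dict[str, int]  # over all 8 columns
    n_experts: int
    group_cells: dict[str, int]  # denominator cell counts by group name

    def __post_init__(self) -> None:
        for f, counts in self.per_factor.items():
            if sum(counts.values()) != self.n_experts:
                raise ValueError(f"level counts for {f} do not sum to n_experts")


def count_levels(
    panel: ExpertPanel,
    hierarchy: FactorHierarchy,
    anchors: CorrelationAnchors | None = None,
) -> LevelCounts:
    """Tally correlation levels per factor, plus pooled tallies and group sizes."""
    if anchors is None:
        anchors = CorrelationAnchors()
    per_factor: dict[str, dict[str, int]] = {}
    for f in hierarchy.factors:
        col = panel.column(f)
        counts = {lv: 0 for lv in LEVELS}
        for r in col:
            counts[map_correlation_level(int(r), anchors)] += 1
        per_factor[f] = counts
    pooled = {
        lv: sum(per_factor[f][lv] for f in hierarchy.factors) for lv in LEVELS
    }
    n = panel.n_experts
    group_cells = {
        "core_stage": len(hierarchy.stage_group(hierarchy.primary_factors[0])) * n,
        "external_stage": len(hierarchy.stage_group(hierarchy.primary_factors[1])) * n,
        "secondary": len(hierarchy.secondary_factors) * n,
        "all": len(hierarchy.factors) * n,
    }
    return LevelCounts(
        per_factor=per_factor, pooled=pooled, n_experts=n, group_cells=group_cells
    )


@dataclass(frozen=True)
class PosteriorComputation:
    prior: float
    likelihood: float
    inverse: float
    marginal: float
    posterior: float
    undefined: bool = False


def posterior_probability(prior: float, likelihood: float) -> PosteriorComputation:
    """Fill the inverse/marginal/posterior record from a prior and likelihood."""
    for name, v in (("prior", prior), ("likelihood", likelihood)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {v} outside [0, 1]")
    inverse = 1.0 - likelihood
    marginal = prior * likelihood + (1.0 - prior) * inverse
    if marginal > 0:
        posterior = prior * likelihood / marginal
        undefined = False
    else:
        posterior = float("nan")
        undefined = True
    return PosteriorComputation(
        prior=prior,
        likelihood=likelihood,
        inverse=inverse,
        marginal=marginal,
        posterior=posterior,
        undefined=undefined,
    )


@dataclass(frozen=True)
class RiskBandScheme:
    """Band edges for posterior probabilities (equidistant 0.2 grid)."""

    risky_cut: float = 0.4
    high_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.risky_cut < self.high_min <= 1.0:
            raise ValueError("require 0 < risky_cut < high_min <= 1")


def classify_band(p: float, scheme: RiskBandScheme | None = None) -> str:
    """Band a posterior: low (p <= 0.4), medium (0.4 < p < 0.8), high (p >= 0.8)."""
    if scheme is None:
        scheme = RiskBandScheme()
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p <= scheme.risky_cut:
        return "low"
    if p < scheme.high_min:
        return "medium"
    return "high"


def is_risky(p: float, scheme: RiskBandScheme | None = None) -> bool:
    if scheme is None:
        scheme = RiskBandScheme()
    return p > scheme.risky_cut


#: Valid denominator group names for the counting ratios.
_GROUPS = ("stage", "secondary", "all", "column")


@dataclass(frozen=True)
class DenominatorConfig:
    """Which cell group forms each counting ratio's denominator.

    ``stage`` = the factor's own 4-column stage group, ``secondary`` = the
    pooled six secondary columns, ``all`` = all eight columns, ``column`` =
    the factor's own column (n_experts cells).  The published description of
    the denominators is ambiguous, so all are configurable; defaults follow
    the most literal reading.  Note that under the defaults a factor-level
    likelihood is at most 1/6, so factor posteriors cannot reach 1 even on a
    unanimous panel; ``column`` denominators restore that degenerate
    certainty.
    """

    prior: str = "stage"
    likelihood: str = "secondary"

    def __post_init__(self) -> None:
        for name, v in (("prior", self.prior), ("likelihood", self.likelihood)):
            if v not in _GROUPS:
                raise ValueError(f"{name} denominator {v!r} not one of {_GROUPS}")


def _denominator(counts: LevelCounts, group: str, factor: str, hierarchy) -> int:
    if group == "all":
        return counts.group_cells["all"]
    if group == "secondary":
        return counts.group_cells["secondary"]
    if group == "column":
        return counts.n_experts
    stage = hierarchy.stage_of[factor]
    return counts.group_cells["core_stage" if stage == "core" else "external_stage"]


@dataclass(frozen=True)
class RiskAssessment:
    """Per-(scope, level) posterior records with bands; scope ALL = all-cause."""

    records: pd.DataFrame
    counts: LevelCounts
    scheme: RiskBandScheme = field(default_factory=RiskBandScheme)

    def lookup(self, scope: str, level: str) -> pd.Series:
        df = self.records
        hit = df[(df["scope"] == scope) & (df["level"] == level)]
        if hit.empty:
            raise KeyError((scope, level))
        return hit.iloc[0]


def assess_risk(
    panel: ExpertPanel,
    hierarchy: FactorHierarchy,
    anchors: CorrelationAnchors | None = None,
    scheme: RiskBandScheme | None = None,
    denominators: DenominatorConfig | None = None,
    canonical: bool = False,
) -> RiskAssessment:
    """Compute prior/likelihood/posterior per (factor, level) and all-cause.

    Factor priors divide the factor's level counts by its stage-group cell
    count; likelihoods divide by the pooled secondary cell count (both
    configurable).  The all-cause scope uses the pooled all-column tallies
    over the all-column cell count for both ratios.  With ``canonical=True``
    posteriors are instead normalized across levels
    (prior*likelihood / sum over levels of prior*likelihood).
    """
    if anchors is None:
        anchors = CorrelationAnchors()
    if scheme is None:
        scheme = RiskBandScheme()
    if denominators is None:
        denominators = DenominatorConfig()
    counts = count_levels(panel, hierarchy, anchors)
    rows = []
    scopes: list[str] = list(hierarchy.factors) + [ALL_CAUSE]
    for scope in scopes:
        if scope == ALL_CAUSE:
            level_counts = counts.pooled
            prior_den = counts.group_cells["all"]
            lik_den = counts.group_cells["all"]
        else:
            level_counts = counts.per_factor[scope]
            prior_den = _denominator(counts, denominators.prior, scope, hierarchy)
            lik_den = _denominator(counts, denominators.likelihood, scope, hierarchy)
        pls = {
            lv: (level_counts[lv] / prior_den, level_counts[lv] / lik_den)
            for lv in LEVELS
        }
        if canonical:
            norm = sum(p * l for p, l in pls.values())
        for lv in LEVELS:
            prior, lik = pls[lv]
            pc = posterior_probability(prior, lik)
            if canonical:
                if norm > 0:
                    pc = PosteriorComputation(
                        prior=prior,
                        likelihood=lik,
                        inverse=pc.inverse,
                        marginal=norm,
                        posterior=prior * lik / norm,
                    )
                else:
                    pc = PosteriorComputation(prior, lik, pc.inverse, 0.0,
                                              float("nan"), undefined=True)
            if pc.undefined:
                logger.warning("undefined posterior (marginal 0) at %s/%s", scope, lv)
                band, risky = "low", False
            else:
                band = classify_band(pc.posterior, scheme)
                risky = is_risky(pc.posterior, scheme)
            rows.append(
                {
                    "scope": scope,
                    "level": lv,
                    "count": level_counts[lv],
                    "prior": pc.prior,
                    "likelihood": pc.likelihood,
                    "inverse": pc.inverse,
                    "marginal": pc.marginal,
                    "posterior": pc.posterior,
                    "undefined": pc.undefined,
                    "band": band,
                    "risky": risky,
                }
            )
    return RiskAssessment(records=pd.DataFrame(rows), counts=counts, scheme=scheme)
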