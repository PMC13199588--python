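"""Gaussian-copula simulator for ordinal Likert expert panels.

Each factor's 5-category marginal is parameterized by a latent normal with
free location/scale, discretized at the fixed cutpoints 1.5, 2.5, 3.5, 4.5.
The location is solved so the discrete mean matches the target exactly; the
scale is then optimized so the discrete SD is as close to the target as the
5-point support allows.  Correlated draws come from a Gaussian copula with a
configurable latent correlation matrix.  All randomness flows through an
explicit seed, so identical config + seed gives a byte-identical panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm

from .factor_model import ExpertPanel, FactorHierarchy, default_hierarchy

__all__ = [
    "PanelSimConfig",
    "SimulationConfigError",
    "default_config",
    "fit_marginal_cutpoints",
    "simulate_panel",
]

_CATEGORY_EDGES = np.array([1.5, 2.5, 3.5, 4.5])
_CATEGORIES = np.arange(1, 6)
_PSD_TOL = 1e-8


class SimulationConfigError(ValueError):
    """Raised for invalid or unattainable simulator configurations."""


@dataclass(frozen=True)
class PanelSimConfig:
    """Targets and correlation structure for a simulated expert panel."""

    n_experts: int
    factor_means: np.ndarray
    factor_sds: np.ndarray
    latent_correlation: np.ndarray
    seed: int = 0
    factor_codes: tuple[str, ...] = field(
        default_factory=lambda: default_hierarchy().factors
    )

    def __post_init__(self) -> None:
        means = np.asarray(self.factor_means, dtype=float)
        sds = np.asarray(self.factor_sds, dtype=float)
        corr = np.asarray(self.latent_correlation, dtype=float)
        k = len(self.factor_codes)
        if means.shape != (k,) or sds.shape != (k,):
            raise SimulationConfigError(
                f"factor_means and factor_sds must have shape ({k},)"
            )
        if self.n_experts < 1:
            raise SimulationConfigError("n_experts must be >= 1")
        if np.any(means <= 1.0) or np.any(means >= 5.0):
            raise SimulationConfigError("factor means must lie strictly inside (1, 5)")
        if np.any(sds <= 0):
            raise SimulationConfigError("factor SDs must be positive")
        if corr.shape != (k, k):
            raise SimulationConfigError(f"latent_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise SimulationConfigError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise SimulationConfigError("latent_correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
            raise SimulationConfigError(
                "latent_correlation is not positive semi-definite"
            )
        object.__setattr__(self, "factor_means", means)
        object.__setattr__(self, "factor_sds", sds)
        object.__setattr__(self, "latent_correlation", corr)


def default_config(seed: int = 0) -> PanelSimConfig:
    """A 62-expert default panel configuration.

    Per-factor target means span 1.79 (X6, lowest) to 3.90 (X7, highest) with
    the remaining means spaced inside that range so the pooled mean is close
    to 2.96; SDs sit inside [0.90, 1.59].  The latent correlation is 0.4
    within each stage block and 0.2 across stages — an artifact choice, since
    no correlation structure is reported for the original panel.
    """
    means = np.array([3.49, 2.60, 3.20, 2.90, 3.05, 1.79, 3.90, 2.75])
    sds = np.array([1.00, 1.10, 1.20, 1.05, 0.95, 0.90, 1.00, 1.25])
    corr = np.full((8, 8), 0.2)
    corr[:4, :4] = 0.4
    corr[4:, 4:] = 0.4
    np.fill_diagonal(corr, 1.0)
    return PanelSimConfig(
        n_experts=62,
        factor_means=means,
        factor_sds=sds,
        latent_correlation=corr,
        seed=seed,
    )


def _discrete_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of the 5-category discretization of N(mu, sigma)."""
    cdf = norm.cdf((_CATEGORY_EDGES - mu) / sigma)
    p = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    mean = float(np.dot(_CATEGORIES, p))
    var = float(np.dot((_CATEGORIES - mean) ** 2, p))
    return mean, np.sqrt(var)


def _attainable_sd_bounds(mean: float) -> tuple[float, float]:
    # max SD: all mass on {1, 5}; min SD: mass on the two adjacent integers
    upper = float(np.sqrt((mean - 1.0) * (5.0 - mean)))
    frac = mean - np.floor(mean)
    lower = float(np.sqrt(frac * (1.0 - frac)))
    return lower, upper


def fit_marginal_cutpoints(
    mean: float, sd: float, factor: str = "?"
) -> np.ndarray:
    """Standard-normal cutpoints whose discretization matches (mean, sd).

    Returns the 4 increasing cutpoints ``z`` such that category
    ``1 + sum(z < u)`` of a standard normal draw ``u`` has the target mean
    exactly and the closest attainable SD.  Raises
    :class:`SimulationConfigError` when the (mean, sd) pair is outside the
    support of any 5-category distribution.
    """
    lo, hi = _attainable_sd_bounds(mean)
    if not (lo - 0.05 <= sd <= hi + 1e-9):
        raise SimulationConfigError(
            f"target (mean={mean}, sd={sd}) unattainable on 5-point support "
            f"for factor {factor}: attainable SD range is [{lo:.4f}, {hi:.4f}]"
        )

    def solve_mu(sigma: float) -> float:
        return brentq(
            lambda m: _discrete_moments(m, sigma)[0] - mean, -40.0, 45.0, xtol=1e-12
        )

    def sd_error(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        mu = solve_mu(sigma)
        return (_discrete_moments(mu, sigma)[1] - sd) ** 2

    res = minimize_scalar(sd_error, bounds=(-4.0, 4.0), method="bounded")
    sigma = float(np.exp(res.x))
    mu = solve_mu(sigma)
    got_mean, got_sd = _discrete_moments(mu, sigma)
    if abs(got_mean - mean) > 1e-8:
        raise SimulationConfigError(
            f"could not match target mean {mean} for factor {factor}"
        )
    if abs(got_sd - sd) > 0.2:
        raise SimulationConfigError(
            f"best attainable SD {got_sd:.4f} too far from target {sd} "
            f"for factor {factor}"
        )
    return (_CATEGORY_EDGES - mu) / sigma


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """A deterministic square root of a PSD correlation matrix (eigh-based)."""
    w, v = np.linalg.eigh(corr)
    if w.min() < -_PSD_TOL:
        raise SimulationConfigError("latent_correlation is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_panel(
    config: PanelSimConfig, hierarchy: FactorHierarchy | None = None
) -> ExpertPanel:
    """Draw an ordinal panel from the Gaussian copula defined by ``config``."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    k = len(config.factor_codes)
    cutpoints = [
        fit_marginal_cutpoints(
            float(config.factor_means[j]), float(config.factor_sds[j]),
            config.factor_codes[j],
        )
        for j in range(k)
    ]
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.n_experts, k))
    L = _correlation_factor(config.latent_correlation)
    latent = z @ L.T
    ratings = np.empty_like(latent, dtype=np.int64)
    for j in range(k):
        ratings[:, j] = 1 + np.searchsorted(cutpoints[j], latent[:, j])
    return ExpertPanel(
        ratings=ratings,
        factor_codes=config.factor_codes,
        expert_ids=tuple(str(i) for i in range(1, config.n_experts + 1)),
    )
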