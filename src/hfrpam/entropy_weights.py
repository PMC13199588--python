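"""Entropy-reduction risk weights over the factor columns.

Each column of the rating matrix is normalized to shares p_ij, its Shannon
entropy E_j = -(1/ln n) * sum_i p_ij ln p_ij is computed (0 ln 0 = 0), and
the weight is the renormalized difference coefficient g_j = 1 - E_j,
w_j = g_j / sum g_j.  Low-dispersion columns carry entropy near 1 and hence
near-zero g, so weights tend toward uniform as dispersion shrinks.

Two normalization modes are exposed.  ``ratio`` divides each cell by the
column range (max - min) as literally described in the source procedure;
``column_share`` divides by the column sum.  In both cases the shares are
rescaled to sum 1 per column before the entropy step (required for
E_j in [0, 1]), which makes the two modes agree except in how constant
columns are handled: a constant column is degenerate under ``ratio``
(zero range) and is assigned E = 1, g = 0 — zero dispersion carries no
discriminating information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor_model import ExpertPanel

__all__ = ["EntropyComputation", "normalize_panel", "entropy_weights"]

logger = logging.getLogger(__name__)

_MODES = ("ratio", "column_share")


def _as_matrix(panel) -> tuple[np.ndarray, list[str]]:
    if isinstance(panel, ExpertPanel):
        return np.asarray(panel.ratings, dtype=float), list(panel.factor_codes)
    x = np.asarray(panel, dtype=float)
    return x, [f"col{j + 1}" for j in range(x.shape[1])]


def normalize_panel(panel, mode: str = "ratio") -> np.ndarray:
    """Column-normalize the rating matrix.

    ``ratio``: cell / (column max - column min); constant columns (zero
    range) are returned as zeros and flagged downstream.  ``column_share``:
    cell / column sum.
    """
    if mode not in _MODES:
        raise ValueError(f"mode {mode!r} not one of {_MODES}")
    x, _ = _as_matrix(panel)
    if x.shape[0] < 2:
        raise ValueError("normalization requires at least 2 rows")
    out = np.zeros_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if mode == "ratio":
            rng = col.max() - col.min()
            if rng > 0:
                out[:, j] = col / rng
        else:
            s = col.sum()
            if s > 0:
                out[:, j] = col / s
    return out


@dataclass(frozen=True)
class EntropyComputation:
    """Full entropy-weight audit trail for one panel."""

    normalized: np.ndarray
    k: float  # moderating coefficient 1 / ln(n_experts)
    E: pd.Series  # per-factor entropy
    g: pd.Series  # difference coefficients 1 - E
    w: pd.Series  # weights g / sum(g)
    rank: pd.Series  # 1 = largest weight, ties by factor order
    degenerate: tuple[str, ...]
    uniform_fallback: bool = False

    @property
    def w_percent(self) -> pd.Series:
        return self.w * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "E": self.E,
                "g": self.g,
                "w": self.w,
                "w_percent": self.w_percent,
                "rank": self.rank,
            }
        )


def entropy_weights(panel, mode: str = "ratio") -> EntropyComputation:
    """Compute entropy-reduction weights for each factor column."""
    x, codes = _as_matrix(panel)
    n = x.shape[0]
    if n < 2:
        raise ValueError("entropy weights require at least 2 experts")
    normalized = normalize_panel(x, mode=mode)
    k = 1.0 / np.log(n)
    E = np.ones(x.shape[1])
    degenerate = []
    for j in range(x.shape[1]):
        col = normalized[:, j]
        s = col.sum()
        if s <= 0 or x[:, j].max() == x[:, j].min():
            degenerate.append(codes[j])
            continue  # E stays 1, g = 0
        p = col / s  # rescale to column-stochastic shares
        nz = p[p > 0]
        E[j] = -k * float(np.sum(nz * np.log(nz)))
    g = 1.0 - E
    total = g.sum()
    uniform_fallback = False
    if total <= 0:
        logger.warning("all columns degenerate; falling back to uniform weights")
        w = np.full(x.shape[1], 1.0 / x.shape[1])
        uniform_fallback = True
    else:
        w = g / total
    # rank 1 = largest weight; ties broken by column (factor-code) order
    order = np.lexsort((np.arange(len(w)), -w))
    rank = np.empty(len(w), dtype=int)
    rank[order] = np.arange(1, len(w) + 1)
    idx = pd.Index(codes, name="factor")
    return EntropyComputation(
        normalized=normalized,
        k=k,
        E=pd.Series(E, index=idx, name="E"),
        g=pd.Series(g, index=idx, name="g"),
        w=pd.Series(w, index=idx, name="w"),
        rank=pd.Series(rank, index=idx, name="rank"),
        degenerate=tuple(degenerate),
        uniform_fallback=uniform_fallback,
    )
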