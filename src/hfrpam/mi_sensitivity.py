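"""Pairwise mutual information between factors and stage-anchored sensitivity.

MI is the plug-in estimate from the empirical joint table, in nats
(0 ln 0 = 0).  The default discretization keeps the five Likert categories
as-is; an equal-frequency binning utility is available as an option.

The sensitivity value of a factor is the mean of its MI with the two
primary (stage) factors, counting a factor's MI with itself as 0.  This
aggregation rule is an interpretation of an ambiguous published sentence;
it is the unique simple rule that reproduces every published sensitivity
value from the published MI matrix, and is flagged as such here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor_model import ExpertPanel, FactorHierarchy

__all__ = [
    "MIMatrix",
    "SensitivityVector",
    "discretize",
    "mutual_information",
    "entropy",
    "mi_matrix",
    "sensitivity_values",
    "round_half_away",
    "load_mi_matrix",
]

LN2 = math.log(2.0)


def round_half_away(x, decimals: int = 4):
    """Round half away from zero (display convention of the published tables)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    # small nudge so exact .5 values stored as ...4999 floats still round up
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5 + 1e-9) / factor
    return float(out) if out.ndim == 0 else out


def discretize(column, method: str = "raw", n_bins: int | None = None) -> np.ndarray:
    """Return integer category labels for a rating column.

    ``raw`` keeps the values as categories; ``equal_frequency`` splits ranks
    into ``n_bins`` (default ceil(sqrt(n))) near-equal groups, keeping tied
    values in a single bin.
    """
    col = np.asarray(column)
    if method == "raw":
        return col.copy()
    if method != "equal_frequency":
        raise ValueError(f"unknown discretization method {method!r}")
    n = len(col)
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n))
    labels = pd.qcut(col.astype(float), q=n_bins, labels=False, duplicates="drop")
    return np.asarray(labels, dtype=int)


def _joint_probs(x: np.ndarray, y: np.ndarray):
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return joint / n


def entropy(x, base: str = "nats") -> float:
    """Plug-in Shannon entropy of a categorical sample."""
    x = np.asarray(x)
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / LN2 if base == "bits" else h


def mutual_information(x, y, base: str = "nats") -> float:
    """I(X;Y) = sum_xy p(x,y) ln[p(x,y) / (p(x) p(y))] from the joint table."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("mutual information requires at least 2 observations")
    pxy = _joint_probs(x, y)
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / outer[mask])))
    mi = max(mi, 0.0)  # guard float noise; plug-in MI is non-negative
    return mi / LN2 if base == "bits" else mi


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric factor-by-factor MI matrix with an undefined (NaN) diagonal."""

    values: pd.DataFrame  # index and columns = factor codes

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValueError("MI matrix index and columns must match")
        off = v.to_numpy(dtype=float).copy()
        np.fill_diagonal(off, 0.0)
        if not np.allclose(off, off.T, atol=1e-12):
            raise ValueError("MI matrix must be symmetric")
        if np.nanmin(off) < -1e-12:
            raise ValueError("MI values must be non-negative")

    @property
    def factor_codes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def get(self, a: str, b: str) -> float:
        """MI(a, b), with the self entry counted as 0."""
        if a == b:
            return 0.0
        return float(self.values.loc[a, b])

    def to_csv_text(self, decimals: int | None = 4) -> str:
        df = self.values.copy()
        if decimals is not None:
            df = df.map(
                lambda v: "" if pd.isna(v) else f"{round_half_away(v, decimals):.{decimals}f}"
            )
        df = df.fillna("NA")
        return df.to_csv(index_label="code", na_rep="NA")


def mi_matrix(
    panel: ExpertPanel,
    method: str = "raw",
    n_bins: int | None = None,
    base: str = "nats",
) -> MIMatrix:
    """All 28 unordered pairwise MI values, mirrored, with NaN diagonal."""
    codes = list(panel.factor_codes)
    cols = {
        c: discretize(panel.column(c), method=method, n_bins=n_bins) for c in codes
    }
    k = len(codes)
    m = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            v = mutual_information(cols[codes[i]], cols[codes[j]], base=base)
            m[i, j] = m[j, i] = v
    return MIMatrix(values=pd.DataFrame(m, index=codes, columns=codes))


def load_mi_matrix(path) -> MIMatrix:
    """Read a factor-by-factor MI matrix CSV ('NA' diagonal accepted)."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MIMatrix(values=df.astype(float))


@dataclass(frozen=True)
class SensitivityVector:
    """Per-factor sensitivity value and activity rank (1 = most active)."""

    sv: pd.Series
    activity_rank: pd.Series

    def __post_init__(self) -> None:
        ranks = sorted(self.activity_rank)
        if ranks != list(range(1, len(self.sv) + 1)):
            raise ValueError("activity ranks must be a permutation of 1..k")


def sensitivity_values(
    mi: MIMatrix, hierarchy: FactorHierarchy
) -> SensitivityVector:
    """SV(f) = mean of MI(f, p) over the two primary factors p; self-MI = 0."""
    primaries = hierarchy.primary_factors
    codes = list(mi.factor_codes)
    sv = pd.Series(
        [float(np.mean([mi.get(f, p) for p in primaries])) for f in codes],
        index=pd.Index(codes, name="factor"),
        name="sv",
    )
    order = np.lexsort((np.arange(len(sv)), -sv.to_numpy()))
    rank = np.empty(len(sv), dtype=int)
    rank[order] = np.arange(1, len(sv) + 1)
    return SensitivityVector(
        sv=sv, activity_rank=pd.Series(rank, index=sv.index, name="activity_rank")
    )
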