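"""Panel quality control: internal consistency, content validity, test-retest
agreement, and per-factor descriptive moments.

Conventions fixed here: Cronbach's alpha from sample variances (ddof=1);
I-CVI counts ratings at or above a configurable relevance floor (default 4
on the 5-point scale) and S-CVI is the average of the I-CVIs; test-retest
agreement is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — with a McGraw-Wong confidence interval; skewness is the
adjusted Fisher-Pearson statistic and kurtosis is reported plain
(non-excess), flagged against |skew| < 3 and |kurt| < 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factor_model import ExpertPanel

__all__ = [
    "QCReport",
    "ICCResult",
    "cronbach_alpha",
    "content_validity",
    "icc_test_retest",
    "descriptives",
    "qc_report",
]

ALPHA_THRESHOLD = 0.7
I_CVI_THRESHOLD = 0.8
S_CVI_THRESHOLD = 0.9
ICC_THRESHOLD = 0.5
SKEW_THRESHOLD = 3.0
KURT_THRESHOLD = 10.0


def _as_matrix(panel) -> np.ndarray:
    if isinstance(panel, ExpertPanel):
        return np.asarray(panel.ratings, dtype=float)
    return np.asarray(panel, dtype=float)


def cronbach_alpha(panel) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    x = _as_matrix(panel)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("cronbach_alpha requires at least 2 rows and 2 columns")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def content_validity(
    relevance_ratings, relevant_min: int = 4
) -> tuple[np.ndarray, float]:
    """Item-level and scale-level content validity indices.

    I-CVI per item (column) = proportion of experts rating >= ``relevant_min``;
    S-CVI = mean of the I-CVIs (averaging convention).
    """
    x = _as_matrix(relevance_ratings)
    if x.size == 0:
        raise ValueError("empty relevance-rating matrix")
    if x.ndim == 1:
        x = x[:, None]
    i_cvi = (x >= relevant_min).mean(axis=0)
    return i_cvi, float(i_cvi.mean())


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_low: float
    ci_high: float

    def __float__(self) -> float:
        return self.value


def icc_test_retest(test, retest, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``test`` and ``retest`` are same-shape matrices (or vectors) of the two
    administrations; matrices are flattened cell-wise so every cell is a
    "subject" rated on two occasions.  The confidence interval follows
    McGraw & Wong (1996).
    """
    a = _as_matrix(test).ravel()
    b = _as_matrix(retest).ravel()
    if a.shape != b.shape:
        raise ValueError("test and retest must have identical shapes")
    n = a.size
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    y = np.column_stack([a, b])  # n subjects x k=2 occasions
    k = 2
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero variance in both administrations")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0 and msc <= 0:  # perfect agreement, CI collapses
        return ICCResult(float(icc), float(icc), float(icc))
    a_coef = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a_coef):
        num = (a_coef * msc + b_coef * mse) ** 2
        den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else n - 1
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lo = hi = 1.0
    return ICCResult(float(icc), float(lo), float(hi))


def descriptives(panel) -> pd.DataFrame:
    """Per-column mean, SD (ddof=1), skewness, kurtosis, and threshold flags.

    Constant columns get skewness/kurtosis 0 with ``degenerate=True``.
    """
    if isinstance(panel, ExpertPanel):
        codes = list(panel.factor_codes)
        x = np.asarray(panel.ratings, dtype=float)
    else:
        x = np.asarray(panel, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        codes = [f"col{j + 1}" for j in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("descriptives require at least 2 rows")
    rows = []
    for j, code in enumerate(codes):
        col = x[:, j]
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            skew = kurt = 0.0
        else:
            skew = float(stats.skew(col, bias=False))
            kurt = float(stats.kurtosis(col, bias=False, fisher=False))
        rows.append(
            {
                "factor": code,
                "mean": mean,
                "sd": sd,
                "skewness": skew,
                "kurtosis": kurt,
                "degenerate": degenerate,
                "skew_ok": abs(skew) < SKEW_THRESHOLD,
                "kurt_ok": abs(kurt) < KURT_THRESHOLD,
            }
        )
    return pd.DataFrame(rows).set_index("factor")


@dataclass(frozen=True)
class QCReport:
    cronbach_alpha: float
    i_cvi: tuple[float, ...]
    s_cvi: float
    icc: ICCResult | None
    per_factor: pd.DataFrame

    @property
    def warnings(self) -> list[str]:
        msgs = []
        if self.cronbach_alpha <= ALPHA_THRESHOLD:
            msgs.append(
                f"Cronbach's alpha {self.cronbach_alpha:.3f} <= {ALPHA_THRESHOLD}"
            )
        if any(v < I_CVI_THRESHOLD for v in self.i_cvi):
            msgs.append(f"some I-CVI below {I_CVI_THRESHOLD}")
        if self.s_cvi < S_CVI_THRESHOLD:
            msgs.append(f"S-CVI {self.s_cvi:.3f} < {S_CVI_THRESHOLD}")
        if self.icc is not None and self.icc.value < ICC_THRESHOLD:
            msgs.append(f"ICC {self.icc.value:.3f} < {ICC_THRESHOLD}")
        return msgs


def qc_report(
    panel: ExpertPanel,
    retest: ExpertPanel | None = None,
    relevant_min: int = 4,
) -> QCReport:
    """Run the full QC stage on a panel (ICC only when a retest is supplied)."""
    i_cvi, s_cvi = content_validity(panel.ratings, relevant_min=relevant_min)
    icc = None
    if retest is not None:
        icc = icc_test_retest(panel.ratings, retest.ratings)
    return QCReport(
        cronbach_alpha=cronbach_alpha(panel),
        i_cvi=tuple(float(v) for v in i_cvi),
        s_cvi=s_cvi,
        icc=icc,
        per_factor=descriptives(panel),
    )
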