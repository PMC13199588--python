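"""Pipeline orchestration: QC -> risk levels -> weights -> MI/sensitivity ->
optimization, plus the replay entry point that rebuilds the optimization
table from externally supplied weight and MI tables.

JSON is the canonical report format; CSV side files mirror the published
table layouts for human comparison.  Runs are deterministic given input
bytes and configuration, and the provenance digest changes iff either does.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bayes_risk import DenominatorConfig, RiskBandScheme, assess_risk
from .entropy_weights import entropy_weights
from .factor_model import (
    CorrelationAnchors,
    ExpertPanel,
    FactorHierarchy,
    default_hierarchy,
    read_panel,
)
from .mi_sensitivity import (
    MIMatrix,
    load_mi_matrix,
    mi_matrix,
    round_half_away,
    sensitivity_values,
)
from .optimization_path import build_optimization_records
from .psychometrics import qc_report

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "replay_tables",
    "load_weight_table",
    "reference_mi_matrix",
    "reference_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables, defaulting to the published-procedure-faithful choices."""

    anchors: CorrelationAnchors = field(default_factory=CorrelationAnchors)
    band_scheme: RiskBandScheme = field(default_factory=RiskBandScheme)
    denominators: DenominatorConfig = field(default_factory=DenominatorConfig)
    canonical_bayes: bool = False
    entropy_mode: str = "ratio"
    mi_method: str = "raw"
    mi_bins: int | None = None
    cvi_relevant_min: int = 4

    def to_dict(self) -> dict:
        return {
            "anchors": asdict(self.anchors),
            "band_scheme": asdict(self.band_scheme),
            "denominators": asdict(self.denominators),
            "canonical_bayes": self.canonical_bayes,
            "entropy_mode": self.entropy_mode,
            "mi_method": self.mi_method,
            "mi_bins": self.mi_bins,
            "cvi_relevant_min": self.cvi_relevant_min,
        }

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = {}
        if "anchors" in raw:
            kwargs["anchors"] = CorrelationAnchors(**raw["anchors"])
        if "band_scheme" in raw:
            kwargs["band_scheme"] = RiskBandScheme(**raw["band_scheme"])
        if "denominators" in raw:
            kwargs["denominators"] = DenominatorConfig(**raw["denominators"])
        for key in ("canonical_bayes", "entropy_mode", "mi_method", "mi_bins",
                    "cvi_relevant_min"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _digest(panel_bytes: bytes, config: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(panel_bytes)
    h.update(json.dumps(config.to_dict(), sort_keys=True).encode())
    h.update(__version__.encode())
    return h.hexdigest()


def _optimization_frame(records) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records]).set_index("factor")


def run_pipeline(
    panel_path,
    config: PipelineConfig | None = None,
    hierarchy: FactorHierarchy | None = None,
    out_dir=None,
) -> dict:
    """Execute all five stages on a panel file and return the JSON-able report.

    QC threshold violations are logged as warnings but never abort; a
    validation failure in any stage raises with the stage named.
    """
    if config is None:
        config = PipelineConfig()
    if hierarchy is None:
        hierarchy = default_hierarchy()
    panel_path = Path(panel_path)
    panel_bytes = panel_path.read_bytes()

    stage = "cleansing"
    try:
        panel = read_panel(panel_path, hierarchy)
        qc = qc_report(panel, relevant_min=config.cvi_relevant_min)
        for msg in qc.warnings:
            logger.warning("QC: %s", msg)

        stage = "risk_level"
        risk = assess_risk(
            panel,
            hierarchy,
            anchors=config.anchors,
            scheme=config.band_scheme,
            denominators=config.denominators,
            canonical=config.canonical_bayes,
        )

        stage = "risk_weight"
        ew = entropy_weights(panel, mode=config.entropy_mode)
        if ew.degenerate:
            logger.warning("degenerate (constant) columns: %s", ew.degenerate)

        stage = "sensitivity"
        mi = mi_matrix(panel, method=config.mi_method, n_bins=config.mi_bins)
        sv = sensitivity_values(mi, hierarchy)

        stage = "optimization"
        records = build_optimization_records(sv, ew.w, hierarchy)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "qc": {
            "cronbach_alpha": qc.cronbach_alpha,
            "i_cvi": list(qc.i_cvi),
            "s_cvi": qc.s_cvi,
            "icc": None,
            "per_factor": qc.per_factor.reset_index().to_dict(orient="records"),
            "warnings": qc.warnings,
        },
        "risk": risk.records.to_dict(orient="records"),
        "weights": ew.to_frame().reset_index().to_dict(orient="records"),
        "weights_uniform_fallback": ew.uniform_fallback,
        "mi_matrix": json.loads(
            mi.values.where(pd.notna(mi.values), None).to_json(orient="split")
        ),
        "sensitivity": {
            "sv": sv.sv.to_dict(),
            "activity_rank": sv.activity_rank.astype(int).to_dict(),
        },
        "optimization": [asdict(r) for r in records],
        "provenance": {
            "version": __version__,
            "config": config.to_dict(),
            "input_digest": _digest(panel_bytes, config),
            "panel_file": panel_path.name,
            "n_experts": panel.n_experts,
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        risk.records.to_csv(out / "risk.csv", index=False)
        ew.to_frame().to_csv(out / "weights.csv")
        (out / "mi_matrix.csv").write_text(mi.to_csv_text())
        _optimization_frame(records).to_csv(out / "optimization.csv")
    return report


def load_weight_table(path) -> pd.Series:
    """Read a factor weight table (columns ``code`` and ``weight_pct`` or ``w``).

    Percentages are converted to proportions.
    """
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    if "weight_pct" in df.columns:
        w = df["weight_pct"].astype(float) / 100.0
    elif "w" in df.columns:
        w = df["w"].astype(float)
    else:
        w = df.iloc[:, 0].astype(float)
        if w.sum() > 2.0:  # looks like percentages
            w = w / 100.0
    w.index = w.index.astype(str)
    w.name = "w"
    return w


def replay_tables(
    weights, mi: MIMatrix | str | Path, hierarchy: FactorHierarchy | None = None,
    decimals: int | None = 4,
) -> dict:
    """Rebuild the optimization table from supplied weight and MI tables.

    ``weights`` may be a Series of proportions or a CSV path; ``mi`` an
    :class:`MIMatrix` or a CSV path.  Factors are canonicalized to hierarchy
    order.  When ``decimals`` is set, SV and OI are additionally reported
    rounded half-away-from-zero for table comparison.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    if not isinstance(weights, pd.Series):
        weights = load_weight_table(weights)
    if not isinstance(mi, MIMatrix):
        mi = load_mi_matrix(mi)
    order = list(hierarchy.factors)
    weights = weights.reindex(order)
    if weights.isna().any():
        raise ValueError("weight table does not cover all hierarchy factors")
    mi = MIMatrix(values=mi.values.loc[order, order])
    sv = sensitivity_values(mi, hierarchy)
    records = build_optimization_records(sv, weights, hierarchy)
    out = {
        "sv": sv.sv.to_dict(),
        "weight": weights.to_dict(),
        "oi": {r.factor: r.oi for r in records},
        "activity_rank": {r.factor: r.activity_rank for r in records},
        "paths": [
            {"path_id": r.path_id, "factor": r.factor, "role": r.path_role,
             "label": r.path_label}
            for r in records
        ],
    }
    if decimals is not None:
        out["sv_rounded"] = {f: round_half_away(v, decimals) for f, v in out["sv"].items()}
        out["oi_rounded"] = {f: round_half_away(v, decimals) for f, v in out["oi"].items()}
    return out


def replay_frame(replay: dict, hierarchy: FactorHierarchy | None = None) -> pd.DataFrame:
    """Tabular (factor-per-column) view of a replay result."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    order = list(hierarchy.factors)
    roles = {p["factor"]: p for p in replay["paths"]}
    rows = {
        "SV": [replay["sv"][f] for f in order],
        "RL": [replay["weight"][f] for f in order],
        "OI": [replay["oi"][f] for f in order],
        "AS": [replay["activity_rank"][f] for f in order],
        "OP": [f"{roles[f]['path_id']}:{roles[f]['label']}" for f in order],
    }
    return pd.DataFrame(rows, index=order).T


def reference_mi_matrix() -> MIMatrix:
    """The bundled published MI matrix (replay input)."""
    with resources.files("hfrpam.data").joinpath("reference_mi_matrix.csv").open() as fh:
        return load_mi_matrix(fh)


def reference_weights() -> pd.Series:
    """The bundled published risk weights as proportions (replay input)."""
    with resources.files("hfrpam.data").joinpath("reference_weights.csv").open() as fh:
        return load_weight_table(fh)
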