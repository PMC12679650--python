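"""Config-driven end-to-end runner: read, match, model, compare, export.

A run reads index-trial IPD and a comparator target/effect configuration,
estimates MAIC weights (anchored and/or per-arm unanchored), fits the
weighted outcome models per endpoint, synthesizes the cross-trial
comparisons, and writes a balance table, per-subject weights, a forest
table and a JSON manifest that records inputs (hashed), seed, options and
machine-readable warnings — enough to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indirect_comparison import (
    ComparisonResult,
    RelativeEffect,
    Z95,
    bayes_fe_nma,
    bucher_combine,
    se_from_interval,
    unanchored_contrast,
)
from .maic_weights import (
    MatchSpec,
    WeightSet,
    fit_maic,
    weight_distribution_summary,
    weighted_baseline_table,
)
from .outcome_models import (
    build_change_outcomes,
    derive_composite_events,
    fit_mmrm,
    fit_weighted_cox,
)
from .trial_data import (
    DEFAULT_TIMEPOINT_MAP,
    AggregateTargets,
    ComparatorSummary,
    SubjectRecord,
    read_ipd,
    read_targets,
)

__all__ = ["RunConfig", "run_pipeline", "export_forest_table"]

logger = logging.getLogger(__name__)

ALL_ENDPOINTS = ("egfr", "upcr", "uacr", "composite")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    ipd: str
    targets: str
    output_dir: str
    mode: str = "anchored"  # anchored | unanchored | both
    endpoints: tuple[str, ...] = ALL_ENDPOINTS
    analysis_months: tuple[float, ...] = tuple(DEFAULT_TIMEPOINT_MAP.months)
    prior_sd: float = 100.0
    draws: int = 0
    seed: int = 0
    unanchored_active_targets: str | None = None
    unanchored_control_targets: str | None = None
    covariate_subsets: dict = field(default_factory=dict)  # endpoint -> list of covariates

    def __post_init__(self) -> None:
        if self.mode not in ("anchored", "unanchored", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        bad = set(self.endpoints) - set(ALL_ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoints {sorted(bad)}")
        for path_attr in ("ipd", "targets"):
            if not Path(getattr(self, path_attr)).exists():
                raise FileNotFoundError(f"{path_attr} file not found: {getattr(self, path_attr)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["endpoints"] = tuple(doc.get("endpoints", ALL_ENDPOINTS))
        if "analysis_months" in doc:
            doc["analysis_months"] = tuple(float(t) for t in doc["analysis_months"])
        return cls(**doc)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _endpoint_scale(endpoint: str) -> str:
    return {"egfr": "mean_difference", "upcr": "log_gmr", "uacr": "log_gmr", "composite": "log_hr"}[
        endpoint
    ]


def _anchored_results(
    records: Sequence[SubjectRecord],
    weights: WeightSet,
    summary: ComparatorSummary,
    cfg: RunConfig,
    warnings_out: list[str],
) -> list[ComparisonResult]:
    results: list[ComparisonResult] = []
    arms = {r.subject_id: r.arm for r in records}
    for ep in cfg.endpoints:
        scale = _endpoint_scale(ep)
        if ep == "composite":
            events = derive_composite_events(records)
            fit = fit_weighted_cox(events, arms, weights)
            if fit.degenerate:
                warnings_out.append("composite: no events in one arm; comparison skipped")
                continue
            pairs = [("overall", fit.log_hr, fit.se)]
        else:
            table = build_change_outcomes(records, ep)
            mfit = fit_mmrm(
                table,
                weights,
                scale="absolute_change" if ep == "egfr" else "log_ratio",
                visits=[t for t in cfg.analysis_months if t in set(table["month"])],
            )
            if mfit.used_cs_fallback:
                warnings_out.append(f"{ep}: MMRM fell back to compound symmetry")
            pairs = [(t, *mfit.contrast_at(t)) for t in mfit.visits]
        for timepoint, est, se in pairs:
            try:
                pub = summary.lookup(ep, timepoint)
            except KeyError:
                warnings_out.append(f"{ep}@{timepoint}: no published comparator effect; skipped")
                continue
            index_eff = RelativeEffect(scale, timepoint, est, se, source="index_weighted")
            comp_eff = RelativeEffect(
                scale,
                timepoint,
                pub.estimate,
                se_from_interval(pub.lower, pub.upper, pub.interval_type, scale="mean_difference"),
                source="comparator_published",
            )
            results.append(bucher_combine(index_eff, comp_eff, endpoint=ep))
            results.append(
                bayes_fe_nma(
                    index_eff,
                    comp_eff,
                    prior_sd=cfg.prior_sd,
                    draws=cfg.draws,
                    seed=cfg.seed,
                    endpoint=ep,
                )
            )
    return results


def _unanchored_results(
    records: Sequence[SubjectRecord],
    active_weights: WeightSet,
    summary: ComparatorSummary,
    cfg: RunConfig,
    warnings_out: list[str],
) -> list[ComparisonResult]:
    """Weighted index active-arm summaries vs published comparator active arm."""
    results: list[ComparisonResult] = []
    active = [r for r in records if r.arm == "active"]
    arms = {r.subject_id: r.arm for r in records}
    for ep in cfg.endpoints:
        scale = _endpoint_scale(ep)
        if ep == "composite":
            # an arm-level hazard cannot be contrasted without a common anchor
            # unless the comparator publishes an absolute hazard; skipped here
            warnings_out.append("composite: unanchored mode reports no comparison")
            continue
        table = build_change_outcomes(active, ep)
        mfit = fit_mmrm(
            table,
            active_weights,
            scale="absolute_change" if ep == "egfr" else "log_ratio",
            visits=[t for t in cfg.analysis_months if t in set(table["month"])],
        )
        for t in mfit.visits:
            row = mfit.ls_means[(mfit.ls_means["arm"] == "active") & (mfit.ls_means["month"] == t)]
            est, se = float(row["estimate"].iloc[0]), float(row["se"].iloc[0])
            try:
                pub = summary.lookup(ep, t, level="arm", arm="active")
            except KeyError:
                warnings_out.append(f"{ep}@{t}: no published comparator arm summary; skipped")
                continue
            pub_se = se_from_interval(pub.lower, pub.upper, pub.interval_type, "mean_difference")
            results.append(
                unanchored_contrast((est, se), (pub.estimate, pub_se), scale, t, endpoint=ep)
            )
    return results


def export_forest_table(results: Sequence[ComparisonResult], path: str | Path) -> pd.DataFrame:
    """One row per (endpoint, timepoint, method), canonically ordered."""
    if not results:
        raise ValueError("no comparison results to export")
    rows = [
        {
            "endpoint": r.endpoint,
            "timepoint": r.timepoint,
            "method": r.method,
            "estimate": r.estimate,
            "lower": r.lower,
            "upper": r.upper,
            "scale": r.scale,
            "interval_type": r.interval_type,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    keys = df[["endpoint", "timepoint", "method"]].astype(str).agg("|".join, axis=1)
    if keys.duplicated().any():
        raise ValueError(f"duplicate forest rows: {sorted(keys[keys.duplicated()])}")
    df = df.sort_values(["endpoint", "timepoint", "method"], key=lambda s: s.astype(str))
    df = df.reset_index(drop=True)
    df.to_csv(path, index=False)  # default str() formatting round-trips floats
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_out: list[str] = []

    records = read_ipd(cfg.ipd)
    targets, summary = read_targets(cfg.targets)
    logger.info("read %d subjects, %d targets", len(records), len(targets))

    results: list[ComparisonResult] = []
    weight_summaries: dict[str, dict] = {}

    if cfg.mode in ("anchored", "both"):
        ws = fit_maic(records, MatchSpec("anchored", targets))
        if ws.excluded_subjects:
            warnings_out.append(
                f"anchored: excluded {len(ws.excluded_subjects)} incomplete subjects"
            )
        ws.as_series().to_csv(out / "weights_anchored.csv", header=True, index_label="subject_id")
        weighted_baseline_table(records, ws, targets).to_csv(
            out / "baseline_table.csv", index=False, float_format="%.6f"
        )
        weight_summaries["anchored"] = weight_distribution_summary(ws.weights)
        weight_summaries["anchored"]["beta"] = [float(b) for b in ws.beta]
        weight_summaries["anchored"]["gradient_norm"] = ws.gradient_norm
        weight_summaries["anchored"]["iterations"] = ws.iterations
        results += _anchored_results(records, ws, summary, cfg, warnings_out)

    if cfg.mode in ("unanchored", "both"):
        t_active = targets
        if cfg.unanchored_active_targets:
            t_active, _ = read_targets(cfg.unanchored_active_targets)
        ws_a = fit_maic(records, MatchSpec("unanchored_active", t_active))
        ws_a.as_series().to_csv(
            out / "weights_unanchored_active.csv", header=True, index_label="subject_id"
        )
        weight_summaries["unanchored_active"] = weight_distribution_summary(ws_a.weights)
        results += _unanchored_results(records, ws_a, summary, cfg, warnings_out)

    forest = export_forest_table(results, out / "forest_table.csv") if results else None
    if forest is None:
        warnings_out.append("no comparisons produced (missing comparator effects?)")

    manifest = {
        "package": {"name": "maictools", "version": __version__},
        "versions": _library_versions(),
        "inputs": {
            "ipd": {"path": str(cfg.ipd), "sha256": _sha256(cfg.ipd)},
            "targets": {"path": str(cfg.targets), "sha256": _sha256(cfg.targets)},
        },
        "options": {
            "mode": cfg.mode,
            "endpoints": list(cfg.endpoints),
            "analysis_months": list(cfg.analysis_months),
            "prior_sd": cfg.prior_sd,
            "draws": cfg.draws,
            "seed": cfg.seed,
            "z_multiplier": Z95,
            "weight_gradient_tol_per_subject": 1e-10,
            "mmrm_rel_tol": 1e-8,
        },
        "counts": {
            "subjects_read": len(records),
            "comparisons": 0 if forest is None else int(len(forest)),
        },
        "weights": weight_summaries,
        "warnings": warnings_out,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _library_versions() -> dict[str, str]:
    import lifelines
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
    }
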