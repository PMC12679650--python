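"""Method-of-moments MAIC weight estimation, ESS, and balance diagnostics.

MAIC reweights the index trial's IPD so its covariate moments equal the
comparator trial's published aggregates.  With the matching matrix centered
at the targets (columns c_j = x_j - target_j), the weights take the
exponential-tilting form w_i = exp(c_i' beta), where beta is the unique
minimizer of the convex objective

    Q(beta) = sum_i exp(c_i' beta).

The gradient of Q is the weighted sum of the centered covariates, so the
first-order condition is exactly the moment-matching condition: every
weighted covariate mean equals its target.  The information carried by the
weighted sample is summarized by the effective sample size
ESS = (sum w)^2 / sum w^2.

Anchored matching pools both randomized arms into one fit (the within-trial
randomization is preserved because every subject is reweighted by baseline
covariates only); unanchored matching fits each arm to its counterpart arm
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_data import (
    AggregateTargets,
    SubjectRecord,
    complete_case_filter,
    derive_threshold_indicators,
)

__all__ = [
    "MatchSpec",
    "WeightSet",
    "center_covariates",
    "estimate_weights",
    "effective_sample_size",
    "fit_maic",
    "weighted_baseline_table",
    "weight_distribution_summary",
]

logger = logging.getLogger(__name__)

MODES = ("anchored", "unanchored_active", "unanchored_control")

GRADIENT_TOL_PER_N = 1e-10
MAX_NEWTON_ITER = 200
COLLINEARITY_TOL = 1e-10  # drop centered columns with |corr| > 1 - tol


@dataclass(frozen=True)
class MatchSpec:
    """Which subjects enter the weight fit and against which targets."""

    mode: str
    target_set: AggregateTargets
    covariate_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def targets(self) -> AggregateTargets:
        if self.covariate_subset is None:
            return self.target_set
        return self.target_set.subset(self.covariate_subset)

    def select(self, records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
        if self.mode == "anchored":
            return list(records)
        arm = "active" if self.mode == "unanchored_active" else "control"
        return [r for r in records if r.arm == arm]


@dataclass
class WeightSet:
    """Estimated MAIC weights plus solver diagnostics.

    ``weights`` are rescaled to sum to the number of weighted subjects for
    reporting; every downstream quantity (ESS, weighted moments, outcome
    models) is invariant to that rescaling.
    """

    subject_ids: list[str]
    weights: np.ndarray
    beta: np.ndarray
    matched_labels: list[str]
    ess: float
    converged: bool
    gradient_norm: float
    iterations: int
    excluded_subjects: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)
    balanced_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("all weights must be positive")

    @property
    def n(self) -> int:
        return len(self.weights)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.subject_ids, name="weight")


def center_covariates(
    matrix: pd.DataFrame | np.ndarray, targets: AggregateTargets
) -> tuple[np.ndarray, list[bool]]:
    """Subtract each target from its covariate column.

    Returns the centered matrix and a per-column "already balanced" flag
    (a column constant at its target centers to exactly zero).  A target
    outside the open range of its column makes the moment condition
    infeasible — no positive weights can satisfy it — and raises.
    """
    X = np.asarray(matrix, dtype=float)
    vals = targets.values
    if X.ndim != 2 or X.shape[1] != len(vals):
        raise ValueError(f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, expected {len(vals)}")
    balanced: list[bool] = []
    centered = X - vals
    for j, m in enumerate(targets):
        col = X[:, j]
        if np.all(col == col[0]):
            if np.isclose(col[0], vals[j], rtol=0, atol=1e-12):
                balanced.append(True)
                continue
            raise ValueError(f"infeasible target for {m.label}: column is constant at {col[0]!r}")
        if not (col.min() < vals[j] < col.max()):
            raise ValueError(
                f"infeasible target for {m.label}: {vals[j]!r} outside observed range "
                f"({col.min()!r}, {col.max()!r})"
            )
        balanced.append(False)
    return centered, balanced


def _drop_collinear(centered: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, list[int], list[str]]:
    """Drop later columns that are near-perfectly correlated with earlier ones."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(centered.shape[1]):
        col = centered[:, j]
        if np.allclose(col, 0.0):
            keep.append(j)  # balanced columns are handled upstream
            continue
        redundant = False
        for k in keep:
            other = centered[:, k]
            if np.allclose(other, 0.0):
                continue
            denom = np.linalg.norm(col) * np.linalg.norm(other)
            if denom > 0 and abs(float(col @ other)) / denom > 1.0 - COLLINEARITY_TOL:
                redundant = True
                break
        if redundant:
            dropped.append(labels[j])
            logger.warning("dropping collinear centered column %r", labels[j])
        else:
            keep.append(j)
    return centered[:, keep], keep, dropped


def _objective(C: np.ndarray, beta: np.ndarray) -> tuple[float, np.ndarray]:
    w = np.exp(np.clip(C @ beta, -700.0, 700.0))
    return float(w.sum()), w


def _solve_beta(C: np.ndarray) -> tuple[np.ndarray, float, int, bool]:
    """Damped Newton with backtracking line search on Q(beta) = sum exp(C beta)."""
    n, k = C.shape
    beta = np.zeros(k)
    tol = GRADIENT_TOL_PER_N * n
    iters = 0
    for iters in range(1, MAX_NEWTON_ITER + 1):
        q0, w = _objective(C, beta)
        grad = C.T @ w
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= tol:
            return beta, gnorm, iters - 1, True
        H = (C * w[:, None]).T @ C
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        while t > 1e-14:
            cand = beta - t * step
            qc = _objective(C, cand)[0]
            # near the optimum the true decrease drops below float precision;
            # accept a non-increasing full step so Newton can finish quadratically
            if qc < q0 or (t == 1.0 and qc <= q0 * (1.0 + 1e-12)):
                beta = cand
                break
            t *= 0.5
        else:
            break  # no descent direction left; report current gradient
    _, w = _objective(C, beta)
    gnorm = float(np.linalg.norm(C.T @ w))
    return beta, gnorm, iters, gnorm <= tol


def estimate_weights(
    centered: np.ndarray,
    spec: MatchSpec | None = None,
    *,
    labels: Sequence[str] | None = None,
    subject_ids: Sequence[str] | None = None,
    excluded_subjects: Sequence[str] | None = None,
    balanced: Sequence[bool] | None = None,
) -> WeightSet:
    """Solve the method-of-moments weights from a centered matching matrix.

    Weights are ``exp(c_i' beta)`` with beta minimizing ``sum_i exp(c_i' beta)``
    (damped Newton from beta = 0, gradient tolerance 1e-10 per subject).
    At the optimum every weighted centered column averages to zero, i.e.
    every weighted moment equals its target.
    """
    C = np.asarray(centered, dtype=float)
    if C.ndim != 2 or C.shape[0] == 0:
        raise ValueError("centered matrix must be 2-D and non-empty")
    n, k = C.shape
    labels = list(labels) if labels is not None else [f"c{j}" for j in range(k)]
    balanced_cols = [labels[j] for j in range(k) if (balanced is not None and balanced[j])]

    # zero (balanced) columns contribute nothing to the fit
    active = [j for j in range(k) if not np.allclose(C[:, j], 0.0)]
    active_labels = [labels[j] for j in active]
    C_active, keep_rel, dropped = _drop_collinear(C[:, active], active_labels)
    kept_labels = [active_labels[j] for j in keep_rel]

    if C_active.shape[1] == 0:
        weights = np.ones(n)
        beta_full = np.zeros(0)
        gnorm, iters, ok = 0.0, 0, True
    else:
        beta_full, gnorm, iters, ok = _solve_beta(C_active)
        weights = np.exp(C_active @ beta_full)
    if not ok:
        raise RuntimeError(
            f"MAIC weight solver did not converge after {MAX_NEWTON_ITER} iterations "
            f"(gradient norm {gnorm:.3e})"
        )
    weights = weights * (n / weights.sum())  # presentation rescaling; ESS-invariant
    return WeightSet(
        subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)],
        weights=weights,
        beta=beta_full,
        matched_labels=kept_labels,
        ess=effective_sample_size(weights),
        converged=ok,
        gradient_norm=gnorm,
        iterations=iters,
        excluded_subjects=list(excluded_subjects or []),
        dropped_columns=dropped,
        balanced_columns=balanced_cols,
    )


def effective_sample_size(weights: Sequence[float] | np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2; scale-invariant."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return float(w.sum() ** 2 / (w**2).sum())


def fit_maic(records: Sequence[SubjectRecord], spec: MatchSpec) -> WeightSet:
    """End-to-end weight fit: arm selection, complete-case filtering,
    indicator derivation, centering, and the Newton solve."""
    selected = spec.select(records)
    targets = spec.targets
    kept, excluded = complete_case_filter(selected, targets)
    if excluded:
        logger.info("excluding %d subjects with missing matching covariates", len(excluded))
    if not kept:
        raise ValueError("no complete-case subjects available for weighting")
    X = derive_threshold_indicators(kept, targets)
    centered, balanced = center_covariates(X, targets)
    return estimate_weights(
        centered,
        spec,
        labels=targets.labels,
        subject_ids=[r.subject_id for r in kept],
        excluded_subjects=excluded,
        balanced=balanced,
    )


def weighted_baseline_table(
    records: Sequence[SubjectRecord],
    weights: WeightSet,
    targets: AggregateTargets,
) -> pd.DataFrame:
    """Three-column balance table (unweighted, target, weighted).

    Proportions are reported on the percentage scale, continuous means on
    their natural scale.  The weighted column reproduces the target column
    for every matched moment (to solver tolerance).
    """
    by_id = {r.subject_id: r for r in records}
    try:
        kept = [by_id[s] for s in weights.subject_ids]
    except KeyError as e:
        raise ValueError(f"weight set refers to unknown subject {e}") from None
    if len(kept) != weights.n:
        raise ValueError("record/weight length mismatch")
    X = derive_threshold_indicators(kept, targets).to_numpy()
    w = weights.weights
    unweighted = X.mean(axis=0)
    weighted = (w[:, None] * X).sum(axis=0) / w.sum()
    rows = []
    for j, m in enumerate(targets):
        scale = 100.0 if m.is_proportion else 1.0
        rows.append(
            {
                "parameter": m.label + (" (%)" if m.is_proportion else ""),
                "unweighted": unweighted[j] * scale,
                "target": m.value * scale,
                "weighted": weighted[j] * scale,
            }
        )
    return pd.DataFrame(rows)


#: Histogram bin edges for relative weights (w / mean w); recorded in manifests.
WEIGHT_HIST_EDGES = np.concatenate([np.arange(0.0, 5.25, 0.25), [np.inf]])


def weight_distribution_summary(weights: Sequence[float] | np.ndarray) -> dict:
    """Deterministic, permutation-invariant summary of the weight distribution."""
    w = np.sort(np.asarray(weights, dtype=float))
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("weights must be a non-empty positive vector")
    rel = w / w.mean()
    qs = [0.0, 0.05, 0.25, 0.5, 0.75, 0.95, 1.0]
    hist, _ = np.histogram(rel, bins=WEIGHT_HIST_EDGES)
    return {
        "n": int(w.size),
        "ess": effective_sample_size(w),
        "quantiles": {f"q{int(q * 100):02d}": float(np.quantile(w, q)) for q in qs},
        "max_min_ratio": float(w[-1] / w[0]),
        "relative_histogram": {
            "edges": [float(e) for e in WEIGHT_HIST_EDGES],
            "counts": [int(c) for c in hist],
        },
    }
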