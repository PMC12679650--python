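"""Weighted outcome models for the index trial's IPD.

Three endpoints drive the comparison:

* absolute change from baseline in eGFR at each analysis visit;
* log post-baseline/baseline ratios of UPCR and UACR (reported as geometric
  mean ratios or percent changes after back-transformation);
* a composite time-to-event endpoint (confirmed 40% eGFR reduction, ESKD,
  or all-cause death).

Longitudinal endpoints are fitted with a mixed-effects model for repeated
measures (MMRM): fixed effects for treatment, visit, baseline, baseline-by-
visit and treatment-by-visit, an unstructured within-subject residual
covariance estimated by restricted maximum likelihood (EM iterations over
a profiled generalized-least-squares fit), and MAIC weights entering as
fixed subject-level frequency weights.  Contrast standard errors use a
robust (sandwich) estimator clustered on subject, treating the weights as
fixed.  The composite endpoint uses a weighted Cox proportional-hazards
model (Efron ties, robust variance) from lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maic_weights import WeightSet
from .trial_data import SubjectRecord

__all__ = [
    "MMRMFit",
    "CompositeEvent",
    "CoxFit",
    "build_change_outcomes",
    "fit_mmrm",
    "derive_composite_events",
    "fit_weighted_cox",
]

logger = logging.getLogger(__name__)

MMRM_REL_TOL = 1e-8
MMRM_MAX_ITER = 100


# ---------------------------------------------------------------------------
# Change-from-baseline outcome construction


def build_change_outcomes(
    records: Sequence[SubjectRecord], endpoint: str
) -> pd.DataFrame:
    """Long outcome table for one endpoint.

    eGFR yields ``y = visit - baseline`` with the raw baseline as covariate;
    UPCR/UACR yield ``y = ln(visit / baseline)`` with the log baseline as
    covariate.  Missing visit values stay missing (NaN rows are omitted);
    ratio-endpoint subjects with baseline 0 (log undefined) are excluded
    with a log entry.
    """
    if endpoint not in ("egfr", "upcr", "uacr"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    log_scale = endpoint != "egfr"
    rows = []
    excluded = []
    for r in records:
        base = getattr(r, f"{endpoint}_baseline")
        if base is None:
            excluded.append(r.subject_id)
            continue
        if log_scale and base <= 0:
            excluded.append(r.subject_id)
            continue
        baseline_cov = float(np.log(base)) if log_scale else float(base)
        for v in r.visits:
            val = getattr(v, endpoint)
            if val is None:
                continue
            if log_scale:
                if val <= 0:
                    continue  # log-ratio undefined; value stays out of the likelihood
                y = float(np.log(val / base))
            else:
                y = float(val - base)
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "arm": r.arm,
                    "month": v.month,
                    "baseline": baseline_cov,
                    "y": y,
                }
            )
    if excluded:
        logger.info(
            "%s endpoint: excluded %d subjects with unusable baseline (%s...)",
            endpoint,
            len(excluded),
            ", ".join(excluded[:5]),
        )
    return pd.DataFrame(rows, columns=["subject_id", "arm", "month", "baseline", "y"])


# ---------------------------------------------------------------------------
# MMRM


@dataclass
class MMRMFit:
    """Fitted repeated-measures model on one endpoint scale."""

    visits: list[float]
    ls_means: pd.DataFrame  # arm, month, estimate, se
    contrasts: pd.DataFrame  # month, estimate, se (active minus control)
    residual_covariance: pd.DataFrame
    scale: str  # absolute_change | log_ratio
    n_used: int
    converged: bool
    iterations: int
    reml_loglik: float
    beta: np.ndarray = field(repr=False, default=None)
    cov_beta: np.ndarray = field(repr=False, default=None)
    used_cs_fallback: bool = False

    def contrast_at(self, month: float) -> tuple[float, float]:
        row = self.contrasts[self.contrasts["month"] == month]
        if row.empty:
            raise KeyError(f"no contrast at month {month}")
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])


def _design_row(trt: int, visit_ix: int, baseline: float, m: int) -> np.ndarray:
    """Fixed effects: intercept, treatment, visit, baseline, baseline:visit,
    treatment:visit (reference level = first visit)."""
    p = 3 + 3 * (m - 1)
    x = np.zeros(p)
    x[0] = 1.0
    x[1] = trt
    if visit_ix > 0:
        x[1 + visit_ix] = 1.0  # visit dummy
    x[m + 1] = baseline
    if visit_ix > 0:
        x[m + 1 + visit_ix] = baseline  # baseline:visit
        x[2 * m + visit_ix] = trt  # treatment:visit
    return x


def _design_labels(vlist: Sequence[float], keep: np.ndarray) -> list[str]:
    later = [f"{v:g}" for v in vlist[1:]]
    full = (
        ["intercept", "treatment"]
        + [f"visit[{v}]" for v in later]
        + ["baseline"]
        + [f"baseline:visit[{v}]" for v in later]
        + [f"treatment:visit[{v}]" for v in later]
    )
    return [lab for lab, k in zip(full, keep) if k]


def _nearest_pd(S: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    floor = max(vals.max(), 1e-12) * floor_frac
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _cs_project(S: np.ndarray) -> np.ndarray:
    """Project a covariance onto compound symmetry (equal variance/covariance)."""
    m = S.shape[0]
    var = float(np.mean(np.diag(S)))
    if m == 1:
        return np.array([[max(var, 1e-12)]])
    off = float((S.sum() - np.trace(S)) / (m * (m - 1)))
    rho = np.clip(off / var if var > 0 else 0.0, -1.0 / (m - 1) + 1e-6, 1 - 1e-6)
    return var * ((1 - rho) * np.eye(m) + rho * np.ones((m, m)))


def fit_mmrm(
    outcomes: pd.DataFrame,
    weights: WeightSet | Mapping[str, float] | None = None,
    *,
    scale: str = "absolute_change",
    visits: Sequence[float] | None = None,
) -> MMRMFit:
    """Fit the weighted MMRM by EM-REML over the unstructured covariance.

    ``outcomes`` is the long table from :func:`build_change_outcomes`.
    Subjects absent from the weight set are excluded (they were excluded
    from matching); ``weights=None`` means uniform.  LS means are evaluated
    at the weighted mean baseline of the analysis population.
    """
    df = outcomes.dropna(subset=["y"]).copy()
    if visits is not None:
        df = df[df["month"].isin(list(visits))]
    vlist = sorted(df["month"].unique()) if visits is None else sorted(visits)
    m = len(vlist)
    if m == 0:
        raise ValueError("no post-baseline observations at the requested visits")
    vix = {v: i for i, v in enumerate(vlist)}

    if isinstance(weights, WeightSet):
        wmap = dict(zip(weights.subject_ids, weights.weights))
    elif weights is None:
        wmap = None
    else:
        wmap = dict(weights)
    if wmap is not None:
        dropped = sorted(set(df["subject_id"]) - set(wmap))
        if dropped:
            logger.info("MMRM: dropping %d subjects without weights", len(dropped))
        df = df[df["subject_id"].isin(wmap)]

    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        arm = grp["arm"].iloc[0]
        trt = 1 if arm == "active" else 0
        base = float(grp["baseline"].iloc[0])
        mask = np.zeros(m, dtype=bool)
        yfull = np.zeros(m)
        for _, row in grp.iterrows():
            i = vix[row["month"]]
            mask[i] = True
            yfull[i] = row["y"]
        Xfull = np.stack([_design_row(trt, i, base, m) for i in range(m)])
        w = 1.0 if wmap is None else float(wmap[sid])
        subjects.append((sid, trt, base, mask, yfull, Xfull, w))
    n = len(subjects)
    present_arms = sorted({t for _, t, *_ in subjects})
    two_arm = len(present_arms) == 2
    if n < 2 or (two_arm and n < 4):
        raise ValueError("MMRM needs at least two subjects per arm with post-baseline data")
    # single-arm (arm-level) fits drop the treatment and treatment:visit terms
    p_full = 3 + 3 * (m - 1)
    keep = np.ones(p_full, dtype=bool)
    if not two_arm:
        keep[1] = False
        keep[2 * m + 1 : 3 * m] = False
    subjects = [
        (sid, trt, base, mask, yfull, Xfull[:, keep], w)
        for sid, trt, base, mask, yfull, Xfull, w in subjects
    ]
    p = int(keep.sum())

    # group by missingness pattern for vectorized E/M steps
    patterns: dict[tuple, dict] = {}
    for sid, trt, base, mask, yfull, Xfull, w in subjects:
        key = tuple(mask)
        g = patterns.setdefault(key, {"Y": [], "X": [], "w": [], "Xf": [], "sid": []})
        g["Y"].append(yfull[mask])
        g["X"].append(Xfull[mask])
        g["Xf"].append(Xfull)
        g["w"].append(w)
        g["sid"].append(sid)
    for key, g in patterns.items():
        g["Y"] = np.asarray(g["Y"])  # (ng, o)
        g["X"] = np.asarray(g["X"])  # (ng, o, p)
        g["Xf"] = np.asarray(g["Xf"])  # (ng, m, p)
        g["w"] = np.asarray(g["w"])
        g["obs"] = np.flatnonzero(np.asarray(key))
        g["mis"] = np.flatnonzero(~np.asarray(key))
    W = sum(float(g["w"].sum()) for g in patterns.values())

    # initial covariance: per-visit weighted variance of OLS residuals
    allX = np.concatenate([g["X"].reshape(-1, p) for g in patterns.values()])
    allY = np.concatenate([g["Y"].reshape(-1) for g in patterns.values()])
    allW = np.concatenate([np.repeat(g["w"], g["X"].shape[1]) for g in patterns.values()])
    sw = np.sqrt(allW)
    beta0 = np.linalg.lstsq(allX * sw[:, None], allY * sw, rcond=None)[0]
    res0 = allY - allX @ beta0
    s2 = float(np.sum(allW * res0**2) / allW.sum())
    Sigma = np.eye(m) * max(s2, 1e-10)

    # aliased-term check on the pooled design (rank of X'X)
    labels = _design_labels(vlist, keep)
    XtX = (allX * allW[:, None]).T @ allX
    svals = np.linalg.svd(XtX, compute_uv=False)
    if svals[-1] <= 1e-10 * svals[0]:
        null = np.linalg.svd(XtX)[2][-1]
        aliased = [labels[j] for j in np.flatnonzero(np.abs(null) > 0.3)]
        raise ValueError(f"singular MMRM design; aliased terms: {', '.join(aliased)}")

    beta = beta0
    loglik = -np.inf
    converged = False
    used_cs = False
    iters = 0
    for iters in range(1, MMRM_MAX_ITER + 1):
        # GLS step given Sigma
        A = np.zeros((p, p))
        b = np.zeros(p)
        for g in patterns.values():
            So = Sigma[np.ix_(g["obs"], g["obs"])]
            g["Soi"] = np.linalg.inv(So)
            g["logdet"] = float(np.linalg.slogdet(So)[1])
            SX = np.einsum("ou,nup->nop", g["Soi"], g["X"])  # Soi @ X_i
            g["SX"] = SX
            A += np.einsum("n,nop,noq->pq", g["w"], g["X"], SX)
            b += np.einsum("n,nop,no->p", g["w"], SX, g["Y"])
        A = (A + A.T) / 2.0
        G = np.linalg.inv(A)
        beta = G @ b

        # REML log-likelihood and EM covariance update
        ll = -0.5 * float(np.linalg.slogdet(A)[1])
        Snew = np.zeros((m, m))
        for g in patterns.values():
            obs, mis = g["obs"], g["mis"]
            R = g["Y"] - np.einsum("nop,p->no", g["X"], beta)  # (ng, o)
            SoiR = np.einsum("ou,nu->no", g["Soi"], R)
            ll += -0.5 * float(
                np.sum(g["w"] * (g["logdet"] + np.einsum("no,no->n", R, SoiR)))
            )
            # conditional residual expectation and variance
            Ehat = np.zeros((len(g["w"]), m))
            Ehat[:, obs] = R
            H = np.array(g["Xf"], copy=True)  # (ng, m, p)
            if mis.size:
                B = Sigma[np.ix_(mis, obs)] @ g["Soi"]  # (mm, oo)
                Ehat[:, mis] = np.einsum("mo,no->nm", B, R)
                H[:, mis, :] = g["Xf"][:, mis, :] - np.einsum("mo,nop->nmp", B, g["X"])
                Cmm = Sigma[np.ix_(mis, mis)] - B @ Sigma[np.ix_(obs, mis)]
                Snew[np.ix_(mis, mis)] += float(g["w"].sum()) * Cmm
            Snew += np.einsum("n,nj,nk->jk", g["w"], Ehat, Ehat)
            HG = np.einsum("njp,pq->njq", H, G)
            Snew += np.einsum("n,njq,nkq->jk", g["w"], HG, H)
        Snew /= W
        Snew = (Snew + Snew.T) / 2.0
        if np.linalg.eigvalsh(Snew).min() <= 0:
            Snew = _nearest_pd(Snew)

        if np.isfinite(loglik) and abs(ll - loglik) <= MMRM_REL_TOL * (abs(loglik) + 1.0):
            loglik = ll
            converged = True
            break
        loglik = ll
        Sigma = Snew
    if not converged:
        # compound-symmetry fallback keeps the fit usable when the
        # unstructured REML surface fails to stabilize
        warnings.warn("MMRM covariance did not converge; falling back to compound symmetry")
        used_cs = True
        Sigma = _cs_project(Sigma)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for g in patterns.values():
            So = Sigma[np.ix_(g["obs"], g["obs"])]
            g["Soi"] = np.linalg.inv(So)
            SX = np.einsum("ou,nup->nop", g["Soi"], g["X"])
            A += np.einsum("n,nop,noq->pq", g["w"], g["X"], SX)
            b += np.einsum("n,nop,no->p", g["w"], SX, g["Y"])
        A = (A + A.T) / 2.0
        G = np.linalg.inv(A)
        beta = G @ b

    # Sandwich covariance clustered on subject, weights treated as fixed,
    # with the Bell-McCaffrey CR2 leverage adjustment: working in the
    # Sigma^(-1/2)-transformed space, each cluster's residual is rescaled by
    # (I - P_i)^(-1/2) where P_i is its own GLS leverage.  The unadjusted
    # (CR0) sandwich is biased downward when weights are skewed.
    M = np.zeros((p, p))
    for g in patterns.values():
        So = Sigma[np.ix_(g["obs"], g["obs"])]
        evals, evecs = np.linalg.eigh(So)
        T = (evecs / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T  # So^(-1/2)
        R = g["Y"] - np.einsum("nop,p->no", g["X"], beta)
        sw = np.sqrt(g["w"])
        U = sw[:, None, None] * np.einsum("ou,nup->nop", T, g["X"])  # (ng, o, p)
        V = sw[:, None] * np.einsum("ou,nu->no", T, R)  # (ng, o)
        P = np.einsum("nop,pq,nuq->nou", U, G, U)  # cluster leverage, (ng, o, o)
        eye = np.eye(P.shape[1])
        lam, Q = np.linalg.eigh(eye[None] - P)
        adj = np.einsum("nou,nu,nvu->nov", Q, 1.0 / np.sqrt(np.clip(lam, 1e-8, None)), Q)
        Vadj = np.einsum("nou,nu->no", adj, V)
        S = np.einsum("nop,no->np", U, Vadj)  # adjusted cluster scores
        M += np.einsum("np,nq->pq", S, S)
    cov_beta = G @ M @ G

    # LS means at the weighted mean baseline of the analysis population
    uniq = df.drop_duplicates("subject_id")
    if wmap is None:
        bbar = float(uniq["baseline"].mean())
    else:
        wv = uniq["subject_id"].map(wmap).to_numpy(dtype=float)
        bbar = float(np.average(uniq["baseline"], weights=wv))

    ls_rows, con_rows = [], []
    arm_levels = (
        [("active", 1), ("control", 0)]
        if two_arm
        else [("active" if present_arms[0] == 1 else "control", present_arms[0])]
    )
    for i, v in enumerate(vlist):
        xs = {}
        for arm, trt in arm_levels:
            x = _design_row(trt, i, bbar, m)[keep]
            xs[arm] = x
            ls_rows.append(
                {
                    "arm": arm,
                    "month": v,
                    "estimate": float(x @ beta),
                    "se": float(np.sqrt(x @ cov_beta @ x)),
                }
            )
        if two_arm:
            d = xs["active"] - xs["control"]
            con_rows.append(
                {
                    "month": v,
                    "estimate": float(d @ beta),
                    "se": float(np.sqrt(d @ cov_beta @ d)),
                }
            )
    return MMRMFit(
        visits=list(vlist),
        ls_means=pd.DataFrame(ls_rows, columns=["arm", "month", "estimate", "se"]),
        contrasts=pd.DataFrame(con_rows, columns=["month", "estimate", "se"]),
        residual_covariance=pd.DataFrame(Sigma, index=vlist, columns=vlist),
        scale=scale,
        n_used=n,
        converged=converged or used_cs,
        iterations=iters,
        reml_loglik=float(loglik),
        beta=beta,
        cov_beta=cov_beta,
        used_cs_fallback=used_cs,
    )


# ---------------------------------------------------------------------------
# Composite kidney-failure endpoint


@dataclass(frozen=True)
class CompositeEvent:
    """Time to confirmed 40% eGFR reduction, ESKD or death, else censoring."""

    subject_id: str
    time: float
    status: str  # event | censored
    component: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.status == "event" and self.component is None:
            raise ValueError("event needs a component")
        if self.status == "censored" and self.component is not None:
            raise ValueError("censored records carry no component")


def _confirmed_egfr_event(r: SubjectRecord) -> float | None:
    """First visit with eGFR <= 60% of baseline confirmed at the next
    eGFR-measured scheduled visit; returns the first qualifying month."""
    thr = 0.6 * r.egfr_baseline
    measured = [(v.month, v.egfr) for v in r.visits if v.egfr is not None]
    for (t0, e0), (_t1, e1) in zip(measured, measured[1:]):
        if e0 <= thr and e1 <= thr:
            return t0
    return None


def derive_composite_events(records: Sequence[SubjectRecord]) -> list[CompositeEvent]:
    """Derive the composite endpoint per subject.

    The earliest of (a) confirmed 40% eGFR reduction derived from the visit
    series, (b) a recorded ESKD event, (c) recorded death, wins; otherwise
    the subject is censored at the last visit (or the recorded censoring
    time if earlier data stop).
    """
    out = []
    for r in records:
        candidates: list[tuple[float, str]] = []
        t_egfr = _confirmed_egfr_event(r)
        if t_egfr is not None:
            candidates.append((t_egfr, "egfr40_confirmed"))
        if r.event_type in ("eskd", "death", "egfr40_confirmed") and r.event_time is not None:
            candidates.append((r.event_time, r.event_type))
        if candidates:
            t, comp = min(candidates, key=lambda c: c[0])
            out.append(CompositeEvent(r.subject_id, t, "event", comp))
            continue
        last_visit = r.visits[-1].month if r.visits else 0.0
        if r.event_type == "censored" and r.event_time is not None:
            last_visit = min(last_visit, r.event_time) if r.visits else r.event_time
        if not r.visits:
            warnings.warn(f"subject {r.subject_id}: no post-baseline data, censored at 0")
        out.append(CompositeEvent(r.subject_id, last_visit, "censored"))
    return out


@dataclass
class CoxFit:
    """Weighted Cox proportional-hazards fit (active vs control)."""

    log_hr: float
    se: float
    n_events: int
    ties_method: str = "efron"
    degenerate: bool = False  # one arm without events: interval unbounded


def fit_weighted_cox(
    events: Sequence[CompositeEvent],
    arms: Mapping[str, str],
    weights: WeightSet | Mapping[str, float] | None = None,
) -> CoxFit:
    """Weighted partial-likelihood Cox model via lifelines (Efron ties,
    robust variance, weights fixed)."""
    from lifelines import CoxPHFitter

    if isinstance(weights, WeightSet):
        wmap = dict(zip(weights.subject_ids, weights.weights))
    else:
        wmap = None if weights is None else dict(weights)
    rows = []
    for e in events:
        if e.subject_id not in arms:
            raise ValueError(f"no arm label for subject {e.subject_id}")
        if wmap is not None and e.subject_id not in wmap:
            continue
        rows.append(
            {
                "duration": max(e.time, 1e-8),
                "event": 1 if e.status == "event" else 0,
                "trt": 1 if arms[e.subject_id] == "active" else 0,
                "w": 1.0 if wmap is None else float(wmap[e.subject_id]),
            }
        )
    df = pd.DataFrame(rows)
    n_events = int(df["event"].sum())
    if n_events == 0 or df["trt"].nunique() < 2:
        raise ValueError("Cox model needs at least one event and two arms")
    events_by_arm = df.groupby("trt")["event"].sum()
    if (events_by_arm == 0).any():
        # no information about the hazard ratio in one arm: flag, don't crash
        return CoxFit(log_hr=float("nan"), se=float("inf"), n_events=n_events, degenerate=True)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="duration", event_col="event", weights_col="w", robust=True)
    return CoxFit(
        log_hr=float(cph.params_["trt"]),
        se=float(cph.standard_errors_["trt"]),
        n_events=n_events,
    )
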