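"""Calibrated synthetic two-trial generator.

Real IPD for the trials this methodology targets is proprietary, so every
stage of the pipeline is exercised on synthetic parallel-arm RCTs that
reproduce the published marginal structure: correlated baseline covariates
(age, sex, race, eGFR, UPCR, UACR, 24-h urinary protein excretion) drawn
through a Gaussian copula, longitudinal eGFR / proteinuria trajectories
with treatment-by-visit effects and an unstructured residual covariance,
and composite kidney-failure event times from a Weibull proportional-
hazards model with administrative censoring at the last visit.

Marginals are calibrated analytically to printed aggregate moments
(Bernoulli p equals the target proportion; normal means equal the target;
log-normal mu is solved from the mean identity E X = exp(mu + sigma^2/2) or
from a threshold-exceedance probability).  ``exact_moments`` additionally
forces the *in-sample* moments of a finite draw to hit the targets exactly:
binary covariates by latent-rank thresholding (which preserves the copula
dependence), continuous means by an additive or multiplicative recentering,
and threshold covariates by a monotone rescaling that puts exactly the
target count above the threshold.

All randomness flows from one integer seed through a ``SeedSequence``
split (covariates, trajectories, events); the same seed reproduces the
same trial byte for byte.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .trial_data import (
    AggregateTargets,
    ComparatorSummary,
    PublishedEffect,
    SubjectRecord,
    TargetMoment,
    VisitMeasurement,
)

__all__ = [
    "Marginal",
    "GeneratorConfig",
    "TrueEffects",
    "PairedScenario",
    "calibrate_marginals",
    "generate_trial",
    "make_paired_scenario",
    "load_scenario",
    "scenario_path",
    "aggregate_targets_from_records",
]

COVARIATE_ORDER = ("age", "male", "white", "egfr", "upcr", "uacr", "uprot24h")


@dataclass
class Marginal:
    """One covariate's marginal distribution plus its calibration target."""

    dist: str  # truncnorm | bernoulli | lognormal
    params: dict
    target: dict = field(default_factory=dict)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        p = self.params
        if self.dist == "bernoulli":
            # high latent values map to 1 so rank calibration is monotone
            return (u > 1.0 - p["p"]).astype(float)
        if self.dist == "truncnorm":
            low = p.get("low", 0.0)
            high = p.get("high", math.inf)
            loc = p.get("loc", p["mean"])
            a = (low - loc) / p["sd"]
            b = (high - loc) / p["sd"]
            return stats.truncnorm.ppf(u, a, b, loc=loc, scale=p["sd"])
        if self.dist == "lognormal":
            return np.exp(p["mu"] + p["sigma"] * stats.norm.ppf(u))
        raise ValueError(f"unknown marginal family {self.dist!r}")


def _truncnorm_loc_for_mean(mean: float, sd: float, low: float, high: float = math.inf) -> float:
    """Location parameter making the truncated normal's mean equal the target."""

    def f(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    from scipy.optimize import brentq

    return float(brentq(f, mean - 6 * sd, mean + 6 * sd, xtol=1e-12))


def _finalize_truncnorm(params: dict) -> dict:
    p = dict(params)
    p.setdefault("low", 0.0)
    p["loc"] = _truncnorm_loc_for_mean(p["mean"], p["sd"], p["low"], p.get("high", math.inf))
    return p


def _lognormal_mu_from_mean(mean: float, sigma: float) -> float:
    # E X = exp(mu + sigma^2 / 2)
    return math.log(mean) - sigma**2 / 2.0


def _lognormal_mu_from_threshold(threshold: float, exceed_prob: float, sigma: float) -> float:
    # P(X > t) = 1 - Phi((ln t - mu) / sigma)
    return math.log(threshold) - sigma * stats.norm.ppf(1.0 - exceed_prob)


def calibrate_marginals(
    targets: AggregateTargets, family_hints: Mapping[str, Mapping] | None = None
) -> dict[str, Marginal]:
    """Build marginals whose analytic moments equal the target moments.

    ``family_hints`` supplies the non-identified parameters per covariate
    (``{"age": {"dist": "truncnorm", "sd": 10.0}, "upcr": {"dist":
    "lognormal", "sigma": 0.55}, ...}``).  A threshold-proportion target
    takes precedence over a mean target for the same covariate unless both
    can be satisfied by solving for sigma jointly; an unsolvable pair fails
    with a diagnostic.
    """
    hints = dict(family_hints or {})
    by_cov: dict[str, list[TargetMoment]] = {}
    for m in targets:
        by_cov.setdefault(m.covariate, []).append(m)
    out: dict[str, Marginal] = {}
    for cov, moments in by_cov.items():
        hint = dict(hints.get(cov, {}))
        mean_t = next((m for m in moments if m.kind == "mean"), None)
        prop_t = next((m for m in moments if m.kind == "proportion"), None)
        thr_t = next((m for m in moments if m.kind == "threshold_proportion"), None)
        if prop_t is not None:
            out[cov] = Marginal("bernoulli", {"p": prop_t.value}, {"p": prop_t.value})
        elif thr_t is not None:
            sigma = hint.get("sigma", 0.6)
            p_exceed = thr_t.value if thr_t.direction == "greater" else 1.0 - thr_t.value
            if mean_t is not None:
                # solve sigma^2/2 - z*sigma + ln(t/mean) = 0 for sigma > 0
                z = stats.norm.ppf(1.0 - p_exceed)
                disc = z**2 - 2.0 * math.log(thr_t.threshold / mean_t.value)
                if disc < 0:
                    raise ValueError(
                        f"{cov}: mean {mean_t.value} and P(>{thr_t.threshold}) = "
                        f"{p_exceed} admit no log-normal solution (discriminant {disc:.3g})"
                    )
                roots = [z + math.sqrt(disc), z - math.sqrt(disc)]
                pos = [s for s in roots if s > 0]
                if not pos:
                    raise ValueError(f"{cov}: no positive sigma satisfies both constraints")
                sigma = min(pos)
            mu = _lognormal_mu_from_threshold(thr_t.threshold, p_exceed, sigma)
            out[cov] = Marginal(
                "lognormal",
                {"mu": mu, "sigma": sigma},
                {"threshold": thr_t.threshold, "exceed_prob": p_exceed},
            )
        elif mean_t is not None:
            dist = hint.get("dist", "truncnorm")
            if dist == "lognormal":
                sigma = hint.get("sigma", 0.6)
                out[cov] = Marginal(
                    "lognormal",
                    {"mu": _lognormal_mu_from_mean(mean_t.value, sigma), "sigma": sigma},
                    {"mean": mean_t.value},
                )
            else:
                out[cov] = Marginal(
                    "truncnorm",
                    _finalize_truncnorm(
                        {
                            "mean": mean_t.value,
                            "sd": hint.get("sd", 1.0),
                            "low": hint.get("low", 0.0),
                        }
                    ),
                    {"mean": mean_t.value},
                )
    return out


# ---------------------------------------------------------------------------
# Generator configuration


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic trial."""

    trial_id: str
    n: int
    marginals: dict[str, Marginal]
    correlation: np.ndarray
    egfr_effects: dict[str, dict[float, float]]
    ratio_effects: dict[str, dict[str, dict[float, float]]]
    event_model: dict
    allocation: float = 0.5
    visit_months: tuple[float, ...] = (3, 6, 9, 12, 18, 24)
    egfr_intercept_sd: float = 4.0
    egfr_residual_cov: np.ndarray | None = None
    ratio_intercept_sd: float = 0.25
    ratio_residual_sd: float = 0.35
    censor_month: float = 24.0
    exact_moments: bool = False
    seed: int = 0
    # optional treatment-effect modification: the active-arm eGFR effect
    # gains slope * (egfr_baseline - ref) at every visit
    egfr_effect_modification: dict | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(COVARIATE_ORDER),) * 2:
            raise ValueError("correlation matrix must cover the seven matching covariates")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        self.correlation = R
        if not 0.0 < self.allocation < 1.0:
            raise ValueError("allocation ratio must be in (0, 1)")
        if self.egfr_residual_cov is None:
            m = len(self.visit_months)
            self.egfr_residual_cov = 36.0 * (0.55 * np.ones((m, m)) + 0.45 * np.eye(m))
        S = np.asarray(self.egfr_residual_cov, dtype=float)
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("eGFR residual covariance must be positive semi-definite")
        self.egfr_residual_cov = S
        # zero noise is allowed (degenerate, deterministic trajectories)
        if self.egfr_intercept_sd < 0 or self.ratio_intercept_sd < 0 or self.ratio_residual_sd < 0:
            raise ValueError("SDs must be non-negative")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        doc = copy.deepcopy(dict(doc))
        marginals = {}
        for cov in COVARIATE_ORDER:
            spec = dict(doc["marginals"][cov])
            dist = spec.pop("dist")
            if dist == "lognormal":
                sigma = spec["sigma"]
                if "mean" in spec:
                    mu = _lognormal_mu_from_mean(spec["mean"], sigma)
                    target = {"mean": spec["mean"]}
                else:
                    mu = _lognormal_mu_from_threshold(spec["threshold"], spec["exceed_prob"], sigma)
                    target = {"threshold": spec["threshold"], "exceed_prob": spec["exceed_prob"]}
                marginals[cov] = Marginal(dist, {"mu": mu, "sigma": sigma}, target)
            elif dist == "bernoulli":
                marginals[cov] = Marginal(dist, {"p": spec["p"]}, {"p": spec["p"]})
            else:
                marginals[cov] = Marginal(dist, _finalize_truncnorm(spec), {"mean": spec["mean"]})
        corr = np.asarray(doc["correlation"]["matrix"], dtype=float)
        order = list(doc["correlation"].get("order", COVARIATE_ORDER))
        if tuple(order) != COVARIATE_ORDER:
            perm = [order.index(c) for c in COVARIATE_ORDER]
            corr = corr[np.ix_(perm, perm)]
        visits = tuple(float(v) for v in doc.get("visit_months", (3, 6, 9, 12, 18, 24)))

        def _vmap(d):
            return {float(k): float(v) for k, v in d.items()}

        egfr_eff = {arm: _vmap(v) for arm, v in doc["egfr_effects"].items()}
        ratio_eff = {
            ep: {arm: _vmap(v) for arm, v in arms.items()}
            for ep, arms in doc["ratio_effects"].items()
        }
        res = doc.get("egfr_residual")
        cov = None
        if res is not None:
            sd = np.asarray(res["sd"], dtype=float)
            rho = float(res["corr"])
            m = len(visits)
            C = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
            cov = np.outer(sd, sd) * C
        return cls(
            trial_id=doc["trial_id"],
            n=int(doc["n"]),
            marginals=marginals,
            correlation=corr,
            egfr_effects=egfr_eff,
            ratio_effects=ratio_eff,
            event_model=dict(doc["event_model"]),
            allocation=float(doc.get("allocation", 0.5)),
            visit_months=visits,
            egfr_intercept_sd=float(doc.get("egfr_intercept_sd", 4.0)),
            egfr_residual_cov=cov,
            ratio_intercept_sd=float(doc.get("ratio_intercept_sd", 0.25)),
            ratio_residual_sd=float(doc.get("ratio_residual_sd", 0.35)),
            censor_month=float(doc.get("censor_month", 24.0)),
            exact_moments=bool(doc.get("exact_moments", False)),
            seed=int(doc.get("seed", 0)),
        )


def scenario_path(name: str) -> Path:
    """Path of a bundled scenario file (``nefigard_like``, ``protect_like``)."""
    base = resources.files("maictools") / "scenarios" / f"{name}.yaml"
    return Path(str(base))


def load_scenario(name_or_path: str | Path, **overrides) -> GeneratorConfig:
    """Load a YAML scenario by bundled name or explicit path."""
    p = Path(name_or_path)
    if not p.exists():
        p = scenario_path(str(name_or_path))
    doc = yaml.safe_load(p.read_text())
    doc.update(overrides)
    return GeneratorConfig.from_dict(doc)


# ---------------------------------------------------------------------------
# Trial generation


def _exact_adjust(x: np.ndarray, z: np.ndarray, marg: Marginal) -> np.ndarray:
    """Force the finite sample's moment to its calibration target exactly."""
    n = len(x)
    t = marg.target
    if marg.dist == "bernoulli":
        k = int(round(t["p"] * n))
        out = np.zeros(n)
        out[np.argsort(z)[n - k :]] = 1.0  # top-k latent ranks; keeps dependence
        return out
    if "mean" in t:
        if marg.dist == "lognormal":
            return x * (t["mean"] / x.mean())
        return x + (t["mean"] - x.mean())
    if "threshold" in t:
        thr, p = t["threshold"], t["exceed_prob"]
        k = int(round(p * n))
        s = np.sort(x)
        # monotone rescale putting exactly k strictly above the threshold
        boundary = math.sqrt(s[n - k - 1] * s[n - k]) if 0 < k < n else (thr if k == 0 else thr / 2)
        return x * (thr / boundary)
    return x


def generate_trial(config: GeneratorConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw one synthetic trial as a list of validated subject records."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_cov, rng_traj, rng_event = (np.random.default_rng(s) for s in ss.spawn(3))
    n = config.n
    k = len(COVARIATE_ORDER)

    L = np.linalg.cholesky(config.correlation)
    Z = rng_cov.standard_normal((n, k)) @ L.T
    U = stats.norm.cdf(Z)
    cols = {}
    for j, cov in enumerate(COVARIATE_ORDER):
        marg = config.marginals[cov]
        x = marg.ppf(U[:, j])
        if config.exact_moments:
            x = _exact_adjust(x, Z[:, j], marg)
        cols[cov] = x

    n_active = int(round(config.allocation * n))
    arm_ix = rng_cov.permutation(n) < n_active
    arms = np.where(arm_ix, "active", "control")

    months = list(config.visit_months)
    m = len(months)
    # eGFR: baseline + arm-by-visit effect + subject intercept + correlated residual
    eg_eff = np.array(
        [[config.egfr_effects[a].get(t, 0.0) for t in months] for a in arms]
    )
    mod = config.egfr_effect_modification
    if mod:
        eg_eff = eg_eff + (
            arm_ix.astype(float) * mod["slope"] * (cols["egfr"] - mod.get("ref", 58.0))
        )[:, None]
    eg_u = rng_traj.normal(0.0, config.egfr_intercept_sd, n) if config.egfr_intercept_sd else np.zeros(n)
    # eigen transform tolerates a singular (zero-noise) residual covariance
    vals, vecs = np.linalg.eigh(config.egfr_residual_cov)
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    eg_e = rng_traj.standard_normal((n, m)) @ root.T
    egfr_vals = cols["egfr"][:, None] + eg_eff + eg_u[:, None] + eg_e
    egfr_vals = np.maximum(egfr_vals, 1.0)

    ratio_vals = {}
    for ep in ("upcr", "uacr"):
        eff = np.array(
            [[config.ratio_effects[ep][a].get(t, 0.0) for t in months] for a in arms]
        )
        u = rng_traj.normal(0.0, config.ratio_intercept_sd, n)
        e = rng_traj.normal(0.0, config.ratio_residual_sd, (n, m))
        ratio_vals[ep] = cols[ep][:, None] * np.exp(eff + u[:, None] + e)

    # composite events: Weibull proportional hazards on baseline covariates
    em = config.event_model
    eta = (
        em.get("log_hr_active", 0.0) * arm_ix.astype(float)
        + em.get("beta_egfr", 0.0) * (cols["egfr"] - em.get("egfr_ref", 58.0))
        + em.get("beta_log_upcr", 0.0)
        * (np.log(cols["upcr"]) - math.log(em.get("upcr_ref", 1.5)))
    )
    shape = em.get("weibull_shape", 1.4)
    scale = em.get("weibull_scale_months", 180.0)
    u_ev = rng_event.uniform(size=n)
    t_ev = scale * (-np.log(u_ev) / np.exp(eta)) ** (1.0 / shape)
    is_death = rng_event.uniform(size=n) < em.get("death_fraction", 0.3)

    records = []
    for i in range(n):
        visits = [
            VisitMeasurement(
                month=months[j],
                egfr=float(egfr_vals[i, j]),
                upcr=float(ratio_vals["upcr"][i, j]),
                uacr=float(ratio_vals["uacr"][i, j]),
            )
            for j in range(m)
        ]
        event_time = event_type = None
        if t_ev[i] <= config.censor_month:
            event_time = float(t_ev[i])
            event_type = "death" if is_death[i] else "eskd"
        records.append(
            SubjectRecord(
                subject_id=f"{config.trial_id}-{i + 1:04d}",
                trial_id=config.trial_id,
                arm=str(arms[i]),
                age=float(cols["age"][i]),
                male=bool(cols["male"][i]),
                white=bool(cols["white"][i]),
                egfr_baseline=float(cols["egfr"][i]),
                upcr_baseline=float(cols["upcr"][i]),
                uacr_baseline=float(cols["uacr"][i]),
                uprot24h_baseline=float(cols["uprot24h"][i]),
                visits=visits,
                event_time=event_time,
                event_type=event_type,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Paired-trial scenarios


def aggregate_targets_from_records(
    records: Sequence[SubjectRecord],
    thresholds: Mapping[str, float] | None = None,
) -> AggregateTargets:
    """Summarize a trial's sample moments in the seven-covariate target form
    (what a publication's baseline table would print)."""
    thresholds = dict(thresholds or {"uacr": 1.1, "uprot24h": 1.8})
    arr = {
        c: np.array([float(getattr(r, _fld(c))) for r in records]) for c in COVARIATE_ORDER
    }
    moments = [
        TargetMoment("age", "mean", float(arr["age"].mean())),
        TargetMoment("male", "proportion", float(arr["male"].mean())),
        TargetMoment("white", "proportion", float(arr["white"].mean())),
        TargetMoment("egfr", "mean", float(arr["egfr"].mean())),
        TargetMoment("upcr", "mean", float(arr["upcr"].mean())),
        TargetMoment(
            "uacr",
            "threshold_proportion",
            float((arr["uacr"] > thresholds["uacr"]).mean()),
            threshold=thresholds["uacr"],
        ),
        TargetMoment(
            "uprot24h",
            "threshold_proportion",
            float((arr["uprot24h"] > thresholds["uprot24h"]).mean()),
            threshold=thresholds["uprot24h"],
        ),
    ]
    return AggregateTargets(moments)


def _fld(cov: str) -> str:
    return {"age": "age", "male": "male", "white": "white"}.get(cov, f"{cov}_baseline")


@dataclass
class TrueEffects:
    """Per-trial generator overrides defining the simulated truth."""

    index: dict = field(default_factory=dict)
    comparator: dict = field(default_factory=dict)


@dataclass
class PairedScenario:
    """The information regime of an aggregate-data indirect comparison:
    index IPD, comparator aggregate targets, comparator published effects."""

    index_records: list[SubjectRecord]
    comparator_targets: AggregateTargets
    comparator_summary: ComparatorSummary
    truth: TrueEffects


def _apply_overrides(config: GeneratorConfig, overrides: Mapping) -> GeneratorConfig:
    cfg = copy.deepcopy(config)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"unknown generator field {key!r}")
        setattr(cfg, key, copy.deepcopy(val))
    return cfg


def make_paired_scenario(
    true_effects: TrueEffects,
    seed: int,
    *,
    index_config: GeneratorConfig | None = None,
    comparator_config: GeneratorConfig | None = None,
    endpoints: Sequence[str] = ("egfr", "upcr", "uacr", "composite"),
    analysis_months: Sequence[float] = (9, 12, 24),
) -> PairedScenario:
    """Generate both trials, summarize the comparator, discard its IPD.

    The comparator's within-trial relative effects (with standard errors)
    are computed by fitting the same outcome models to its own IPD with
    uniform weights — mimicking what that trial's publication would report —
    and its aggregate baseline moments become the matching targets.
    """
    from .outcome_models import (
        build_change_outcomes,
        derive_composite_events,
        fit_mmrm,
        fit_weighted_cox,
    )

    ss = np.random.SeedSequence(seed)
    s_index, s_comp = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    icfg = _apply_overrides(index_config or load_scenario("nefigard_like"), true_effects.index)
    ccfg = _apply_overrides(comparator_config or load_scenario("protect_like"), true_effects.comparator)
    index_records = generate_trial(icfg, seed=s_index)
    comp_records = generate_trial(ccfg, seed=s_comp)

    targets = aggregate_targets_from_records(comp_records)
    effects: list[PublishedEffect] = []
    from .indirect_comparison import Z95

    for ep in endpoints:
        if ep == "composite":
            ev = derive_composite_events(comp_records)
            arms = {r.subject_id: r.arm for r in comp_records}
            fit = fit_weighted_cox(ev, arms)
            if not fit.degenerate:
                effects.append(
                    PublishedEffect(
                        endpoint="composite",
                        scale="log_hr",
                        timepoint="overall",
                        estimate=fit.log_hr,
                        lower=fit.log_hr - Z95 * fit.se,
                        upper=fit.log_hr + Z95 * fit.se,
                    )
                )
            continue
        table = build_change_outcomes(comp_records, ep)
        months = [t for t in analysis_months if t in set(table["month"])]
        fit = fit_mmrm(
            table,
            scale="absolute_change" if ep == "egfr" else "log_ratio",
            visits=months,
        )
        scale = "mean_difference" if ep == "egfr" else "log_gmr"
        for t in months:
            est, se = fit.contrast_at(t)
            effects.append(
                PublishedEffect(
                    endpoint=ep,
                    scale=scale,
                    timepoint=t,
                    estimate=est,
                    lower=est - Z95 * se,
                    upper=est + Z95 * se,
                )
            )
            for arm in ("active", "control"):
                row = fit.ls_means[(fit.ls_means["arm"] == arm) & (fit.ls_means["month"] == t)]
                effects.append(
                    PublishedEffect(
                        endpoint=ep,
                        scale=scale,
                        timepoint=t,
                        estimate=float(row["estimate"].iloc[0]),
                        lower=float(row["estimate"].iloc[0] - Z95 * row["se"].iloc[0]),
                        upper=float(row["estimate"].iloc[0] + Z95 * row["se"].iloc[0]),
                        level="arm",
                        arm=arm,
                    )
                )
    return PairedScenario(
        index_records=index_records,
        comparator_targets=targets,
        comparator_summary=ComparatorSummary(effects),
        truth=true_effects,
    )
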