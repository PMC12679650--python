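"""Data model, I/O and covariate derivation for trial IPD and aggregate targets.

The package works in the standard population-adjustment information regime:
individual patient data (IPD) for one "index" randomized trial, and only
published aggregate summaries for a "comparator" trial.  This module defines
the in-memory containers for both sides, CSV readers/writers for the IPD,
a JSON/YAML reader for the aggregate targets and published relative effects,
and the derivation of the numeric matching-covariate matrix (raw values for
mean targets, strict 0/1 indicators for proportion and threshold targets).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VisitMeasurement",
    "SubjectRecord",
    "TimepointMap",
    "TargetMoment",
    "AggregateTargets",
    "PublishedEffect",
    "ComparatorSummary",
    "read_ipd",
    "write_ipd",
    "read_targets",
    "write_targets",
    "derive_threshold_indicators",
    "complete_case_filter",
    "DEFAULT_TIMEPOINT_MAP",
    "COVARIATE_FIELDS",
]

ARMS = ("active", "control")
EVENT_TYPES = ("egfr40_confirmed", "eskd", "death", "censored")
ENDPOINTS = ("egfr", "upcr", "uacr")


@dataclass(frozen=True)
class VisitMeasurement:
    """One scheduled post-baseline visit; missing assays stay ``None``."""

    month: float
    egfr: float | None = None
    upcr: float | None = None
    uacr: float | None = None

    def __post_init__(self) -> None:
        if self.egfr is None and self.upcr is None and self.uacr is None:
            raise ValueError(f"visit at month {self.month}: all outcomes missing")
        for name in ENDPOINTS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"visit at month {self.month}: {name}={v!r} must be >= 0")


@dataclass
class SubjectRecord:
    """One trial participant: arm, baseline covariates, visits, event data."""

    subject_id: str
    trial_id: str
    arm: str
    age: float
    male: bool | None
    white: bool | None
    egfr_baseline: float
    upcr_baseline: float
    uacr_baseline: float | None = None
    uprot24h_baseline: float | None = None
    visits: list[VisitMeasurement] = field(default_factory=list)
    event_time: float | None = None
    event_type: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"subject {self.subject_id}: arm must be one of {ARMS}")
        if not self.age > 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        if not self.egfr_baseline > 0:
            raise ValueError(f"subject {self.subject_id}: egfr_baseline must be > 0")
        for name in ("upcr_baseline", "uacr_baseline", "uprot24h_baseline"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be >= 0")
        months = [v.month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError(f"subject {self.subject_id}: visit months must be strictly increasing")
        if self.event_time is not None and self.event_time < 0:
            raise ValueError(f"subject {self.subject_id}: event_time must be >= 0")
        if self.event_type is not None and self.event_type not in EVENT_TYPES:
            raise ValueError(f"subject {self.subject_id}: unknown event_type {self.event_type!r}")

    def visit_value(self, month: float, endpoint: str) -> float | None:
        for v in self.visits:
            if v.month == month:
                return getattr(v, endpoint)
        return None


class TimepointMap:
    """Bijective pairing of index-trial months with comparator-trial weeks.

    Only the listed pairs are valid analysis timepoints; values are mapped,
    never interpolated.
    """

    def __init__(self, pairs: Sequence[tuple[float, float]]):
        months = [m for m, _ in pairs]
        weeks = [w for _, w in pairs]
        if len(set(months)) != len(months) or len(set(weeks)) != len(weeks):
            raise ValueError("timepoint pairs must be bijective")
        order = sorted(range(len(pairs)), key=lambda i: months[i])
        if [weeks[i] for i in order] != sorted(weeks):
            raise ValueError("timepoint pairs must be monotone in both coordinates")
        self.pairs = [tuple(pairs[i]) for i in order]
        self._m2w = {m: w for m, w in self.pairs}
        self._w2m = {w: m for m, w in self.pairs}

    @property
    def months(self) -> list[float]:
        return [m for m, _ in self.pairs]

    def to_weeks(self, month: float) -> float:
        try:
            return self._m2w[month]
        except KeyError:
            raise KeyError(f"month {month} is not a mapped analysis timepoint") from None

    def to_months(self, week: float) -> float:
        try:
            return self._w2m[week]
        except KeyError:
            raise KeyError(f"week {week} is not a mapped analysis timepoint") from None


#: Month 9 <-> week 36, month 12 <-> week 48, month 24 <-> week 106
#: (the comparator's closest scheduled visit to month 24).
DEFAULT_TIMEPOINT_MAP = TimepointMap([(9, 36), (12, 48), (24, 106)])

MOMENT_KINDS = ("mean", "proportion", "threshold_proportion")

#: Matching-covariate names resolvable against SubjectRecord fields.
COVARIATE_FIELDS: dict[str, str] = {
    "age": "age",
    "male": "male",
    "white": "white",
    "egfr": "egfr_baseline",
    "egfr_baseline": "egfr_baseline",
    "upcr": "upcr_baseline",
    "upcr_baseline": "upcr_baseline",
    "uacr": "uacr_baseline",
    "uacr_baseline": "uacr_baseline",
    "uprot24h": "uprot24h_baseline",
    "uprot24h_baseline": "uprot24h_baseline",
}


@dataclass(frozen=True)
class TargetMoment:
    """A single aggregate moment of the comparator population to match."""

    covariate: str
    kind: str  # mean | proportion | threshold_proportion
    value: float  # fractional scale for proportions
    threshold: float | None = None
    direction: str = "greater"  # only for threshold_proportion
    source: str = ""
    raw_text: str = ""  # original printed value, kept for reporting

    def __post_init__(self) -> None:
        if self.kind not in MOMENT_KINDS:
            raise ValueError(f"unknown moment kind {self.kind!r}")
        if self.covariate not in COVARIATE_FIELDS:
            raise ValueError(f"covariate {self.covariate!r} not resolvable to a subject field")
        if self.kind == "threshold_proportion":
            if self.threshold is None:
                raise ValueError(f"{self.covariate}: threshold_proportion requires a threshold")
            if self.direction not in ("greater", "less"):
                raise ValueError(f"{self.covariate}: direction must be 'greater' or 'less'")
        if self.kind in ("proportion", "threshold_proportion") and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"{self.covariate}: proportion {self.value} outside [0, 1]")

    @property
    def field_name(self) -> str:
        return COVARIATE_FIELDS[self.covariate]

    @property
    def label(self) -> str:
        if self.kind == "threshold_proportion":
            op = ">" if self.direction == "greater" else "<"
            return f"{self.covariate} {op}{self.threshold:g}"
        return self.covariate

    @property
    def is_proportion(self) -> bool:
        return self.kind in ("proportion", "threshold_proportion")


@dataclass
class AggregateTargets:
    """Ordered list of target moments for the comparator population."""

    moments: list[TargetMoment]

    def __post_init__(self) -> None:
        if not self.moments:
            raise ValueError("no targets: the moment list is empty")
        keys = [(m.covariate, m.kind, m.threshold) for m in self.moments]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (covariate, kind, threshold) target entries")

    def __iter__(self):
        return iter(self.moments)

    def __len__(self) -> int:
        return len(self.moments)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.moments]

    @property
    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.moments], dtype=float)

    def subset(self, covariates: Sequence[str]) -> "AggregateTargets":
        keep = [m for m in self.moments if m.covariate in covariates]
        return AggregateTargets(keep)


EFFECT_SCALES = ("mean_difference", "log_gmr", "log_hr")


@dataclass(frozen=True)
class PublishedEffect:
    """A published comparator summary: point estimate with a 95% interval.

    ``level`` distinguishes within-trial relative effects (``relative``,
    active vs control) from arm-level absolute summaries (``arm``), the
    latter used only by the unanchored comparison.
    """

    endpoint: str  # egfr | upcr | uacr | composite
    scale: str
    timepoint: float | str  # month label, or "overall" for the composite
    estimate: float
    lower: float
    upper: float
    interval_type: str = "confidence"
    level: str = "relative"
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in EFFECT_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError(
                f"{self.endpoint}@{self.timepoint}: interval "
                f"({self.lower}, {self.upper}) does not bracket {self.estimate}"
            )
        if self.interval_type not in ("confidence", "credible"):
            raise ValueError(f"interval_type {self.interval_type!r}")


@dataclass
class ComparatorSummary:
    """All published comparator-trial effect summaries, keyed for lookup."""

    effects: list[PublishedEffect] = field(default_factory=list)

    def lookup(
        self, endpoint: str, timepoint: float | str, level: str = "relative", arm: str | None = None
    ) -> PublishedEffect:
        for e in self.effects:
            if (
                e.endpoint == endpoint
                and e.timepoint == timepoint
                and e.level == level
                and (arm is None or e.arm == arm)
            ):
                return e
        raise KeyError(f"no published {level} effect for {endpoint} at {timepoint}")


# ---------------------------------------------------------------------------
# IPD reading and writing

LONG_COLUMNS = [
    "subject_id",
    "trial_id",
    "arm",
    "age",
    "male",
    "white",
    "egfr_baseline",
    "upcr_baseline",
    "uacr_baseline",
    "uprot24h_baseline",
    "month",
    "egfr",
    "upcr",
    "uacr",
    "event_time",
    "event_type",
]

_BASE_NUMERIC = ["age", "egfr_baseline", "upcr_baseline", "uacr_baseline", "uprot24h_baseline"]
_OPTIONAL_BASE = {"uacr_baseline", "uprot24h_baseline", "male", "white", "event_time", "event_type"}


def _parse_bool(v, where: str) -> bool | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes", "1.0"):
        return True
    if s in ("0", "false", "f", "no", "0.0"):
        return False
    raise ValueError(f"{where}: cannot interpret {v!r} as boolean")


def _parse_float(v, where: str) -> float | None:
    if v is None or v == "":
        return None
    try:
        x = float(v)
    except (TypeError, ValueError):
        raise ValueError(f"{where}: non-numeric value {v!r}") from None
    return None if math.isnan(x) else x


def read_ipd(path: str | Path, schema: Mapping[str, str] | None = None) -> list[SubjectRecord]:
    """Read IPD from a long-format CSV (one row per subject-visit).

    ``schema`` maps canonical column names to the file's column names; any
    canonical column not mentioned keeps its own name.  Baseline covariates
    and event data must be constant within subject; rows with an empty
    ``month`` carry baseline-only subjects (no visits).
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)
    for col in LONG_COLUMNS:
        if col not in df.columns and col not in _OPTIONAL_BASE and col not in ("month", "egfr", "upcr", "uacr"):
            raise ValueError(f"unknown/missing column: expected {col!r} in {path}")
        if col not in df.columns:
            df[col] = ""

    records: list[SubjectRecord] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        first = grp.iloc[0]
        row_ix = int(grp.index[0]) + 2  # 1-based with header, for error messages
        where = f"row {row_ix} (subject {sid})"
        kwargs = dict(
            subject_id=str(sid),
            trial_id=str(first["trial_id"]),
            arm=str(first["arm"]),
            age=_parse_float(first["age"], where),
            male=_parse_bool(first["male"], where),
            white=_parse_bool(first["white"], where),
            egfr_baseline=_parse_float(first["egfr_baseline"], where),
            upcr_baseline=_parse_float(first["upcr_baseline"], where),
            uacr_baseline=_parse_float(first["uacr_baseline"], where),
            uprot24h_baseline=_parse_float(first["uprot24h_baseline"], where),
            event_time=_parse_float(first["event_time"], where),
            event_type=str(first["event_type"]) or None,
        )
        for req in ("age", "egfr_baseline", "upcr_baseline"):
            if kwargs[req] is None:
                raise ValueError(f"{where}: missing required covariate {req}")
        visits = []
        seen_months = set()
        for ix, row in grp.iterrows():
            vwhere = f"row {int(ix) + 2} (subject {sid})"
            month = _parse_float(row["month"], vwhere)
            if month is None:
                continue
            if month in seen_months:
                raise ValueError(f"{vwhere}: duplicate (subject, timepoint) month {month:g}")
            seen_months.add(month)
            visits.append(
                VisitMeasurement(
                    month=month,
                    egfr=_parse_float(row["egfr"], vwhere),
                    upcr=_parse_float(row["upcr"], vwhere),
                    uacr=_parse_float(row["uacr"], vwhere),
                )
            )
        visits.sort(key=lambda v: v.month)
        records.append(SubjectRecord(visits=visits, **kwargs))
    return records


def write_ipd(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write records to the long CSV format read back by :func:`read_ipd`."""
    rows = []
    for r in records:
        base = dict(
            subject_id=r.subject_id,
            trial_id=r.trial_id,
            arm=r.arm,
            age=r.age,
            male="" if r.male is None else int(r.male),
            white="" if r.white is None else int(r.white),
            egfr_baseline=r.egfr_baseline,
            upcr_baseline=r.upcr_baseline,
            uacr_baseline="" if r.uacr_baseline is None else r.uacr_baseline,
            uprot24h_baseline="" if r.uprot24h_baseline is None else r.uprot24h_baseline,
            event_time="" if r.event_time is None else r.event_time,
            event_type=r.event_type or "",
        )
        if not r.visits:
            rows.append({**base, "month": "", "egfr": "", "upcr": "", "uacr": ""})
        for v in r.visits:
            rows.append(
                {
                    **base,
                    "month": v.month,
                    "egfr": "" if v.egfr is None else repr(v.egfr),
                    "upcr": "" if v.upcr is None else repr(v.upcr),
                    "uacr": "" if v.uacr is None else repr(v.uacr),
                }
            )
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregate target configuration


def _normalize_proportion(raw: float, scale_hint: str | None, where: str) -> tuple[float, str]:
    """Return (fraction, raw_text).  Values in (1, 100] default to percent."""
    if not 0.0 <= raw <= 100.0:
        raise ValueError(f"{where}: proportion {raw} outside [0, 100]")
    if scale_hint == "fraction":
        frac = raw
    elif scale_hint == "percent" or raw > 1.0:
        frac = raw / 100.0
    else:
        frac = raw
    return frac, repr(raw)


def read_targets(path: str | Path) -> tuple[AggregateTargets, ComparatorSummary]:
    """Read aggregate target moments and published comparator effects.

    Accepts JSON or YAML; the document holds a ``targets`` list (covariate,
    kind, value, optional threshold/direction/scale/source) and an optional
    ``comparator_effects`` list (endpoint, scale, timepoint, estimate,
    lower, upper, interval_type, level, arm).
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    raw_targets = doc.get("targets") or []
    if not raw_targets:
        raise ValueError("no targets: the configuration lists no target moments")

    moments = []
    for i, t in enumerate(raw_targets):
        where = f"targets[{i}]"
        kind = t.get("kind", "mean")
        value = float(t["value"])
        raw_text = str(t["value"])
        if kind in ("proportion", "threshold_proportion"):
            value, raw_text = _normalize_proportion(value, t.get("scale"), where)
        moments.append(
            TargetMoment(
                covariate=t["covariate"],
                kind=kind,
                value=value,
                threshold=None if t.get("threshold") is None else float(t["threshold"]),
                direction=t.get("direction", "greater"),
                source=t.get("source", ""),
                raw_text=raw_text,
            )
        )
    effects = [
        PublishedEffect(
            endpoint=e["endpoint"],
            scale=e["scale"],
            timepoint=e["timepoint"] if e["timepoint"] == "overall" else float(e["timepoint"]),
            estimate=float(e["estimate"]),
            lower=float(e["lower"]),
            upper=float(e["upper"]),
            interval_type=e.get("interval_type", "confidence"),
            level=e.get("level", "relative"),
            arm=e.get("arm"),
        )
        for e in doc.get("comparator_effects") or []
    ]
    return AggregateTargets(moments), ComparatorSummary(effects)


def write_targets(
    targets: AggregateTargets,
    summary: ComparatorSummary | None,
    path: str | Path,
) -> None:
    """Serialize targets (+ optional comparator effects) to the YAML/JSON
    schema read back by :func:`read_targets`.  Proportions are written on
    the percentage scale, mirroring how publications print them."""
    doc: dict = {"targets": []}
    for m in targets:
        entry: dict = {"covariate": m.covariate, "kind": m.kind}
        if m.is_proportion:
            entry["value"] = round(m.value * 100.0, 10)
            entry["scale"] = "percent"
        else:
            entry["value"] = m.value
        if m.kind == "threshold_proportion":
            entry["threshold"] = m.threshold
            entry["direction"] = m.direction
        if m.source:
            entry["source"] = m.source
        doc["targets"].append(entry)
    if summary is not None and summary.effects:
        doc["comparator_effects"] = [
            {
                "endpoint": e.endpoint,
                "scale": e.scale,
                "timepoint": e.timepoint,
                "estimate": e.estimate,
                "lower": e.lower,
                "upper": e.upper,
                "interval_type": e.interval_type,
                "level": e.level,
                **({"arm": e.arm} if e.arm else {}),
            }
            for e in summary.effects
        ]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Matching-covariate matrix


def _subject_value(record: SubjectRecord, moment: TargetMoment):
    return getattr(record, moment.field_name)


def complete_case_filter(
    records: Sequence[SubjectRecord], targets: AggregateTargets
) -> tuple[list[SubjectRecord], list[str]]:
    """Split records into complete cases (all matching covariates present)
    and the ids of excluded subjects."""
    kept, excluded = [], []
    for r in records:
        if any(_subject_value(r, m) is None for m in targets):
            excluded.append(r.subject_id)
        else:
            kept.append(r)
    return kept, excluded


def derive_threshold_indicators(
    records: Sequence[SubjectRecord], targets: AggregateTargets
) -> pd.DataFrame:
    """Build the numeric matching matrix: one column per target moment.

    Mean targets pass the raw covariate through; proportion targets yield the
    0/1 covariate itself; threshold-proportion targets yield strict-inequality
    indicators (a value exactly at the threshold scores 0).  Column order
    follows the target order.  Any missing covariate value is an error listing
    the offending subjects — filter with :func:`complete_case_filter` first.
    """
    missing: list[str] = []
    cols: dict[str, list[float]] = {m.label: [] for m in targets}
    for r in records:
        for m in targets:
            v = _subject_value(r, m)
            if v is None:
                missing.append(f"{r.subject_id}:{m.covariate}")
                continue
            if m.kind == "mean":
                x = float(v)
            elif m.kind == "proportion":
                x = float(bool(v))
            else:  # threshold_proportion, strict inequality
                x = float(v > m.threshold) if m.direction == "greater" else float(v < m.threshold)
            cols[m.label].append(x)
    if missing:
        raise ValueError(
            "missing matching covariates for subjects: " + ", ".join(sorted(set(missing)))
        )
    out = pd.DataFrame(cols, index=[r.subject_id for r in records])
    return out[[m.label for m in targets]]
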