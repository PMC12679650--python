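import numpy as np
import pytest

from maictools.synthetic_data import generate_trial, load_scenario, scenario_path
from maictools.trial_data import (
    AggregateTargets,
    SubjectRecord,
    TargetMoment,
    VisitMeasurement,
    read_targets,
)

#: Published aggregate column of the comparator population (the matching
#: targets): mean age, % male, % White, mean eGFR, mean UPCR, % UACR > 1.1,
#: % urinary protein excretion > 1.8 g/day.
COMPARATOR_COLUMN = {
    "age": 46.00,
    "male": 69.80,
    "white": 67.33,
    "egfr": 56.95,
    "upcr": 1.44,
    "uacr >1.1": 50.00,
    "uprot24h >1.8": 50.00,
}

#: The index trial's own unweighted baseline column (n = 364).
INDEX_COLUMN = {
    "age": 42.70,
    "male": 65.93,
    "white": 75.55,
    "egfr": 57.87,
    "upcr": 1.48,
    "uacr >1.1": 40.66,
    "uprot24h >1.8": 65.66,
}


@pytest.fixture(scope="session")
def comparator_targets() -> AggregateTargets:
    targets, _ = read_targets(scenario_path("protect_targets"))
    return targets


@pytest.fixture(scope="session")
def calibrated_trial():
    """364 synthetic index-trial subjects whose unweighted covariate moments
    equal the index trial's published baseline column exactly."""
    cfg = load_scenario("nefigard_like", exact_moments=True)
    return generate_trial(cfg, seed=7)


def make_subject(
    sid="s1",
    arm="active",
    age=45.0,
    egfr=60.0,
    upcr=1.2,
    uacr=1.0,
    uprot=1.5,
    visits=(),
    **kw,
) -> SubjectRecord:
    return SubjectRecord(
        subject_id=sid,
        trial_id="toy",
        arm=arm,
        age=age,
        male=True,
        white=True,
        egfr_baseline=egfr,
        upcr_baseline=upcr,
        uacr_baseline=uacr,
        uprot24h_baseline=uprot,
        visits=[VisitMeasurement(month=m, **vals) for m, vals in visits],
        **kw,
    )


@pytest.fixture
def toy_targets() -> AggregateTargets:
    return AggregateTargets(
        [
            TargetMoment("age", "mean", 46.0),
            TargetMoment("male", "proportion", 0.5),
            TargetMoment("uacr", "threshold_proportion", 0.5, threshold=1.1),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
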