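import numpy as np
import pytest

from recurve.data_model import Cohort, CovariateSchema, CovariateSpec, SubjectRecord


@pytest.fixture
def xz_schema():
    return CovariateSchema(
        {"x": CovariateSpec("binary"), "z": CovariateSpec("continuous")}
    )


@pytest.fixture
def mixed_schema():
    return CovariateSchema(
        {
            "x": CovariateSpec("binary"),
            "smoke": CovariateSpec("categorical", ("non", "current", "ex")),
            "z": CovariateSpec("continuous"),
        }
    )


def make_cohort(schema, rows):
    """rows: iterable of (id, covariates, end, event_times)."""
    return Cohort(
        tuple(SubjectRecord(sid, covs, end, tuple(times)) for sid, covs, end, times in rows),
        schema,
    )


@pytest.fixture
def small_cohort(mixed_schema):
    return make_cohort(
        mixed_schema,
        [
            ("A", {"x": 1, "smoke": "non", "z": 1.5}, 100.0, (5.0, 30.0)),
            ("B", {"x": 0, "smoke": "current", "z": -0.3}, 80.0, (12.0,)),
            ("C", {"x": 0, "smoke": "ex", "z": 0.0}, 120.0, ()),
        ],
    )


def random_cohort(rng, n=20, schema=None):
    """Random valid cohort for property tests."""
    if schema is None:
        schema = CovariateSchema(
            {"x": CovariateSpec("binary"), "z": CovariateSpec("continuous")}
        )
    rows = []
    for i in range(n):
        end = float(rng.uniform(10, 400))
        k = int(rng.poisson(2))
        times = np.sort(rng.uniform(0.01, end, size=k))
        times = tuple(float(t) for t in np.unique(times))
        rows.append(
            (f"s{i}", {"x": int(rng.integers(2)), "z": float(rng.normal())}, end, times)
        )
    return make_cohort(schema, rows)
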