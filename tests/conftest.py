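"""Shared fixtures: the packaged schema, weighting schemes, case builders."""

import pytest
from hypothesis import HealthCheck, settings

import fpikit as fp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return fp.default_schema()


@pytest.fixture
def uniform():
    return fp.WeightingScheme.uniform()


def build_case(levels, case_id="case-1", quality=None, status="developed"):
    """A CaseStudy from {metric_id: level}; quality maps metric_id -> rating."""
    quality = quality or {}
    scores = [
        fp.MetricScore(mid, lvl, None if lvl is None else quality.get(mid))
        for mid, lvl in levels.items()
    ]
    return fp.CaseStudy(
        case_id=case_id,
        fishery_name=f"Fishery {case_id}",
        country="Testland",
        base_year=2015,
        development_status=status,
        scores=scores,
    )


@pytest.fixture
def make_case():
    return build_case


@pytest.fixture(scope="session")
def full_case(schema):
    """One case scoring every metric with a deterministic valid level."""
    levels = {
        m.metric_id: (i % 5) + 1 for i, m in enumerate(schema.metrics)
    }
    return build_case(levels, case_id="full-1")
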