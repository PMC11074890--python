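import pytest

from reasonnet import Respondent, ResponseSet, default_codebook


@pytest.fixture(scope="session")
def acceptance_cb():
    return default_codebook("acceptance")


@pytest.fixture(scope="session")
def resistance_cb():
    return default_codebook("resistance")


def make_response_set(codebook, reason_sets, group=None, ages=None):
    """Build a ResponseSet from a list of reason-code iterables."""
    group = group or codebook.group
    ages = ages or ["unknown"] * len(reason_sets)
    respondents = tuple(
        Respondent(id=f"r{i}", group=group, reasons=frozenset(rs), age_group=age)
        for i, (rs, age) in enumerate(zip(reason_sets, ages))
    )
    return ResponseSet(group=group, codebook=codebook, respondents=respondents)


@pytest.fixture
def tiny_rs(acceptance_cb):
    """Two respondents: {disease_risk} and {disease_risk, protecting_others}."""
    return make_response_set(
        acceptance_cb,
        [{"disease_risk"}, {"disease_risk", "protecting_others"}],
    )
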