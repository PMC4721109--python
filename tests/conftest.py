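import pytest
from hypothesis import settings

from cues import load_anchor_table, load_gazetteer

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from cues.questionnaire import (
    AGE_BAND_LABELS,
    BehaviorSet,
    ExposureEpoch,
    ResidencePeriod,
    Respondent,
)


@pytest.fixture(scope="session")
def anchors():
    return load_anchor_table()


@pytest.fixture(scope="session")
def gazetteer():
    return load_gazetteer()


def _default_behaviors(**overrides):
    base = dict(
        tanning_bed_visits="0",
        blistering_sunburns="1-5",
        sunscreen="sometimes",
        long_sleeves="sometimes",
        hat="rarely",
        shade_seeking="often",
    )
    base.update(overrides)
    return BehaviorSet(**base)


def _default_epochs(weekday=2.0, weekend=3.0):
    return [ExposureEpoch(label, weekday, weekend) for label in AGE_BAND_LABELS]


@pytest.fixture
def make_respondent():
    """Factory for a valid respondent; keyword overrides tweak any field."""

    def factory(
        age=46,
        residences=None,
        personal_hx=False,
        dx_age=None,
        dx_type=None,
        family_hx=(),
        weekday=2.0,
        weekend=3.0,
        behaviors_after=None,
        **kwargs,
    ):
        if residences is None:
            residences = [ResidencePeriod("Seattle, WA", 0, age)]
        if personal_hx:
            dx_age = dx_age if dx_age is not None else max(18, age - 10)
            dx_type = dx_type or "BCC"
            behaviors_after = behaviors_after or _default_behaviors(sunscreen="always")
        return Respondent(
            age=age,
            fitzpatrick=kwargs.pop("fitzpatrick", 2),
            personal_hx=personal_hx,
            dx_age=dx_age,
            dx_type=dx_type,
            behaviors_before=kwargs.pop("behaviors_before", _default_behaviors()),
            behaviors_after=behaviors_after,
            family_hx=frozenset(family_hx),
            epochs=kwargs.pop("epochs", _default_epochs(weekday, weekend)),
            residences=residences,
            **kwargs,
        )

    return factory
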