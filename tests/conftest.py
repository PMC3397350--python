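import pytest

import biofortsim as bf


@pytest.fixture(scope="session")
def loadings():
    return bf.load_loadings()


@pytest.fixture(scope="session")
def dri():
    return bf.load_dri()


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under the default study conditions."""
    return bf.generate_cohort(bf.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-subject cohort for cheap structural tests."""
    return bf.generate_cohort(bf.GeneratorConfig(n=80, seed=11))


def make_subject(
    sid="s1",
    sex="female",
    age=35,
    rice_g_day=250.0,
    zinc_rice=None,
    zinc_total=12.0,
    energy=2200.0,
    ffq=None,
    **kw,
):
    """Construct a valid Subject with sensible defaults for hand cohorts."""
    if zinc_rice is None:
        zinc_rice = rice_g_day * 1.7 / 100.0
    return bf.Subject(
        id=sid,
        sex=sex,
        age_years=age,
        region=kw.get("region", "south"),
        residence=kw.get("residence", "rural"),
        ses=kw.get("ses", "medium"),
        education=kw.get("education", "junior"),
        energy_kcal_day=energy,
        zinc_total_mg_day=zinc_total,
        zinc_rice_mg_day=zinc_rice,
        rice_g_day=rice_g_day,
        ffq_weekly_g=ffq or {},
    )


@pytest.fixture
def subject_factory():
    return make_subject
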