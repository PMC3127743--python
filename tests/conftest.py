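import pytest

from mapleac.interrai import ALL_ITEMS, Assessment, Timepoint
from mapleac.synthetic import generate_cohort, load_profile
from mapleac.tree import default_tree


def intact_items(**overrides) -> dict:
    """A fully independent / nothing-wrong item pattern."""
    items = {code: 0 for code in ALL_ITEMS}
    items["goes_out"] = 1
    items.update(overrides)
    return items


def make_assessment(timepoint=Timepoint.PREMORBID, **overrides) -> Assessment:
    return Assessment(timepoint=timepoint, items=intact_items(**overrides))


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def nordic_cohort(tree):
    """Small Nordic cohort reused across tests (seed fixed for the suite)."""
    return generate_cohort(load_profile("nordic", n=1500, seed=20210), tree)


@pytest.fixture(scope="session")
def nordic_episodes(nordic_cohort):
    return nordic_cohort.episodes
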