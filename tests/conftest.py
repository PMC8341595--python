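"""Shared fixtures: all test data is generated programmatically."""

import pytest

from irsefficacy import SyntheticConfig, simulate_campaign
from irsefficacy.bioassay import BioassayRecord


def make_record(**overrides) -> BioassayRecord:
    """A valid single-cone record with sensible defaults."""
    fields = dict(
        house_id="H1",
        wall_type="cement",
        treatment="sprayed",
        age_group="young",
        visit_month=1.5,
        cone_height="bottom",
        n_exposed=10,
        n_dead={24: 2, 48: 4, 72: 8, 96: 9, 120: 9},
    )
    fields.update(overrides)
    return BioassayRecord(**fields)


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign (fixed seed) plus its truth manifest."""
    records, manifest = simulate_campaign(SyntheticConfig(seed=1))
    return records, manifest


@pytest.fixture(scope="session")
def campaign_records(campaign):
    return campaign[0]
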