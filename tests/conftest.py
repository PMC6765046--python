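"""Shared fixtures: one synthetic study featurized once per session."""

from types import SimpleNamespace

import pytest

from isonet.model import sample_balanced_split
from isonet.pipeline import (
    build_featurizer,
    label_fixture,
    labeled_feature_table,
    make_fixture,
)
from isonet.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study with features and labels."""
    config = SimulationConfig(seed=7)
    fixture = make_fixture(config)
    featurizer = build_featurizer(fixture.catalog, fixture.expression)
    labels = label_fixture(fixture)
    X, y = labeled_feature_table(featurizer, labels)
    return SimpleNamespace(
        config=config,
        fixture=fixture,
        catalog=fixture.catalog,
        featurizer=featurizer,
        labels=labels,
        X=X,
        y=y,
    )


@pytest.fixture(scope="session")
def split100(study):
    """Balanced 100/40-per-class split of the session study."""
    return sample_balanced_split(study.X, study.y, 100, 40, seed=7)
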