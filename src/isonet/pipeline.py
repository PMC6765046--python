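"""End-to-end wiring: fixture -> features -> labels -> model -> networks.

Convenience functions that chain the library modules for the common
desk-scale workflow. Each step is also usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .exceptions import DataError
from .expression import ExpressionMatrix, log_transform, tissue_slices
from .labels import LabelSets, build_label_sets
from .model import DatasetSplit, sample_balanced_split
from .pair_features import PairFeaturizer
from .sequence_features import SequenceFeatureParams, compute_all_sequence_groups
from .synthetic import (
    SimulationConfig,
    SyntheticAnnotations,
    plant_modules,
    simulate_annotations,
    simulate_catalog,
    simulate_expression,
)


@dataclass
class Fixture:
    """A complete synthetic study: catalog, expression, annotations."""

    config: SimulationConfig
    catalog: GeneCatalog
    expression: ExpressionMatrix
    annotations: SyntheticAnnotations


def make_fixture(config: SimulationConfig) -> Fixture:
    """Generate a coherent synthetic study from one config + seed."""
    catalog = simulate_catalog(config)
    modules = plant_modules(catalog, config)
    expression = simulate_expression(catalog, config, modules)
    annotations = simulate_annotations(catalog, config, modules)
    return Fixture(config, catalog, expression, annotations)


def build_featurizer(
    catalog: GeneCatalog,
    expression: ExpressionMatrix,
    params: SequenceFeatureParams | None = None,
) -> PairFeaturizer:
    """Log-transform expression, slice by tissue, featurize all isoforms."""
    log_matrix = expression if expression.log_scale else log_transform(expression)
    slices = tissue_slices(log_matrix)
    groups = {
        record.isoform_id: compute_all_sequence_groups(record, params)
        for record in catalog
    }
    return PairFeaturizer(slices, groups)


def label_fixture(fixture: Fixture) -> LabelSets:
    return build_label_sets(
        fixture.catalog,
        fixture.annotations.dag,
        fixture.annotations.annotations + fixture.annotations.pathways,
        fixture.annotations.ppi,
    )


def labeled_feature_table(
    featurizer: PairFeaturizer, labels: LabelSets
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and 0/1 vector for every labeled pair."""
    pairs = [p.key for p in labels.positives] + [p.key for p in labels.negatives]
    if not pairs:
        raise DataError("no labeled pairs")
    X = featurizer.pair_matrix(pairs)
    y = np.array(
        [1] * len(labels.positives) + [0] * len(labels.negatives), dtype=int
    )
    return X, y


def fixture_split(
    fixture: Fixture,
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
    featurizer: PairFeaturizer | None = None,
) -> tuple[DatasetSplit, PairFeaturizer]:
    """Labeled balanced split for a fixture (featurizer reusable)."""
    if featurizer is None:
        featurizer = build_featurizer(fixture.catalog, fixture.expression)
    labels = label_fixture(fixture)
    X, y = labeled_feature_table(featurizer, labels)
    split = sample_balanced_split(
        X, y, n_train_per_class, n_test_per_class, seed=seed
    )
    return split, featurizer
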