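"""Tissue-specific networks via leave-one-tissue-out feature ablation.

One full-feature forest and one forest per tissue (trained on identical
pairs and seeds, with that tissue's expression feature column removed) score
every pair. A pair whose confident functional prediction (probability >= 0.6
with all features) collapses to a confident non-functional one
(probability <= 0.4 without tissue t's feature) is functional specifically
in tissue t; the mirrored flip defines tissue-specific non-functional pairs.
Pairs whose predicted label never changes under any ablation are reference
pairs; label flips that fail the confidence bands are low-confidence and
excluded from the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .model import DatasetSplit, PairClassifier, train_forest

FUNCTIONAL_MIN = 0.6
NONFUNCTIONAL_MAX = 0.4

TISSUE_FUNCTIONAL = "tissue_functional"
TISSUE_NONFUNCTIONAL = "tissue_nonfunctional"
REFERENCE = "reference"
LOW_CONFIDENCE = "low_confidence"


@dataclass(frozen=True)
class TissueEdge:
    """A pair scored under one tissue's ablation."""

    isoform_a: str
    isoform_b: str
    tissue: str
    prob_full: float
    prob_ablated: float
    loto_class: str
    multi_tissue: bool = False

    def __post_init__(self) -> None:
        if self.loto_class == TISSUE_FUNCTIONAL and not (
            self.prob_full >= FUNCTIONAL_MIN
            and self.prob_ablated <= NONFUNCTIONAL_MAX
        ):
            raise ConfigurationError("tissue_functional edge violates bands")
        if self.loto_class == TISSUE_NONFUNCTIONAL and not (
            self.prob_full <= NONFUNCTIONAL_MAX
            and self.prob_ablated >= FUNCTIONAL_MIN
        ):
            raise ConfigurationError("tissue_nonfunctional edge violates bands")

    @property
    def weight(self) -> float:
        """Edge weight: ablated probability for tissue edges (lower = stronger
        tissue-specific functional signal), full probability otherwise."""
        if self.loto_class in (TISSUE_FUNCTIONAL, TISSUE_NONFUNCTIONAL):
            return self.prob_ablated
        return self.prob_full


@dataclass
class LotoEnsemble:
    """The full model plus one ablated model per tissue."""

    full: PairClassifier
    ablated: dict[str, PairClassifier]
    tissues: tuple[str, ...]

    def __len__(self) -> int:
        return 1 + len(self.ablated)

    def manifest(self) -> dict:
        return {
            "full": self.full.manifest(),
            "ablated": {t: m.manifest() for t, m in self.ablated.items()},
            "thresholds": {
                "functional_min": FUNCTIONAL_MIN,
                "nonfunctional_max": NONFUNCTIONAL_MAX,
            },
        }


def train_loto_ensemble(
    split: DatasetSplit,
    tissues: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> LotoEnsemble:
    """Train the full model and |tissues| single-feature-ablated models.

    All models are trained on the same pairs and the same seed, so
    prediction flips reflect the removed feature, not sampling noise. The
    pooled organism-wide expression feature is always retained.
    """
    all_names = tuple(split.X_train.columns)
    for tissue in tissues:
        if f"expr_{tissue}" not in all_names:
            raise ConfigurationError(
                f"no expression feature for tissue {tissue!r}"
            )
    full = train_forest(split, n_trees=n_trees, seed=seed)
    ablated: dict[str, PairClassifier] = {}
    for tissue in tissues:
        subset = tuple(n for n in all_names if n != f"expr_{tissue}")
        ablated[tissue] = train_forest(
            split, n_trees=n_trees, seed=seed, feature_subset=subset
        )
    return LotoEnsemble(full=full, ablated=ablated, tissues=tuple(tissues))


def classify_pair_loto(prob_full: float, prob_ablated: float) -> str:
    """LOTO class for one tissue from the two probabilities."""
    if not (0.0 <= prob_full <= 1.0 and 0.0 <= prob_ablated <= 1.0):
        raise ConfigurationError("probabilities must lie in [0, 1]")
    if prob_full >= FUNCTIONAL_MIN and prob_ablated <= NONFUNCTIONAL_MAX:
        return TISSUE_FUNCTIONAL
    if prob_full <= NONFUNCTIONAL_MAX and prob_ablated >= FUNCTIONAL_MIN:
        return TISSUE_NONFUNCTIONAL
    full_label = prob_full >= 0.5
    ablated_label = prob_ablated >= 0.5
    if full_label == ablated_label:
        return REFERENCE
    return LOW_CONFIDENCE


@dataclass
class TissueNetworks:
    """Per-tissue functional / non-functional edge sets plus references."""

    functional: dict[str, list[TissueEdge]]
    nonfunctional: dict[str, list[TissueEdge]]
    reference: list[TissueEdge] = field(default_factory=list)

    def all_edges(self) -> list[TissueEdge]:
        edges = list(self.reference)
        for group in (self.functional, self.nonfunctional):
            for tissue_edges in group.values():
                edges.extend(tissue_edges)
        return edges


def build_tissue_networks(
    pairs_X: pd.DataFrame, ensemble: LotoEnsemble
) -> TissueNetworks:
    """Score pairs with every model and assemble the tissue networks.

    ``pairs_X`` rows are indexed by canonical "a|b" pair keys. Each pair is
    scored once by the full model and once per ablated model. A pair that
    flips under more than one ablation is emitted to each qualifying tissue
    and flagged multi_tissue.
    """
    prob_full = ensemble.full.predict_proba(pairs_X)
    prob_ablated = {
        t: ensemble.ablated[t].predict_proba(pairs_X) for t in ensemble.tissues
    }
    functional: dict[str, list[TissueEdge]] = {t: [] for t in ensemble.tissues}
    nonfunctional: dict[str, list[TissueEdge]] = {t: [] for t in ensemble.tissues}
    reference: list[TissueEdge] = []
    pair_keys = [key.split("|") for key in pairs_X.index]
    for i, (a, b) in enumerate(pair_keys):
        assignments: list[tuple[str, str, float]] = []
        all_reference = True
        for tissue in ensemble.tissues:
            cls = classify_pair_loto(float(prob_full[i]), float(prob_ablated[tissue][i]))
            if cls != REFERENCE:
                all_reference = False
            if cls in (TISSUE_FUNCTIONAL, TISSUE_NONFUNCTIONAL):
                assignments.append((tissue, cls, float(prob_ablated[tissue][i])))
        if all_reference:
            reference.append(
                TissueEdge(a, b, "", float(prob_full[i]), float(prob_full[i]), REFERENCE)
            )
            continue
        multi = len(assignments) > 1
        for tissue, cls, p_abl in assignments:
            edge = TissueEdge(
                a, b, tissue, float(prob_full[i]), p_abl, cls, multi_tissue=multi
            )
            if cls == TISSUE_FUNCTIONAL:
                functional[tissue].append(edge)
            else:
                nonfunctional[tissue].append(edge)
    return TissueNetworks(
        functional=functional, nonfunctional=nonfunctional, reference=reference
    )
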