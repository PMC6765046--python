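"""Per-pair features: Fisher-z-transformed Pearson correlations.

For each unordered isoform pair the feature row holds one z value per
expression slice (one per tissue plus one over all samples) and one per
sequence descriptor group. With 17 tissues this yields the canonical
18 + 9 = 27 features.

The z transform is

    z = 1/2 * log2( (1 - rho) / (1 + rho) )

which is strictly decreasing in rho. rho = 1 maps to -inf and rho = -1 to
+inf, so those are replaced with the extreme values -100 and +100; an
undefined rho (either vector constant) maps to z = 0. A flag exposes the
classical variant z = 1/2 * ln((1 + rho)/(1 - rho)) for experimentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .exceptions import NumericError, PipelineError
from .expression import ALL_SAMPLES, TissueSlices
from .sequence_features import GROUP_NAMES, FeatureGroupVector

Z_EXTREME = 100.0
_RHO_ONE_TOL = 1e-12


def fisher_z(rho: float, classical: bool = False) -> float:
    """Transform a Pearson correlation into the z feature value.

    ``rho`` may be NaN to mark an undefined correlation, which maps to 0.
    Values within 1e-12 of +/-1 are treated as exactly +/-1 and replaced by
    the extreme values; any other z beyond the extremes is clipped.
    """
    if rho is None or (isinstance(rho, float) and np.isnan(rho)):
        return 0.0
    rho = float(rho)
    if abs(rho) > 1.0 + 1e-9:
        raise NumericError(f"correlation {rho} outside [-1, 1]")
    rho = min(1.0, max(-1.0, rho))
    if rho >= 1.0 - _RHO_ONE_TOL:
        return Z_EXTREME if classical else -Z_EXTREME
    if rho <= -1.0 + _RHO_ONE_TOL:
        return -Z_EXTREME if classical else Z_EXTREME
    if classical:
        z = 0.5 * np.log((1.0 + rho) / (1.0 - rho))
    else:
        z = 0.5 * np.log2((1.0 - rho) / (1.0 + rho))
    return float(np.clip(z, -Z_EXTREME, Z_EXTREME))


def fisher_z_vector(rho: np.ndarray, classical: bool = False) -> np.ndarray:
    """Vectorized :func:`fisher_z`; NaN entries mark undefined correlations."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho[~np.isnan(rho)]) > 1.0 + 1e-9):
        raise NumericError("correlation outside [-1, 1]")
    rho = np.clip(rho, -1.0, 1.0)
    out = np.zeros_like(rho)
    undefined = np.isnan(rho)
    plus_one = ~undefined & (rho >= 1.0 - _RHO_ONE_TOL)
    minus_one = ~undefined & (rho <= -1.0 + _RHO_ONE_TOL)
    regular = ~(undefined | plus_one | minus_one)
    r = rho[regular]
    if classical:
        out[regular] = 0.5 * np.log((1.0 + r) / (1.0 - r))
        out[plus_one] = Z_EXTREME
        out[minus_one] = -Z_EXTREME
    else:
        out[regular] = 0.5 * np.log2((1.0 - r) / (1.0 + r))
        out[plus_one] = -Z_EXTREME
        out[minus_one] = Z_EXTREME
    return np.clip(out, -Z_EXTREME, Z_EXTREME)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order."""
    if a == b:
        raise PipelineError(f"self-pair not allowed: {a}")
    return (a, b) if a < b else (b, a)


def enumerate_pairs(catalog: GeneCatalog) -> Iterator[tuple[str, str]]:
    """Yield every unordered isoform pair exactly once, canonically ordered."""
    yield from itertools.combinations(catalog.isoform_ids, 2)


def pair_count(n_isoforms: int) -> int:
    """C(n, 2): number of unordered pairs (never materialized)."""
    return n_isoforms * (n_isoforms - 1) // 2


@dataclass(frozen=True)
class PairFeatureRow:
    """The z features for one canonical pair, ordered by feature name."""

    isoform_a: str
    isoform_b: str
    names: tuple[str, ...]
    z: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.z, index=list(self.names))


def expression_feature_names(tissues: Sequence[str]) -> tuple[str, ...]:
    return tuple(f"expr_{t}" for t in tissues) + (f"expr_{ALL_SAMPLES}",)


def feature_names(tissues: Sequence[str]) -> tuple[str, ...]:
    """Canonical feature order: tissue slices, pooled slice, sequence groups."""
    return expression_feature_names(tissues) + tuple(
        f"seq_{g}" for g in GROUP_NAMES
    )


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so the dot product of two rows is their Pearson rho.

    Returns (standardized rows, constant-row mask). Constant rows produce an
    undefined correlation and are zeroed with the mask set.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    return centered / safe[:, None], constant


class PairFeaturizer:
    """Precomputes per-isoform standardized vectors, then builds pair rows.

    Correlations reduce to dot products of standardized vectors, so feature
    rows for large pair sets are assembled without recomputing per-slice
    statistics. Expression slices must be on the log scale.
    """

    def __init__(
        self,
        slices: TissueSlices,
        groups: Mapping[str, Mapping[str, FeatureGroupVector]],
        classical: bool = False,
    ):
        self.tissue_order = slices.tissue_order
        self.names = feature_names(self.tissue_order)
        self.classical = classical
        self._isoform_index: dict[str, int] = {
            iso: i for i, iso in enumerate(slices.pooled.index)
        }
        self._expr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for slice_name, table in slices.items():
            if table.shape[1] < 2:
                raise PipelineError(
                    f"slice {slice_name!r} has fewer than 2 samples"
                )
            self._expr[f"expr_{slice_name}"] = _standardize_rows(
                table.values.astype(float)
            )
        self._groups: dict[str, tuple[dict[str, int], np.ndarray, np.ndarray]] = {}
        for gname in GROUP_NAMES:
            index: dict[str, int] = {}
            rows = []
            for iso, gvecs in groups.items():
                if gname not in gvecs:
                    raise PipelineError(
                        f"isoform {iso} missing sequence group {gname!r}"
                    )
                index[iso] = len(rows)
                rows.append(gvecs[gname].values)
            std, const = _standardize_rows(np.asarray(rows, dtype=float))
            self._groups[f"seq_{gname}"] = (index, std, const)

    def _check(self, isoform: str, groups_needed: bool = True) -> None:
        if isoform not in self._isoform_index:
            raise PipelineError(f"isoform {isoform} missing from expression")
        if groups_needed:
            index, _, _ = next(iter(self._groups.values()))
            if isoform not in index:
                raise PipelineError(
                    f"isoform {isoform} missing sequence feature groups"
                )

    def pair_row(self, a: str, b: str) -> PairFeatureRow:
        a, b = canonical_pair(a, b)
        matrix = self.pair_matrix([(a, b)])
        return PairFeatureRow(a, b, self.names, matrix.values[0])

    def pair_matrix(self, pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
        """Feature rows for many pairs; index = "a|b" canonical pair keys."""
        pair_list = [canonical_pair(a, b) for a, b in pairs]
        for a, b in pair_list:
            self._check(a)
            self._check(b)
        n = len(pair_list)
        out = np.zeros((n, len(self.names)), dtype=float)
        ia = np.array([self._isoform_index[a] for a, _ in pair_list], dtype=int)
        ib = np.array([self._isoform_index[b] for _, b in pair_list], dtype=int)
        col = 0
        for slice_name in self.tissue_order + (ALL_SAMPLES,):
            std, const = self._expr[f"expr_{slice_name}"]
            rho = (std[ia] * std[ib]).sum(axis=1)
            undefined = const[ia] | const[ib]
            out[:, col] = self._z_column(rho, undefined)
            col += 1
        for gname in GROUP_NAMES:
            index, std, const = self._groups[f"seq_{gname}"]
            ga = np.array([index[a] for a, _ in pair_list], dtype=int)
            gb = np.array([index[b] for _, b in pair_list], dtype=int)
            rho = (std[ga] * std[gb]).sum(axis=1)
            undefined = const[ga] | const[gb]
            out[:, col] = self._z_column(rho, undefined)
            col += 1
        keys = [f"{a}|{b}" for a, b in pair_list]
        return pd.DataFrame(out, index=keys, columns=list(self.names))

    def _z_column(self, rho: np.ndarray, undefined: np.ndarray) -> np.ndarray:
        return fisher_z_vector(
            np.where(undefined, np.nan, rho), classical=self.classical
        )
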