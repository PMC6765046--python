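"""Expression handling: log transform, tissue slices and tissue similarity.

Expression arrives as an isoform x sample table of FPKM values together with
a sample -> tissue mapping. All correlation-based computations downstream run
on log2(FPKM + 1) values; the +1 keeps zero FPKM at zero on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Column label of the pooled all-samples slice.
ALL_SAMPLES = "all"


@dataclass
class ExpressionMatrix:
    """Isoform x sample FPKM (or log FPKM) table plus sample -> tissue map."""

    values: pd.DataFrame
    sample_tissue: Mapping[str, str]
    tissues: tuple[str, ...] = field(default=())
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.sample_tissue]
        if missing:
            raise InputError(
                f"samples absent from tissue map: {sorted(missing)[:5]}"
            )
        if not self.tissues:
            seen: list[str] = []
            for s in self.values.columns:
                t = self.sample_tissue[s]
                if t not in seen:
                    seen.append(t)
            self.tissues = tuple(seen)
        unknown = {
            self.sample_tissue[s]
            for s in self.values.columns
            if self.sample_tissue[s] not in self.tissues
        }
        if unknown:
            raise InputError(f"unknown tissues in mapping: {sorted(unknown)}")
        if not self.log_scale and (self.values.values < 0).any():
            raise InputError("FPKM values must be nonnegative")

    @property
    def isoform_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, tissue: str) -> list[str]:
        if tissue not in self.tissues:
            raise InputError(f"unknown tissue: {tissue}")
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a new matrix with each cell mapped to log2(value + 1)."""
    if matrix.log_scale:
        raise InputError("matrix is already on the log scale")
    if (matrix.values.values < 0).any():
        raise InputError("cannot log-transform negative FPKM values")
    return ExpressionMatrix(
        values=np.log2(matrix.values + 1.0),
        sample_tissue=matrix.sample_tissue,
        tissues=matrix.tissues,
        log_scale=True,
    )


@dataclass
class TissueSlices:
    """Per-tissue column slices plus the pooled all-samples slice.

    Tissue slices are column-disjoint and their union is the full table;
    the pooled slice repeats all columns under the key ``ALL_SAMPLES``.
    """

    slices: dict[str, pd.DataFrame]
    tissue_order: tuple[str, ...]

    @property
    def pooled(self) -> pd.DataFrame:
        return self.slices[ALL_SAMPLES]

    def __len__(self) -> int:
        return len(self.slices)

    def items(self):
        for t in self.tissue_order:
            yield t, self.slices[t]
        yield ALL_SAMPLES, self.slices[ALL_SAMPLES]


def tissue_slices(matrix: ExpressionMatrix) -> TissueSlices:
    """Split the table into one slice per tissue plus one pooled slice."""
    slices = {t: matrix.values[matrix.samples_of(t)] for t in matrix.tissues}
    slices[ALL_SAMPLES] = matrix.values
    return TissueSlices(slices=slices, tissue_order=matrix.tissues)


def median_profiles(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Tissue x isoform table of per-tissue median expression.

    Expected on the log scale for consistency with the pair features.
    """
    rows = {t: matrix.values[matrix.samples_of(t)].median(axis=1)
            for t in matrix.tissues}
    profiles = pd.DataFrame(rows).T
    return profiles.loc[list(matrix.tissues)]


def tissue_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Tissue x tissue Pearson correlation of median expression profiles."""
    if profiles.shape[0] < 1:
        raise InputError("need at least one tissue profile")
    corr = np.corrcoef(profiles.values)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)
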