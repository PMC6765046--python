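"""Per-isoform sequence descriptor groups.

Nine descriptor groups are computed per isoform: mRNA k-mer compositions for
k = 3..6, protein k-mer compositions for k = 1..2, conjoint-triad
frequencies, pseudo-amino-acid composition, and Moran autocorrelation.
Each group is returned as a :class:`FeatureGroupVector` whose key order is
lexicographic within the group and frozen, so that correlations between two
isoforms' vectors are always computed over aligned keys.

k-mer composition
-----------------
For a sequence of length ``l`` over an alphabet, the frequency of k-mer ``i``
is ``N_i / (l - (k - 1))`` where ``N_i`` counts overlapping occurrences; the
vector ranges over all ``|alphabet|**k`` k-mers and sums to 1.

Conjoint triads
---------------
The 20 amino acids are first mapped onto 7 classes defined by side-chain
volume and dipole ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E},
{C}); triad frequencies are then the k=3 k-mer composition over the 7-letter
class alphabet, giving 7**3 = 343 values.

Pseudo-amino-acid composition
-----------------------------
Chou-type vector of length ``20 + lambda``: the 20 amino-acid frequencies
plus ``lambda`` sequence-order correlation factors built from standardized
hydrophobicity, hydrophilicity and side-chain-mass scales, jointly
normalized so the whole vector sums to 1.

Moran autocorrelation
---------------------
For a standardized residue property P and lag d,

    I(d) = [ (1/(N-d)) * sum_{i=1..N-d} (P_i - Pbar)(P_{i+d} - Pbar) ]
           / [ (1/N) * sum_{i=1..N} (P_i - Pbar)^2 ]

with Pbar the sequence mean of P. I(d) is defined as 0 when N - d < 1 or
when the denominator vanishes, so short (>= 30 residue) proteins remain
featurizable at every lag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import AMINO_ACIDS, MRNA_ALPHABET, IsoformRecord
from .exceptions import FeatureError

GROUP_NAMES = (
    "mrna_3mer",
    "mrna_4mer",
    "mrna_5mer",
    "mrna_6mer",
    "prot_1mer",
    "prot_2mer",
    "conjoint_triad",
    "pseudo_aac",
    "moran",
)

# Canonical dipole / side-chain-volume partition of the 20 amino acids.
CONJOINT_TRIAD_CLASSES: dict[str, str] = {}
for _cls, _members in enumerate(("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"), 1):
    for _aa in _members:
        CONJOINT_TRIAD_CLASSES[_aa] = str(_cls)
_CT_ALPHABET = "1234567"

# Standard per-residue property tables used by the pseudo-AAC correlation
# factors (hydrophobicity, hydrophilicity, side-chain mass).
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
GRANTHAM_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}
RESIDUE_WEIGHT = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}

#: Default property scales for Moran autocorrelation (8 scales x nlag lags).
DEFAULT_MORAN_SCALES: dict[str, Mapping[str, float]] = {
    "hydrophobicity": HYDROPHOBICITY,
    "hydrophobicity_kd": KYTE_DOOLITTLE,
    "hydrophilicity": HYDROPHILICITY,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "polarity": GRANTHAM_POLARITY,
    "volume": GRANTHAM_VOLUME,
    "isoelectric_point": ISOELECTRIC_POINT,
    "residue_weight": RESIDUE_WEIGHT,
}


@dataclass(frozen=True)
class FeatureGroupVector:
    """One named per-isoform descriptor vector with a frozen key order."""

    group_name: str
    keys: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.values):
            raise FeatureError(
                f"{self.group_name}: {len(self.keys)} keys vs "
                f"{len(self.values)} values"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.keys, self.values.tolist()))


@dataclass(frozen=True)
class MoranConfig:
    """Property scales and maximum lag for Moran autocorrelation.

    Each scale must assign a value to all 20 standard residues; scales are
    standardized to zero mean / unit variance over the 20 residues before
    use, making I(d) invariant to affine rescaling of any scale.
    """

    property_scales: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MORAN_SCALES)
    )
    nlag: int = 30

    def __post_init__(self) -> None:
        if self.nlag < 1:
            raise FeatureError("MoranConfig.nlag must be >= 1")
        for name, scale in self.property_scales.items():
            missing = set(AMINO_ACIDS) - set(scale)
            if missing:
                raise FeatureError(
                    f"Moran scale {name!r} missing residues: {sorted(missing)}"
                )


@dataclass(frozen=True)
class SequenceFeatureParams:
    """Parameters for the full nine-group descriptor set."""

    pseaac_lambda: int = 25
    pseaac_weight: float = 0.05
    moran: MoranConfig = field(default_factory=MoranConfig)


def _kmer_keys(alphabet: str, k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(sorted(alphabet), repeat=k))


def kmer_composition(sequence: str, k: int, alphabet: str) -> FeatureGroupVector:
    """Overlapping k-mer frequencies N_i / (l - (k - 1)) over the alphabet."""
    if k < 1:
        raise FeatureError("k must be >= 1")
    l = len(sequence)
    if l < k:
        raise FeatureError(f"sequence length {l} < k = {k}")
    letters = sorted(alphabet)
    index = {c: i for i, c in enumerate(letters)}
    bad = set(sequence) - set(letters)
    if bad:
        raise FeatureError(f"characters outside alphabet: {sorted(bad)}")
    base = len(letters)
    counts = np.zeros(base**k, dtype=float)
    # rolling base-|alphabet| encoding of each window
    code = 0
    mod = base ** (k - 1)
    for i, ch in enumerate(sequence):
        code = (code % mod) * base + index[ch]
        if i >= k - 1:
            counts[code] += 1
    counts /= l - (k - 1)
    name = f"kmer_{k}"
    return FeatureGroupVector(name, _kmer_keys(alphabet, k), counts)


def conjoint_triad(protein_sequence: str) -> FeatureGroupVector:
    """Triad frequencies over the 7-class reduced protein alphabet (343 keys)."""
    if len(protein_sequence) < 3:
        raise FeatureError("conjoint triads require protein length >= 3")
    try:
        reduced = "".join(CONJOINT_TRIAD_CLASSES[aa] for aa in protein_sequence)
    except KeyError as exc:
        raise FeatureError(f"non-standard residue: {exc.args[0]!r}") from None
    vec = kmer_composition(reduced, 3, _CT_ALPHABET)
    return FeatureGroupVector("conjoint_triad", vec.keys, vec.values)


def _standardize_scale(scale: Mapping[str, float]) -> dict[str, float]:
    values = np.array([scale[aa] for aa in AMINO_ACIDS], dtype=float)
    mean = values.mean()
    std = values.std()
    if std == 0:
        return {aa: 0.0 for aa in AMINO_ACIDS}
    return {aa: (scale[aa] - mean) / std for aa in AMINO_ACIDS}


_PSEAAC_SCALES = (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS)


def pseudo_aac(
    protein_sequence: str, lam: int = 25, weight: float = 0.05
) -> FeatureGroupVector:
    """Chou-type pseudo-amino-acid composition of length 20 + lam.

    With ``lam = 0`` the vector reduces to the plain amino-acid composition;
    with ``weight = 0`` the first 20 entries equal the plain composition and
    the tail is zero.
    """
    n = len(protein_sequence)
    if lam < 0:
        raise FeatureError("pseudo-AAC lambda must be >= 0")
    if weight < 0:
        raise FeatureError("pseudo-AAC weight must be >= 0")
    if n <= lam:
        raise FeatureError(f"protein length {n} must exceed lambda = {lam}")
    scales = [_standardize_scale(s) for s in _PSEAAC_SCALES]
    props = np.array(
        [[s[aa] for aa in protein_sequence] for s in scales], dtype=float
    )  # shape (3, n)

    comp = np.array(
        [protein_sequence.count(aa) for aa in AMINO_ACIDS], dtype=float
    )
    comp /= n

    thetas = np.zeros(lam, dtype=float)
    for d in range(1, lam + 1):
        diffs = props[:, d:] - props[:, :-d]  # (3, n-d)
        thetas[d - 1] = np.mean(np.mean(diffs**2, axis=0))

    denom = comp.sum() + weight * thetas.sum()
    first20 = comp / denom
    tail = weight * thetas / denom
    keys = tuple(AMINO_ACIDS) + tuple(f"lambda_{d}" for d in range(1, lam + 1))
    return FeatureGroupVector("pseudo_aac", keys, np.concatenate([first20, tail]))


def moran_autocorrelation(
    protein_sequence: str, config: MoranConfig | None = None
) -> FeatureGroupVector:
    """Moran I(d) for every property scale and lag d = 1..nlag."""
    if config is None:
        config = MoranConfig()
    n = len(protein_sequence)
    if n < 2:
        raise FeatureError("Moran autocorrelation requires length >= 2")
    keys: list[str] = []
    values: list[float] = []
    for scale_name in sorted(config.property_scales):
        scale = _standardize_scale(config.property_scales[scale_name])
        p = np.array([scale[aa] for aa in protein_sequence], dtype=float)
        pbar = p.mean()
        centered = p - pbar
        denom = float(np.mean(centered**2))
        for d in range(1, config.nlag + 1):
            keys.append(f"{scale_name}_lag{d:02d}")
            if n - d < 1 or denom == 0.0:
                values.append(0.0)
                continue
            num = float(np.mean(centered[: n - d] * centered[d:]))
            values.append(num / denom)
    return FeatureGroupVector("moran", tuple(keys), np.array(values))


def compute_all_sequence_groups(
    record: IsoformRecord, params: SequenceFeatureParams | None = None
) -> dict[str, FeatureGroupVector]:
    """All nine descriptor groups for one isoform, in canonical group order."""
    if params is None:
        params = SequenceFeatureParams()
    mrna = record.mrna_sequence
    prot = record.protein_sequence
    groups: dict[str, FeatureGroupVector] = {}
    for k in (3, 4, 5, 6):
        vec = kmer_composition(mrna, k, MRNA_ALPHABET)
        groups[f"mrna_{k}mer"] = FeatureGroupVector(
            f"mrna_{k}mer", vec.keys, vec.values
        )
    for k in (1, 2):
        vec = kmer_composition(prot, k, AMINO_ACIDS)
        groups[f"prot_{k}mer"] = FeatureGroupVector(
            f"prot_{k}mer", vec.keys, vec.values
        )
    groups["conjoint_triad"] = conjoint_triad(prot)
    groups["pseudo_aac"] = pseudo_aac(
        prot, params.pseaac_lambda, params.pseaac_weight
    )
    groups["moran"] = moran_autocorrelation(prot, params.moran)
    return {name: groups[name] for name in GROUP_NAMES}


def group_lengths(params: SequenceFeatureParams | None = None) -> dict[str, int]:
    """Documented vector length per group under the given parameters."""
    if params is None:
        params = SequenceFeatureParams()
    return {
        "mrna_3mer": 4**3,
        "mrna_4mer": 4**4,
        "mrna_5mer": 4**5,
        "mrna_6mer": 4**6,
        "prot_1mer": 20,
        "prot_2mer": 400,
        "conjoint_triad": 7**3,
        "pseudo_aac": 20 + params.pseaac_lambda,
        "moran": len(params.moran.property_scales) * params.moran.nlag,
    }
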