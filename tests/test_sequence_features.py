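"""Sequence descriptors against brute-force and hand-computed oracles."""

import numpy as np
import pytest

from isonet.catalog import AMINO_ACIDS, MRNA_ALPHABET, IsoformRecord
from isonet.exceptions import FeatureError
from isonet.sequence_features import (
    GROUP_NAMES,
    FeatureGroupVector,
    MoranConfig,
    compute_all_sequence_groups,
    conjoint_triad,
    group_lengths,
    kmer_composition,
    moran_autocorrelation,
    pseudo_aac,
)


def brute_force_kmer_counts(sequence, k, alphabet):
    """Independent oracle: direct substring counting per k-mer key."""
    import itertools

    l = len(sequence)
    denom = l - (k - 1)
    out = {}
    for combo in itertools.product(sorted(alphabet), repeat=k):
        kmer = "".join(combo)
        count = sum(
            1 for i in range(l - k + 1) if sequence[i: i + k] == kmer
        )
        out[kmer] = count / denom
    return out


class TestKmerComposition:
    def test_atcg_k3(self):
        vec = kmer_composition("ATCG", 3, MRNA_ALPHABET).as_dict()
        assert vec["ATC"] == pytest.approx(0.5)
        assert vec["TCG"] == pytest.approx(0.5)
        assert sum(v for k, v in vec.items() if k not in ("ATC", "TCG")) == 0

    def test_homopolymer(self):
        vec = kmer_composition("AAAA", 3, MRNA_ALPHABET).as_dict()
        assert vec["AAA"] == pytest.approx(1.0)

    def test_k6_vector_length(self):
        vec = kmer_composition("ACGT" * 3, 6, MRNA_ALPHABET)
        assert len(vec.keys) == 4**6 == 4096

    def test_too_short_rejected(self):
        with pytest.raises(FeatureError, match="length"):
            kmer_composition("AC", 3, MRNA_ALPHABET)

    def test_out_of_alphabet_rejected(self):
        with pytest.raises(FeatureError, match="alphabet"):
            kmer_composition("ACGN", 2, MRNA_ALPHABET)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_agrees_with_brute_force_oracle(self, k):
        rng = np.random.default_rng(123 + k)
        for _ in range(170):  # ~1000 sequences across the 6 parametrizations
            length = int(rng.integers(k, 40))
            seq = "".join(rng.choice(list(MRNA_ALPHABET), size=length))
            vec = kmer_composition(seq, k, MRNA_ALPHABET).as_dict()
            oracle = brute_force_kmer_counts(seq, k, MRNA_ALPHABET)
            assert vec == pytest.approx(oracle, abs=1e-12)
            assert sum(vec.values()) == pytest.approx(1.0, abs=1e-12)

    def test_protein_alphabet(self):
        vec = kmer_composition("ACDAC", 2, AMINO_ACIDS)
        assert len(vec.keys) == 400
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestConjointTriad:
    def test_homopolymer_single_triad(self):
        vec = conjoint_triad("AAAAA").as_dict()
        assert vec["111"] == pytest.approx(1.0)

    def test_hand_reduced_example(self):
        # A->1, D->6, C->7, A->1, R->5: triads 167, 671, 715 each 1/3
        vec = conjoint_triad("ADCAR").as_dict()
        for triad in ("167", "671", "715"):
            assert vec[triad] == pytest.approx(1 / 3)

    def test_vector_length_343(self):
        assert len(conjoint_triad("ACDEFG").keys) == 7**3 == 343

    def test_too_short_rejected(self):
        with pytest.raises(FeatureError):
            conjoint_triad("AC")


def pseudo_aac_oracle(seq, lam, weight):
    """Independent direct-formula implementation of Chou's pseudo-AAC."""
    from isonet.sequence_features import (
        HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS,
    )

    def standardize(table):
        vals = [table[a] for a in AMINO_ACIDS]
        mu = sum(vals) / 20
        sd = (sum((v - mu) ** 2 for v in vals) / 20) ** 0.5
        return {a: (table[a] - mu) / sd for a in AMINO_ACIDS}

    scales = [standardize(t) for t in (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS)]
    n = len(seq)
    freqs = [seq.count(a) / n for a in AMINO_ACIDS]
    thetas = []
    for d in range(1, lam + 1):
        total = 0.0
        for i in range(n - d):
            total += sum(
                (s[seq[i + d]] - s[seq[i]]) ** 2 for s in scales
            ) / 3.0
        thetas.append(total / (n - d))
    denom = sum(freqs) + weight * sum(thetas)
    return [f / denom for f in freqs] + [weight * t / denom for t in thetas]


class TestPseudoAac:
    def test_lambda_zero_is_plain_composition(self):
        seq = "ACDEFGHIKLMNPQRSTVWYAAC"
        vec = pseudo_aac(seq, lam=0, weight=0.05)
        comp = np.array([seq.count(a) / len(seq) for a in AMINO_ACIDS])
        assert vec.values == pytest.approx(comp, abs=1e-12)

    def test_weight_zero_tail_is_zero(self):
        seq = "ACDEFGHIKLMNPQRSTVWYAAC"
        vec = pseudo_aac(seq, lam=5, weight=0.0)
        comp = np.array([seq.count(a) / len(seq) for a in AMINO_ACIDS])
        assert vec.values[:20] == pytest.approx(comp, abs=1e-12)
        assert vec.values[20:] == pytest.approx(np.zeros(5), abs=0)

    def test_sums_to_one_and_length(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        vec = pseudo_aac(seq, lam=25, weight=0.05)
        assert len(vec.values) == 45
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_direct_formula_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
            vec = pseudo_aac(seq, lam=10, weight=0.1)
            oracle = pseudo_aac_oracle(seq, 10, 0.1)
            assert vec.values == pytest.approx(np.array(oracle), abs=1e-9)

    def test_length_not_exceeding_lambda_rejected(self):
        with pytest.raises(FeatureError, match="lambda"):
            pseudo_aac("ACDEF", lam=5, weight=0.05)


class TestMoranAutocorrelation:
    def test_hand_example_lag1_is_zero(self):
        # P = (1, 2, 3): centered (-1, 0, 1); numerator (1/2)((-1)(0)+(0)(1)) = 0
        scale = {a: 0.0 for a in AMINO_ACIDS}
        scale.update({"A": 1.0, "C": 2.0, "D": 3.0})
        config = MoranConfig(property_scales={"toy": scale}, nlag=1)
        vec = moran_autocorrelation("ACD", config).as_dict()
        assert vec["toy_lag01"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_property_sequence_zero_everywhere(self):
        vec = moran_autocorrelation("AAAAAAAA")
        assert np.all(vec.values == 0.0)

    def test_lags_beyond_length_are_zero(self):
        vec = moran_autocorrelation("ACDEF", MoranConfig(nlag=10)).as_dict()
        # N - d < 1 for d >= 5
        for name, value in vec.items():
            if int(name[-2:]) >= 5:
                assert value == 0.0

    def test_affine_invariance_of_property_scales(self):
        """I(d) is unchanged by P -> a*P + b for every scale and lag."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        base = {a: float(rng.normal()) for a in AMINO_ACIDS}
        for a_coef, b_coef in ((2.5, -3.0), (-0.7, 11.0)):
            rescaled = {k: a_coef * v + b_coef for k, v in base.items()}
            cfg1 = MoranConfig(property_scales={"s": base}, nlag=20)
            cfg2 = MoranConfig(property_scales={"s": rescaled}, nlag=20)
            v1 = moran_autocorrelation(seq, cfg1).values
            v2 = moran_autocorrelation(seq, cfg2).values
            assert v1 == pytest.approx(v2, abs=1e-10)

    def test_brute_force_formula_agreement(self):
        """Direct loop evaluation of I(d) matches the implementation."""
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        config = MoranConfig(nlag=8)
        vec = moran_autocorrelation(seq, config).as_dict()
        for scale_name in config.property_scales:
            table = config.property_scales[scale_name]
            vals = np.array([table[a] for a in AMINO_ACIDS])
            std_table = {
                a: (table[a] - vals.mean()) / vals.std() for a in AMINO_ACIDS
            }
            p = [std_table[a] for a in seq]
            n = len(p)
            pbar = sum(p) / n
            denom = sum((x - pbar) ** 2 for x in p) / n
            for d in range(1, 9):
                num = sum(
                    (p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)
                ) / (n - d)
                assert vec[f"{scale_name}_lag{d:02d}"] == pytest.approx(
                    num / denom, abs=1e-12
                )


class TestComputeAllGroups:
    def test_nine_groups_with_documented_lengths(self):
        record = IsoformRecord(
            "I1", "G1", "ACGT" * 40,
            "ACDEFGHIKLMNPQRSTVWY" * 3,
        )
        groups = compute_all_sequence_groups(record)
        assert tuple(groups) == GROUP_NAMES
        lengths = group_lengths()
        for name, vec in groups.items():
            assert len(vec.values) == lengths[name]
            assert np.isfinite(vec.values).all()

    def test_frequency_groups_sum_to_one(self):
        record = IsoformRecord(
            "I1", "G1", "ACCGTA" * 30, "MKLVFF" * 12
        )
        groups = compute_all_sequence_groups(record)
        for name in ("mrna_3mer", "mrna_4mer", "mrna_5mer", "mrna_6mer",
                     "prot_1mer", "prot_2mer", "conjoint_triad", "pseudo_aac"):
            assert groups[name].values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_across_calls(self):
        record = IsoformRecord("I1", "G1", "ACGT" * 50, "ACDEFGHIKLMNPQRSTVWY" * 2)
        g1 = compute_all_sequence_groups(record)
        g2 = compute_all_sequence_groups(record)
        for name in GROUP_NAMES:
            assert g1[name].keys == g2[name].keys
            assert np.array_equal(g1[name].values, g2[name].values)

    def test_thirty_residue_protein_featurizable(self):
        """The minimum retained protein length works at every lag."""
        record = IsoformRecord(
            "I1", "G1", "ACGT" * 20, "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        )
        groups = compute_all_sequence_groups(record)
        assert np.isfinite(groups["moran"].values).all()

    def test_mismatched_keys_rejected(self):
        with pytest.raises(FeatureError):
            FeatureGroupVector("x", ("a", "b"), np.zeros(3))
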