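import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rapep import Peptide, build_feature_matrix, kmer_composition
from rapep.datasets import AMINO_ACIDS
from rapep.features import (
    PeptideFeaturizer,
    UndefinedFeatureError,
    ctd_features,
    misc_family_features,
    terminal_18mer,
    terminal_binary_profile,
)

peptides = st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=20)


class TestKmerComposition:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAAA", 1, {"AAC_A": 100.0}),
            ("ARAR", 2, {"DPC_AR": 200.0 / 3, "DPC_RA": 100.0 / 3}),
            ("GPYGPY", 1, {"AAC_G": 100.0 / 3, "AAC_P": 100.0 / 3, "AAC_Y": 100.0 / 3}),
        ],
    )
    def test_examples(self, seq, k, expected):
        vec = kmer_composition(seq, k)
        for name, val in expected.items():
            assert vec[name] == pytest.approx(val)
        others = sum(v for n, v in vec.items() if n not in expected)
        assert others == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(peptides, st.sampled_from([1, 2, 3]))
    def test_rows_sum_to_100(self, seq, k):
        assert sum(kmer_composition(seq, k).values()) == pytest.approx(100.0, abs=1e-9)
        assert len(kmer_composition(seq, k)) == 20 ** k

    def test_too_short_raises(self):
        with pytest.raises(UndefinedFeatureError):
            kmer_composition("AC", 3)


class TestCTD:
    toy = {"X": (frozenset("A"), frozenset("R"), frozenset(set(AMINO_ACIDS) - set("AR")))}

    def test_toy_partition_hand_enumeration(self):
        vec = ctd_features("AARR", self.toy)
        assert [vec[f"CeTD_c_X{g}"] for g in (1, 2, 3)] == [0.5, 0.5, 0.0]
        assert vec["CeTD_12_X"] == pytest.approx(1 / 3)
        assert vec["CeTD_13_X"] == vec["CeTD_23_X"] == 0.0
        g1 = [vec[f"CeTD_{t}_p_X1"] for t in ("0", "25", "50", "75", "100")]
        g2 = [vec[f"CeTD_{t}_p_X2"] for t in ("0", "25", "50", "75", "100")]
        assert g1 == pytest.approx([0.25, 0.25, 0.5, 0.5, 0.5])
        assert g2 == pytest.approx([0.75, 0.75, 1.0, 1.0, 1.0])
        assert all(vec[f"CeTD_{t}_p_X3"] == 0.0 for t in ("0", "25", "50", "75", "100"))

    def test_homopolymer_distribution(self):
        vec = ctd_features("A" * 9)
        for prop in ("HB", "VW", "PO", "PZ", "CH", "SS", "SA"):
            comps = [vec[f"CeTD_c_{prop}{g}"] for g in (1, 2, 3)]
            g_a = comps.index(1.0) + 1
            assert sum(comps) == pytest.approx(1.0)
            assert vec[f"CeTD_12_{prop}"] == vec[f"CeTD_13_{prop}"] == vec[f"CeTD_23_{prop}"] == 0.0
            dist = [vec[f"CeTD_{t}_p_{prop}{g_a}"] for t in ("0", "25", "50", "75", "100")]
            assert dist == pytest.approx([1 / 9, 3 / 9, 5 / 9, 7 / 9, 1.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(peptides)
    def test_invariants(self, seq):
        vec = ctd_features(seq)
        assert all(0.0 <= v <= 1.0 for v in vec.values())
        for prop in ("HB", "VW", "PO", "PZ", "CH", "SS", "SA"):
            assert sum(vec[f"CeTD_c_{prop}{g}"] for g in (1, 2, 3)) == pytest.approx(1.0)
            for g in (1, 2, 3):
                dist = [vec[f"CeTD_{t}_p_{prop}{g}"] for t in ("0", "25", "50", "75", "100")]
                assert dist == sorted(dist)

    def test_bad_partition_rejected(self):
        broken = {"X": (frozenset("A"), frozenset("A"), frozenset("R"))}
        with pytest.raises(ValueError):
            ctd_features("AARR", broken)


class TestTerminalProfile:
    def test_9mer_duplicates_into_c_block(self):
        assert terminal_18mer("ACDEFGHIK") == "ACDEFGHIKACDEFGHIK"

    def test_12mer_substring_rule(self):
        assert terminal_18mer("ACDEFGHIKLMN") == "ACDEFGHIK" + "EFGHIKLMN"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(peptides)
    def test_one_hot_sums_to_18(self, seq):
        vec = terminal_binary_profile(seq)
        assert len(vec) == 360
        assert sum(vec.values()) == 18.0

    def test_too_short_raises(self):
        with pytest.raises(UndefinedFeatureError):
            terminal_binary_profile("ACDEFGHI")


class TestMiscFamilies:
    def test_pri_negative_set_fractions(self):
        assert misc_family_features("DDEE", "PRI")["PRI_NE"] == 1.0
        assert misc_family_features("AAAA", "PRI")["PRI_NE"] == 0.0

    def test_shannon_entropy_per_residue(self):
        vec = misc_family_features("ARAR", "SER")
        assert vec["SER_A"] == pytest.approx(0.5)  # -0.5*log2(0.5)
        assert vec["SER_G"] == 0.0

    def test_btc_with_toy_table(self):
        table = {"A": {"total": 10.0, "hydrogen": 4.0, "single": 9.0, "double": 1.0}}
        vec = misc_family_features("AA", "BTC", bond_table=table)
        assert vec["BTC_T"] == 10.0 and vec["BTC_H"] == 4.0

    def test_ddr_gap_statistic(self):
        # A at positions 0, 2, 5 in a length-6 peptide: gaps 2 + 3 over L
        vec = misc_family_features("AGAGGA", "DDR")
        assert vec["DDR_A"] == pytest.approx(5 / 6)
        assert vec["DDR_W"] == 0.0

    def test_ctc_normalization(self):
        vec = misc_family_features("AAAA", "CTC")
        assert vec["CTC_111"] == pytest.approx(1.0)  # A is class 1; 2 triads / (L-2)
        assert sum(vec.values()) == pytest.approx(1.0)

    def test_apaac_shape_and_lambda_guard(self):
        vec = misc_family_features("ACDEFGHIK", "APAAC", lam=4)
        assert len(vec) == 20 + 2 * 4
        assert all(np.isfinite(list(vec.values())))
        # composition + weighted order factors normalize to exactly 1
        assert sum(vec.values()) == pytest.approx(1.0)
        with pytest.raises(UndefinedFeatureError):
            misc_family_features("ACDEFGHIK", "APAAC", lam=9)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            misc_family_features("ACDEFGHIK", "NOPE")


class TestFeatureMatrix:
    def test_single_family_shape(self, tiny_data):
        m = build_feature_matrix(tiny_data.peptides[:3], families=("AAC",))
        assert m.shape == (3, 20)

    def test_family_blocks_are_ordered(self, tiny_data):
        m = build_feature_matrix(tiny_data.peptides[:3], families=("AAC", "DPC"))
        assert m.shape == (3, 420)
        assert list(m.columns[:20]) == [f"AAC_{r}" for r in AMINO_ACIDS]
        assert m.columns[20].startswith("DPC_")

    def test_allcomp_expands_and_tags_families(self, tiny_data):
        m = build_feature_matrix(tiny_data.peptides[:2], families=("ALLCOMP",))
        fams = set(m.attrs["family_tags"].values())
        assert {"AAC", "DPC", "TPC", "BTC", "DDR", "CTC", "PRI", "SER", "APAAC", "CeTD"} <= fams

    def test_deterministic_and_id_invariant(self):
        a = build_feature_matrix([Peptide("x", "ACDEFGHIK")], families=("CeTD",))
        b = build_feature_matrix([Peptide("y", "ACDEFGHIK")], families=("CeTD",))
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_precondition_error_names_peptide_and_family(self):
        with pytest.raises(UndefinedFeatureError, match="short.*TPC|TPC"):
            build_feature_matrix([Peptide("short", "AC")], families=("TPC",))


def test_feature_matrix_csv_roundtrip(tmp_path, tiny_data):
    from rapep.features import read_feature_matrix, write_feature_matrix

    m = build_feature_matrix(tiny_data.peptides[:4], families=("AAC", "PRI"))
    write_feature_matrix(m, tmp_path / "m.csv")
    back = read_feature_matrix(tmp_path / "m.csv")
    assert np.allclose(m.to_numpy(), back.to_numpy())
    assert back.attrs["families"] == ["AAC", "PRI"]


class TestFeaturizer:
    def test_sklearn_contract(self, tiny_data):
        from sklearn.base import clone

        f = PeptideFeaturizer(families=("AAC", "PRI"))
        clone(f)  # get_params/set_params round-trip
        out = f.fit_transform(tiny_data.sequences)
        assert out.shape == (len(tiny_data), 30)
        assert list(f.get_feature_names_out()) == list(out.columns)

    def test_transform_matches_function_api(self, tiny_data):
        f = PeptideFeaturizer(families=("CeTD",)).fit(tiny_data.sequences)
        direct = build_feature_matrix(tiny_data.sequences, families=("CeTD",))
        assert np.allclose(f.transform(tiny_data.sequences).to_numpy(), direct.to_numpy())
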