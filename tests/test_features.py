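import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hspkit import features as ft
from hspkit.features import (
    AAPropertyTable,
    CTDAttribute,
    CTDScheme,
    PAACConfig,
    SequenceTooShortError,
    ZeroVarianceError,
)
from hspkit.seqio import AMINO_ACIDS, ProteinSequence

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=50).map(
    lambda s: ProteinSequence("h", s)
)


def brute_force_gpc(residues: str, G: int) -> dict[str, float]:
    """Independent oracle: enumerate every (p, p+G+1) pair directly."""
    n = len(residues)
    counts: dict[str, float] = {}
    for p in range(n - G - 1):
        key = f"g{G}_{residues[p]}{residues[p + G + 1]}"
        counts[key] = counts.get(key, 0) + 1
    return {k: v / (n - G - 1) for k, v in counts.items()}


def paac_reference(residues: str, table: dict[str, float], d: int, w: float):
    """Independent transcription of the pseudo amino-acid composition
    equations with plain loops."""
    vals = [table[a] for a in AMINO_ACIDS]
    mean = sum(vals) / 20
    rms = (sum((v - mean) ** 2 for v in vals) / 20) ** 0.5
    theta = {a: (table[a] - mean) / rms for a in AMINO_ACIDS}
    L = len(residues)
    rho = [
        sum((theta[residues[i]] - theta[residues[i + j]]) ** 2 for i in range(L - j))
        / (L - j)
        for j in range(1, d + 1)
    ]
    f = [residues.count(a) for a in AMINO_ACIDS]
    den = sum(f) + w * sum(rho)
    return [fi / den for fi in f] + [w * r / den for r in rho]


class TestGPC:
    def test_homopolymer(self):
        fv = ft.gpc(ProteinSequence("h", "AAA"), G=0)
        vals = dict(zip(fv.names, fv.values))
        assert vals["g0_AA"] == 1.0
        assert sum(v != 0 for v in fv.values) == 1
        assert fv.values.sum() == 1.0

    def test_skip_one_pairs(self):
        fv = ft.gpc(ProteinSequence("h", "ACAC"), G=1)
        vals = dict(zip(fv.names, fv.values))
        assert vals["g1_AA"] == 0.5
        assert vals["g1_CC"] == 0.5

    @pytest.mark.parametrize("G", [0, 1, 2, 3, 7])
    def test_length_400(self, G, random_seq):
        assert len(ft.gpc(random_seq(30), G)) == 400

    def test_too_short_error_names_n_and_g(self):
        with pytest.raises(SequenceTooShortError, match=r"G=2.*N=3"):
            ft.gpc(ProteinSequence("h", "MKV"), G=2)

    def test_matches_brute_force_oracle(self, random_seq):
        for i in range(200):
            seq = random_seq(6 + i % 45, f"r{i}")
            for G in range(4):
                fv = ft.gpc(seq, G)
                got = dict(zip(fv.names, fv.values))
                expected = brute_force_gpc(seq.residues, G)
                for name, v in got.items():
                    assert v == expected.get(name, 0.0)

    @given(seq_strategy, st.integers(0, 3))
    def test_normalized_in_unit_interval(self, seq, G):
        fv = ft.gpc(seq, G)
        assert abs(fv.values.sum() - 1.0) < 1e-12
        assert (fv.values >= 0).all() and (fv.values <= 1).all()


class TestGPCCombined:
    def test_four_gap_combination_has_1600_descriptors(self, random_seq):
        fv = ft.gpc_combined(random_seq(40), gaps=(0, 1, 2, 3))
        assert len(fv) == 1600
        assert len(set(fv.names)) == 1600

    def test_singleton_gap_equals_plain_gpc(self, random_seq):
        seq = random_seq(25)
        np.testing.assert_array_equal(
            ft.gpc_combined(seq, gaps=(0,)).values, ft.gpc(seq, 0).values
        )

    def test_each_block_sums_to_one(self, random_seq):
        fv = ft.gpc_combined(random_seq(35), gaps=(0, 1, 2, 3))
        for b in range(4):
            assert abs(fv.values[400 * b : 400 * (b + 1)].sum() - 1.0) < 1e-12

    def test_propagates_short_sequence_naming_gap(self):
        with pytest.raises(SequenceTooShortError, match="G=3"):
            ft.gpc_combined(ProteinSequence("h", "MKVL"), gaps=(0, 3))


class TestPAAC:
    def test_dimension_20_plus_d(self, random_seq):
        assert len(ft.paac(random_seq(30))) == 21
        assert len(ft.paac(random_seq(30), PAACConfig(d=4))) == 24

    def test_homopolymer_correlation_vanishes(self):
        fv = ft.paac(ProteinSequence("h", "A" * 10))
        vals = dict(zip(fv.names, fv.values))
        assert vals["paac_rho1"] == 0.0
        assert vals["paac_A"] == 1.0

    def test_matches_reference_equations(self, random_seq, rng):
        for i in range(20):
            seq = random_seq(10 + i, f"r{i}")
            table = {a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))}
            config = PAACConfig(d=3, w=0.11, property_table=AAPropertyTable("t", table))
            got = ft.paac(seq, config).values
            expected = paac_reference(seq.residues, table, d=3, w=0.11)
            np.testing.assert_allclose(got, expected, atol=1e-12)
            assert abs(got.sum() - 1.0) < 1e-9

    @given(st.permutations(list(AMINO_ACIDS)))
    def test_relabeling_invariance(self, perm):
        # permute residues and the property table identically: the multiset
        # of descriptor values is unchanged
        base = ProteinSequence("h", "MKVLAHERTYMKVHA")
        mapping = dict(zip(AMINO_ACIDS, perm))
        table = ft.default_paac_table()
        relabeled = ProteinSequence("h", "".join(mapping[a] for a in base.residues))
        permuted = AAPropertyTable(
            "perm", {mapping[a]: table.values[a] for a in AMINO_ACIDS}
        )
        v1 = ft.paac(base, PAACConfig(property_table=table)).values
        v2 = ft.paac(relabeled, PAACConfig(property_table=permuted)).values
        np.testing.assert_allclose(np.sort(v1), np.sort(v2), atol=1e-12)

    def test_short_sequence_and_constant_table_errors(self):
        with pytest.raises(SequenceTooShortError):
            ft.paac(ProteinSequence("h", "MK"), PAACConfig(d=2))
        const = AAPropertyTable("c", {a: 1.0 for a in AMINO_ACIDS})
        with pytest.raises(ZeroVarianceError):
            ft.paac(ProteinSequence("h", "MKVLA"), PAACConfig(property_table=const))


def one_group_attr():
    g1 = frozenset("ACDEFGH")
    g2 = frozenset("IKLMNPQ")
    g3 = frozenset("RSTVWY")
    return CTDAttribute("toy", (g1, g2, g3))


class TestCTD:
    def test_default_scheme_dimension(self, random_seq):
        assert len(ft.ctd(random_seq(30))) == 147  # 7 attributes x 21

    def test_sequence_within_one_group(self):
        scheme = CTDScheme((one_group_attr(),))
        fv = ft.ctd(ProteinSequence("h", "ACDE"), scheme)  # all in group 1
        vals = dict(zip(fv.names, fv.values))
        assert [vals["ctd_toy_C1"], vals["ctd_toy_C2"], vals["ctd_toy_C3"]] == [1, 0, 0]
        assert vals["ctd_toy_T12"] == vals["ctd_toy_T13"] == vals["ctd_toy_T23"] == 0
        d1 = [vals[f"ctd_toy_D1_{p}"] for p in ("first", "25", "50", "75", "100")]
        assert d1 == [0.25, 0.25, 0.5, 0.75, 1.0]
        assert all(vals[f"ctd_toy_D2_{p}"] == 0 for p in ("first", "25", "50", "75", "100"))

    def test_transitions_count_both_orders(self):
        scheme = CTDScheme((one_group_attr(),))
        # A(g1) I(g2) A(g1) R(g3): transitions 12,21,13 -> T12=2/3, T13=1/3
        fv = ft.ctd(ProteinSequence("h", "AIAR"), scheme)
        vals = dict(zip(fv.names, fv.values))
        assert vals["ctd_toy_T12"] == pytest.approx(2 / 3)
        assert vals["ctd_toy_T13"] == pytest.approx(1 / 3)
        assert vals["ctd_toy_T23"] == 0.0

    @given(seq_strategy)
    def test_composition_partition_and_distribution_monotone(self, seq):
        fv = ft.ctd(seq)
        vals = dict(zip(fv.names, fv.values))
        for attr in ft.default_ctd_scheme().attributes:
            c = [vals[f"ctd_{attr.name}_C{g}"] for g in (1, 2, 3)]
            assert abs(sum(c) - 1.0) < 1e-12
            for g in (1, 2, 3):
                d = [vals[f"ctd_{attr.name}_D{g}_{p}"]
                     for p in ("first", "25", "50", "75", "100")]
                if d[0] > 0:  # group present
                    assert all(x <= y + 1e-12 for x, y in zip(d, d[1:]))
                    assert all(0 < x <= 1 for x in d)
                else:
                    assert d == [0, 0, 0, 0, 0]

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            ft.ctd(ProteinSequence("h", "A"))


class TestACF:
    def test_homopolymer_lag1_is_squared_standardized_value(self):
        table = ft.default_paac_table()
        z = table.standardized()[AMINO_ACIDS.index("W")]
        fv = ft.acf(ProteinSequence("h", "W" * 12), [table], order=1)
        assert fv.values[0] == pytest.approx(z**2)

    def test_dimension_tables_times_order(self, random_seq):
        tables = ft.default_property_tables()
        assert len(ft.acf(random_seq(30), tables, order=2)) == len(tables) * 2
        assert len(ft.acf(random_seq(30), tables[:3], order=1)) == 3

    @given(seq_strategy)
    def test_reversal_symmetry(self, seq):
        rev = ProteinSequence("h", seq.residues[::-1])
        np.testing.assert_allclose(
            ft.acf(seq, order=2).values, ft.acf(rev, order=2).values, atol=1e-12
        )

    def test_errors(self):
        with pytest.raises(SequenceTooShortError):
            ft.acf(ProteinSequence("h", "MK"), order=2)
        const = AAPropertyTable("c", {a: 2.0 for a in AMINO_ACIDS})
        with pytest.raises(ZeroVarianceError):
            ft.acf(ProteinSequence("h", "MKVLA"), [const], order=1)


class TestEncodeDataset:
    def test_shape_and_row_consistency(self, random_seq):
        seqs = [random_seq(20 + i, f"s{i}") for i in range(3)]
        X = ft.encode_dataset(seqs, {"name": "gpc_combined", "gaps": [0, 1, 2, 3]})
        assert X.shape == (3, 1600)
        np.testing.assert_array_equal(
            X.iloc[1].to_numpy(), ft.gpc_combined(seqs[1]).values
        )

    def test_empty_dataset_keeps_columns(self):
        X = ft.encode_dataset([], {"name": "gpc_combined", "gaps": [0, 1, 2, 3]})
        assert X.shape == (0, 1600)

    def test_all_failing_ids_reported(self, random_seq):
        seqs = [
            ProteinSequence("bad1", "MK"),
            random_seq(30, "ok"),
            ProteinSequence("bad2", "AC"),
        ]
        with pytest.raises(ft.EncodingError) as err:
            ft.encode_dataset(seqs, {"name": "gpc_combined", "gaps": [0, 1, 2, 3]})
        assert set(err.value.failures) == {"bad1", "bad2"}

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="unknown encoder"):
            ft.make_encoder({"name": "zpc"})
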