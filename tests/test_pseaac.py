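import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acescreen.pseaac import (
    DegenerateEncodingError,
    PeptideTooShortError,
    PropertyTable,
    PseAACParams,
    correlation_factor,
    encode,
    encode_batch,
    standardize_properties,
)
from acescreen.seqio import CANONICAL_AA, Peptide
from conftest import random_peptide
from oracles import load_standardized_scales, pseaac_oracle


def toy_table(values_per_property):
    """PropertyTable from explicit standardized 20-vectors (bypasses scaling)."""
    arr = np.asarray(values_per_property, dtype=float)
    return PropertyTable(
        names=tuple(f"prop{i}" for i in range(arr.shape[0])),
        raw=arr,
        standardized=arr,
    )


class TestStandardize:
    def test_population_sd_convention(self):
        # residue with raw value 1 in the row 1..20: (1 - 10.5)/sqrt(33.25)
        raw = np.vstack([np.arange(1, 21, dtype=float)] * 6)
        table = standardize_properties(raw)
        expected = (1 - 10.5) / math.sqrt(33.25)
        assert table.standardized[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.6475, abs=5e-5)

    def test_rows_have_zero_mean_unit_sd(self, property_table):
        assert np.abs(property_table.standardized.mean(axis=1)).max() < 1e-10
        assert np.abs(property_table.standardized.std(axis=1, ddof=0) - 1).max() < 1e-10
        # raw rows retained unchanged and non-constant
        assert property_table.raw.shape == (6, 20)
        assert (property_table.raw.std(axis=1) > 0).all()

    def test_constant_row_rejected(self):
        raw = np.vstack([np.full(20, 5.0)] + [np.arange(20, dtype=float)] * 5)
        with pytest.raises(ValueError, match="constant"):
            standardize_properties(raw)

    def test_shipped_table_names_and_order(self, property_table):
        assert property_table.names == (
            "hydrophobicity", "hydrophilicity", "mass", "pK1", "pK2", "pI",
        )


class TestCorrelationFactor:
    def test_single_adjacent_pair(self):
        row = np.zeros(20)
        row[CANONICAL_AA.index("G")] = -0.5
        row[CANONICAL_AA.index("L")] = 1.0
        tau = correlation_factor(Peptide("p", "GL"), row, lag=1)
        assert tau == pytest.approx(-0.5)

    def test_homopolymer_equals_square(self, property_table):
        row = property_table.row("hydrophobicity")
        h_a = row[CANONICAL_AA.index("A")]
        tau = correlation_factor(Peptide("p", "AAAA"), row, lag=1)
        assert tau == pytest.approx(h_a**2)

    def test_lag_not_smaller_than_length_errors(self, property_table):
        row = property_table.row("mass")
        with pytest.raises(PeptideTooShortError):
            correlation_factor(Peptide("p", "GL"), row, lag=2)


class TestEncode:
    def test_default_parameters_give_26_dimensions(self, property_table):
        vec = encode(Peptide("p", "IPP"), property_table)
        assert len(vec.values) == 26
        assert PseAACParams().dimension == 26

    def test_closed_form_homopolymer(self):
        # H_p(A)=1 for all six properties: f_A=1, each tau=1, denom=1.3
        rows = np.zeros((6, 20))
        rows[:, CANONICAL_AA.index("A")] = 1.0
        table = toy_table(rows)
        vec = encode(Peptide("p", "AA"), table)
        a_idx = CANONICAL_AA.index("A")
        assert vec.values[a_idx] == pytest.approx(1 / 1.3)
        assert vec.values[20:] == pytest.approx(np.full(6, 0.05 / 1.3))
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, property_table):
        scales = load_standardized_scales()
        r = random.Random(1234)
        for _ in range(200):
            pep = random_peptide(r, 2, 50)
            got = encode(pep, property_table).values
            want = pseaac_oracle(pep.sequence, scales)
            np.testing.assert_allclose(got, want, atol=1e-12, rtol=0)

    def test_sum_to_one_on_many_random_peptides(self, property_table):
        r = random.Random(99)
        for _ in range(1000):
            pep = random_peptide(r, 2, 30)
            assert abs(encode(pep, property_table).values.sum() - 1.0) < 1e-9

    def test_composition_entry_zero_iff_residue_absent(self, property_table):
        vec = encode(Peptide("p", "GLP"), property_table)
        present = {CANONICAL_AA.index(c) for c in "GLP"}
        for u in range(20):
            assert (vec.values[u] != 0) == (u in present)

    def test_too_short_for_lambda(self, property_table):
        with pytest.raises(PeptideTooShortError):
            encode(Peptide("p", "AW"), property_table, PseAACParams(lambda_=2))

    def test_degenerate_denominator_guard(self):
        # omega*sum(tau) == -1 exactly: H=const c with 6*omega*c^2 = -? need
        # negative products: alternate +c/-c residues -> tau = -c^2 each.
        c = math.sqrt(1 / 0.3)  # 6 * 0.05 * c^2 = 1
        rows = np.zeros((6, 20))
        rows[:, CANONICAL_AA.index("A")] = c
        rows[:, CANONICAL_AA.index("G")] = -c
        with pytest.raises(DegenerateEncodingError):
            encode(Peptide("p", "AG"), toy_table(rows))

    def test_order_sensitivity_same_composition(self, property_table):
        # lag-1 products are symmetric, so reversals tie; this pair's
        # adjacent products genuinely differ:
        v1 = encode(Peptide("a", "AKLW"), property_table).values
        v2 = encode(Peptide("b", "KAWL"), property_table).values
        ratio = v1[:20][v1[:20] > 0] / v2[:20][v2[:20] > 0]
        assert np.allclose(ratio, ratio[0])  # composition block scales identically
        assert not np.allclose(v1[20:], v2[20:])  # correlation block differs

    def test_omega_to_zero_recovers_composition(self, property_table):
        pep = Peptide("p", "GLPW")
        vec = encode(pep, property_table, PseAACParams(omega=1e-12))
        freqs = np.array([pep.sequence.count(aa) / 4 for aa in CANONICAL_AA])
        np.testing.assert_allclose(vec.values[:20], freqs, atol=1e-9)
        np.testing.assert_allclose(vec.values[20:], 0, atol=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seq=st.text(alphabet=CANONICAL_AA, min_size=4, max_size=40),
        lam=st.integers(1, 3),
        nprop=st.integers(1, 6),
    )
    def test_dimension_is_20_plus_i_lambda(self, property_table, seq, lam, nprop):
        sub = PropertyTable(
            names=property_table.names[:nprop],
            raw=property_table.raw[:nprop],
            standardized=property_table.standardized[:nprop],
        )
        params = PseAACParams(lambda_=lam, n_properties=nprop)
        vec = encode(Peptide("p", seq), sub, params)
        assert len(vec.values) == 20 + nprop * lam
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestEncodeBatch:
    def test_batch_of_valid_peptides(self, property_table):
        peps = [Peptide(f"p{i}", s) for i, s in enumerate(["AW", "IPP", "VPPG"])]
        X, ids, skipped = encode_batch(peps, property_table)
        assert X.shape == (3, 26)
        assert ids == ["p0", "p1", "p2"]
        assert skipped == []

    def test_short_peptides_skipped_and_reported(self, property_table):
        peps = [Peptide("a", "AW"), Peptide("b", "G")]
        X, ids, skipped = encode_batch(peps, property_table)
        assert X.shape == (1, 26)
        assert ids == ["a"]
        assert [s[0] for s in skipped] == ["b"]

    def test_all_unencodable_raises(self, property_table):
        with pytest.raises(ValueError, match="no encodable"):
            encode_batch([Peptide("a", "G")], property_table)
        with pytest.raises(ValueError, match="no encodable"):
            encode_batch([], property_table)
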