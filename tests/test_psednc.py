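"""PseDNC encoding against brute-force oracles and its invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dhspred import (
    DINUCLEOTIDES,
    POSITIVE,
    NucleotideSequence,
    PropertyTable,
    dinucleotide_frequencies,
    encode_dataset,
    psednc_encode,
    theta_pair,
    tier_correlations,
)
from dhspred.exceptions import (
    DegeneratePropertyError,
    DhspredError,
    EncodingError,
    SequenceTooShortError,
)

from conftest import make_dataset, random_residues


# ---------------------------------------------------------------- oracles
def oracle_theta_pair(x: str, y: str, std_table) -> float:
    """Direct formula: mean squared difference of standardized values."""
    props = std_table.property_names
    return sum((std_table.value(p, x) - std_table.value(p, y)) ** 2 for p in props) / len(props)


def oracle_tier_correlations(residues: str, lam: int, std_table) -> list[float]:
    """Explicit index-formula summation, one pair at a time."""
    L = len(residues)
    theta = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - 1 - j):
            total += oracle_theta_pair(
                residues[i : i + 2], residues[i + j : i + j + 2], std_table
            )
        theta.append(total / (L - 1 - j))
    return theta


def oracle_psednc(residues: str, w: float, lam: int, std_table) -> list[float]:
    """Single-pass brute-force recomputation of the full descriptor."""
    L = len(residues)
    f = {d: 0 for d in DINUCLEOTIDES}
    for i in range(L - 1):
        f[residues[i : i + 2]] += 1
    freqs = [f[d] / (L - 1) for d in DINUCLEOTIDES]
    theta = oracle_tier_correlations(residues, lam, std_table)
    denom = sum(freqs) + w * sum(theta)
    return [x / denom for x in freqs] + [w * t / denom for t in theta]


def seq(residues: str) -> NucleotideSequence:
    return NucleotideSequence("s", residues)


# ---------------------------------------------------------------- frequencies
@pytest.mark.parametrize(
    "residues,expected",
    [
        ("AAAA", {"AA": 1.0}),
        ("ACGT", {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}),
        ("ACAC", {"AC": 2 / 3, "CA": 1 / 3}),
    ],
)
def test_dinucleotide_frequencies(residues, expected):
    f = dinucleotide_frequencies(seq(residues))
    for i, d in enumerate(DINUCLEOTIDES):
        assert f[i] == pytest.approx(expected.get(d, 0.0), abs=1e-15)
    assert f.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------- standardization
class TestStandardize:
    def _table_with_row(self, row):
        values = pd.DataFrame(
            [row, list(range(16))], index=["p1", "p2"], columns=list(DINUCLEOTIDES), dtype=float
        )
        return PropertyTable(values)

    def test_linear_row_closed_form(self):
        row = list(range(1, 17))
        std = self._table_with_row(row).standardize()
        got = [std.value("p1", d) for d in DINUCLEOTIDES]
        sd = math.sqrt(sum((x - 8.5) ** 2 for x in row) / 16)
        assert got[0] == pytest.approx((1 - 8.5) / sd, abs=1e-12)
        assert np.mean(got) == pytest.approx(0.0, abs=1e-9)
        assert np.std(got) == pytest.approx(1.0, abs=1e-9)

    def test_constant_row_is_degenerate(self):
        with pytest.raises(DegeneratePropertyError, match="p1"):
            self._table_with_row([3.0] * 16).standardize()

    def test_idempotent_within_1e12(self, std_table):
        again = PropertyTable(std_table.values.copy()).standardize()
        assert np.allclose(
            again.values.to_numpy(), std_table.values.to_numpy(), atol=1e-12
        )

    def test_packaged_table_standardizes_to_unit_moments(self, std_table):
        arr = std_table.values.to_numpy()
        assert np.allclose(arr.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(arr.std(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------- theta
class TestThetaPair:
    def test_zero_on_diagonal(self, table):
        assert theta_pair("AA", "AA", table) == 0.0

    def test_symmetric_over_all_256_pairs(self, table):
        m = table.theta_matrix()
        assert np.allclose(m, m.T, atol=0)
        assert np.allclose(np.diag(m), 0.0, atol=0)
        assert (m >= 0).all()

    def test_matches_direct_formula_oracle(self, table, std_table, rng):
        pairs = [("AC", "GT")] + [
            (rng.choice(DINUCLEOTIDES), rng.choice(DINUCLEOTIDES)) for _ in range(30)
        ]
        for x, y in pairs:
            assert theta_pair(x, y, table) == pytest.approx(
                oracle_theta_pair(x, y, std_table), abs=1e-12
            )

    def test_unknown_dinucleotide(self, table):
        with pytest.raises(DhspredError):
            theta_pair("AX", "GT", table)


class TestTierCorrelations:
    def test_homopolymer_gives_zeros(self, table):
        theta = tier_correlations(seq("AAAAAAA"), 3, table)
        assert np.allclose(theta, 0.0, atol=0)

    def test_alternating_repeat_structure(self, table):
        # ACACAC: tier 1 compares AC<->CA only; tier 2 compares identical steps
        theta = tier_correlations(seq("ACACAC"), 2, table)
        assert theta[0] == pytest.approx(theta_pair("AC", "CA", table), abs=1e-12)
        assert theta[1] == pytest.approx(0.0, abs=0)

    def test_too_short_sequence(self, table):
        with pytest.raises(SequenceTooShortError, match="length 4"):
            tier_correlations(seq("ACGT"), 3, table)

    def test_matches_brute_force_oracle(self, table, std_table, rng):
        for _ in range(20):
            residues = random_residues(rng, rng.randint(12, 60))
            lam = rng.randint(1, 8)
            got = tier_correlations(seq(residues), lam, table)
            expect = oracle_tier_correlations(residues, lam, std_table)
            assert np.allclose(got, expect, atol=1e-12)


# ---------------------------------------------------------------- encoding
class TestPsedncEncode:
    def test_weight_off_recovers_plain_composition(self, table, rng):
        residues = random_residues(rng, 50)
        v = psednc_encode(seq(residues), 0.0, 6, table)
        assert np.array_equal(v.components[:16], dinucleotide_frequencies(seq(residues)))
        assert np.array_equal(v.components[16:], np.zeros(6))

    def test_homopolymer_concentrates_on_aa(self, table):
        v = psednc_encode(seq("A" * 10), 0.2, 6, table)
        assert v.components[0] == pytest.approx(1.0, abs=0)
        assert np.allclose(v.components[1:], 0.0, atol=0)

    def test_random_200mer_matches_independent_oracle(self, table, std_table, rng):
        residues = random_residues(rng, 200)
        v = psednc_encode(seq(residues), 0.2, 6, table)
        assert v.dimension == 22
        expect = oracle_psednc(residues, 0.2, 6, std_table)
        assert np.allclose(v.components, expect, atol=1e-12)

    def test_oracle_equivalence_on_100_random_sequences(self, table, std_table, rng):
        for _ in range(100):
            residues = random_residues(rng, rng.randint(15, 120))
            w = rng.choice([0.0, 0.1, 0.2, 0.5, 1.0])
            lam = rng.randint(1, 10)
            got = psednc_encode(seq(residues), w, lam, table).components
            assert np.allclose(got, oracle_psednc(residues, w, lam, std_table), atol=1e-12)

    def test_invalid_weight(self, table):
        with pytest.raises(DhspredError):
            psednc_encode(seq("ACGTACGTAC"), 1.5, 2, table)

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        residues=st.text(alphabet="ACGT", min_size=12, max_size=80),
        w=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        lam=st.integers(min_value=1, max_value=10),
    )
    def test_normalization_invariant(self, table, residues, w, lam):
        """Every descriptor is a probability vector of dimension 16+lambda."""
        v = psednc_encode(seq(residues), w, lam, table)
        assert v.dimension == 16 + lam
        assert (v.components >= 0).all()
        assert v.components.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sequence_order_information_is_captured(self, table):
        """Rearrangements preserving dinucleotide counts still change theta."""
        base = "AACCGGTTAA"
        f0 = dinucleotide_frequencies(seq(base))
        changed = 0
        seen = set()
        for perm in itertools.permutations(base):
            s = "".join(perm)
            if s == base or s in seen:
                continue
            seen.add(s)
            if np.allclose(dinucleotide_frequencies(seq(s)), f0, atol=0):
                t0 = tier_correlations(seq(base), 3, table)
                t1 = tier_correlations(seq(s), 3, table)
                if not np.allclose(t0, t1, atol=1e-12):
                    changed += 1
                    break
        assert changed, "no composition-preserving rearrangement altered theta"


class TestEncodeDataset:
    def test_matrix_shape_and_labels(self, table, rng):
        data = make_dataset(
            [seq(random_residues(rng, 40)) for _ in range(3)],
            [POSITIVE, POSITIVE, "negative"],
        )
        # distinct ids required only at merge; here ids may repeat
        X, y = encode_dataset(data, w=0.2, lam=6, table=table)
        assert X.shape == (3, 22)
        assert y.tolist() == [1, 1, -1]

    def test_empty_dataset(self, table):
        X, y = encode_dataset(make_dataset([], []), w=0.2, lam=6, table=table)
        assert X.shape == (0, 22) and y.size == 0

    def test_aggregate_error_lists_offenders(self, table):
        data = make_dataset(
            [NucleotideSequence("ok", "ACGTACGTACGT"), NucleotideSequence("bad", "ACG")],
            [POSITIVE, POSITIVE],
        )
        with pytest.raises(EncodingError) as exc:
            encode_dataset(data, w=0.2, lam=6, table=table)
        assert exc.value.failed_ids == ("bad",)
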