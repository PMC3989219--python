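import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstscan.errors import ConfigurationError, DomainError, StructuralError
from fstscan.fst import (
    ComparisonSpec,
    FstEstimatorConfig,
    GroupFrequencies,
    comparison_fst,
    group_allele_frequencies,
    pair_fst_weir_cockerham,
    pair_fst_wright_nei,
    snp_fst,
)
from fstscan.genotype_io import GenotypeMatrix, SampleGroups, make_variant_table


def _grid():
    p = np.linspace(0.0, 1.0, 101)
    return np.meshgrid(p, p)


class TestWrightNei:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.0, 1.0),
            (0.0, 1.0, 1.0),
            (0.2, 0.8, 0.36),
        ],
    )
    def test_known_values(self, p1, p2, expected):
        assert snp_fst(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_same_allele_is_nan(self):
        assert np.isnan(snp_fst(0.0, 0.0))
        assert np.isnan(snp_fst(1.0, 1.0))

    def test_domain_error(self):
        with pytest.raises(DomainError):
            snp_fst(1.2, 0.5)
        with pytest.raises(DomainError):
            snp_fst(0.5, -0.1)

    def test_grid_properties(self):
        """Symmetry, [0,1] bounds, zero iff equal, one iff fixed difference."""
        P1, P2 = _grid()
        f = pair_fst_wright_nei(P1, P2)
        f_t = pair_fst_wright_nei(P2, P1)
        np.testing.assert_allclose(f, f_t, equal_nan=True)
        defined = ~np.isnan(f)
        assert (f[defined] >= 0).all() and (f[defined] <= 1).all()
        zero = defined & np.isclose(f, 0.0, atol=1e-12)
        np.testing.assert_array_equal(zero, defined & (P1 == P2))
        one = defined & np.isclose(f, 1.0, atol=1e-12)
        fixed = (P1 + P2 == 1.0) & ((P1 == 0.0) | (P1 == 1.0))
        np.testing.assert_array_equal(one, fixed)

    def test_algebraic_forms_agree(self):
        """(H_T - H_S)/H_T equals (p1-p2)^2 / (4 p̄ q̄) on the dense grid."""
        P1, P2 = _grid()
        pbar = 0.5 * (P1 + P2)
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = P1 * (1.0 - P1) + P2 * (1.0 - P2)
        with np.errstate(invalid="ignore", divide="ignore"):
            direct = (ht - hs) / ht
        ratio = pair_fst_wright_nei(P1, P2)
        defined = ~np.isnan(ratio)
        np.testing.assert_allclose(direct[defined], ratio[defined], atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_bounds_hold_for_arbitrary_frequencies(self, p1, p2):
        f = snp_fst(p1, p2)
        assert np.isnan(f) or 0.0 <= f <= 1.0 + 1e-15


def _wc_anova_oracle(calls_a, calls_b):
    """Weir-Cockerham theta via hierarchical ANOVA sums of squares.

    Each allele copy is a 0/1 observation nested in individuals nested in
    populations; a, b, c come from the mean squares.  Independent of the
    closed-form implementation under test.
    """
    pops = [np.asarray(calls_a, float), np.asarray(calls_b, float)]
    r = 2
    n_i = [len(p) for p in pops]
    n_tot = sum(n_i)
    p_i = [p.sum() / (2 * len(p)) for p in pops]
    p_w = sum(p.sum() for p in pops) / (2 * n_tot)

    ssp = sum(2 * n * (pi - p_w) ** 2 for n, pi in zip(n_i, p_i))
    ssi = sum(
        (2 * (pop / 2 - pi) ** 2).sum() for pop, pi in zip(pops, p_i)
    )
    ssg = sum((pop == 1).sum() * 0.5 for pop in pops)
    msp = ssp / (r - 1)
    msi = ssi / (n_tot - r)
    msg = ssg / (2 * n_tot - n_tot)
    n_c = (n_tot - sum(n**2 for n in n_i) / n_tot) / (r - 1)
    a = (msp - msi) / (2 * n_c)
    b = (msi - msg) / 2
    c = msg
    denom = a + b + c
    return a / denom if denom != 0 else np.nan


class TestWeirCockerham:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 30, size=2)
        calls_a = rng.integers(0, 3, n1)
        calls_b = rng.integers(0, 3, n2)
        p1 = calls_a.sum() / (2 * n1)
        p2 = calls_b.sum() / (2 * n2)
        h1 = (calls_a == 1).mean()
        h2 = (calls_b == 1).mean()
        got = pair_fst_weir_cockerham(p1, p2, n1, n2, h1, h2)
        want = _wc_anova_oracle(calls_a, calls_b)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-10)

    def test_fixed_difference_near_one(self):
        got = pair_fst_weir_cockerham(1.0, 0.0, 50, 50, 0.0, 0.0)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_negative_values_are_retained(self):
        # identical moderate frequencies with finite samples: theta < 0
        got = pair_fst_weir_cockerham(0.5, 0.5, 10, 10, 0.5, 0.5)
        assert got < 0


class TestGroupFrequencies:
    def _matrix(self, calls, groups):
        calls = np.asarray(calls, dtype=np.int8)
        n, m = calls.shape
        variants = make_variant_table(
            ["1"] * m, range(100, 100 + 100 * m, 100), [f"v{j}" for j in range(m)]
        )
        samples = [f"s{i}" for i in range(n)]
        return (
            GenotypeMatrix(calls, variants, samples),
            SampleGroups(dict(zip(samples, groups))),
        )

    def test_basic_frequencies(self):
        g, s = self._matrix([[0], [2]], ["A", "A"])
        f = group_allele_frequencies(g, s)
        assert f.freq[0, 0] == pytest.approx(0.5)

    def test_fixed_alt(self):
        g, s = self._matrix([[2], [2]], ["A", "A"])
        f = group_allele_frequencies(g, s)
        assert f.freq[0, 0] == pytest.approx(1.0)

    def test_hand_count(self):
        g, s = self._matrix([[1], [2], [0], [1]], ["A"] * 4)
        f = group_allele_frequencies(g, s)
        assert f.freq[0, 0] == pytest.approx(0.5)  # 4 alt alleles of 8

    def test_missing_calls_excluded(self):
        g, s = self._matrix([[2], [-1]], ["A", "A"])
        f = group_allele_frequencies(g, s)
        assert f.freq[0, 0] == pytest.approx(1.0)
        assert f.n_samples[0, 0] == 1

    def test_group_without_samples_raises(self):
        g, s = self._matrix([[1]], ["A"])
        s.group_of["ghost"] = "B"
        with pytest.raises(StructuralError):
            group_allele_frequencies(g, s)


class TestComparisonFst:
    def _freqs(self, freq):
        freq = np.asarray(freq, dtype=float)
        ngrp, m = freq.shape
        n = np.full_like(freq, 10.0)
        return GroupFrequencies(
            [chr(ord("A") + i) for i in range(ngrp)], freq, n, np.zeros_like(freq)
        )

    def test_single_pair_is_identity(self):
        f = self._freqs([[0.2, 0.1], [0.8, 0.1]])
        out = comparison_fst(f, ComparisonSpec("x", (("A", "B"),)))
        np.testing.assert_allclose(
            out, pair_fst_wright_nei([0.2, 0.1], [0.8, 0.1])
        )

    def test_two_pairs_average(self):
        # pair A-B gives 0.36, pair C-D gives 0.0 -> mean 0.18
        f = self._freqs([[0.2], [0.8], [0.4], [0.4]])
        out = comparison_fst(
            f, ComparisonSpec("x", (("A", "B"), ("C", "D")))
        )
        assert out[0] == pytest.approx(0.18)

    def test_nan_pair_excluded(self):
        # A-B monomorphic for the same allele (NaN); C-D gives 0.36
        f = self._freqs([[0.0], [0.0], [0.2], [0.8]])
        out = comparison_fst(
            f, ComparisonSpec("x", (("A", "B"), ("C", "D")))
        )
        assert out[0] == pytest.approx(0.36)

    def test_all_nan_snp_stays_nan(self):
        f = self._freqs([[0.0], [0.0]])
        out = comparison_fst(f, ComparisonSpec("x", (("A", "B"),)))
        assert np.isnan(out[0])

    def test_empty_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            ComparisonSpec("x", ())

    def test_repeated_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            ComparisonSpec("x", (("A", "B"), ("A", "B")))

    def test_estimator_name_validated(self):
        with pytest.raises(ConfigurationError):
            FstEstimatorConfig("nei87")
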