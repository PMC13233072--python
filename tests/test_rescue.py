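"""Binomial isolated-SNP test, correlation rescue, masking and the iterative
per-window caller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import straincall as sc
from straincall import CallerConfig, ErrorModel
from straincall.rescue import MULTILOCUS, OBVIOUS, RESCUED, dedupe_calls
from conftest import make_matrix


class TestBinomialTail:
    def test_zero_count_tail_is_one(self):
        assert sc.binomial_tail_pvalue(0, 30, 0.15) == 1.0

    def test_all_successes_single_term(self):
        assert sc.binomial_tail_pvalue(5, 5, 0.5) == pytest.approx(0.5**5)

    def test_frozen_oracle_values(self):
        # direct summation of C(30,j) 0.15^j 0.85^(30-j), j = k..30
        assert sc.binomial_tail_pvalue(13, 30, 0.15) == pytest.approx(
            1.8570244759319213e-4, rel=1e-10
        )
        assert sc.binomial_tail_pvalue(10, 30, 0.15) == pytest.approx(
            9.657635199554853e-3, rel=1e-10
        )

    def test_domain_violations_raise(self):
        with pytest.raises(ValueError):
            sc.binomial_tail_pvalue(6, 5, 0.1)
        with pytest.raises(ValueError):
            sc.binomial_tail_pvalue(1, 5, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(c=st.integers(1, 120), data=st.data(), s=st.floats(0.01, 0.9))
    def test_agrees_with_exact_rational_summation(self, c, data, s):
        from fractions import Fraction
        from math import comb

        k = data.draw(st.integers(0, c))
        fs = Fraction(s)
        p, q = fs.numerator, fs.denominator
        exact = sum(comb(c, j) * p**j * (q - p) ** (c - j) for j in range(k, c + 1))
        expected = float(Fraction(exact, q**c))
        got = sc.binomial_tail_pvalue(k, c, s)
        assert got == pytest.approx(expected, rel=1e-11, abs=1e-300)


def _config(**kw):
    return CallerConfig(**kw)


def _matrix_with_counts(k, c, ref="A", alt="C"):
    """One column, k alt reads of c total."""
    rows = [alt] * k + [ref] * (c - k)
    m = make_matrix(ref, rows)
    sc.filter_candidate_columns(m, 0.05)
    return m


class TestObviousSnps:
    def test_thirteen_of_thirty_called(self):
        m = _matrix_with_counts(13, 30)
        calls = sc.call_obvious_snps(m, ErrorModel(divergence=0.05))  # s = 0.15
        assert len(calls) == 1
        c = calls[0]
        assert (c.alt_base, c.status, c.support, c.depth) == ("C", OBVIOUS, 13, 30)

    def test_ten_of_thirty_not_called(self):
        m = _matrix_with_counts(10, 30)
        assert sc.call_obvious_snps(m, ErrorModel(divergence=0.05)) == []

    def test_zero_count_never_called(self):
        m = _matrix_with_counts(0, 30)
        assert sc.call_obvious_snps(m, ErrorModel(divergence=0.05)) == []

    def test_residual_reads_extend_coverage(self):
        """Partial reads count toward c and k even though they are not rows."""
        m = _matrix_with_counts(6, 12)
        m.extra_counts[1, 0] = 7  # seven residual reads showing C
        calls = sc.call_obvious_snps(m, ErrorModel(divergence=0.05))
        assert len(calls) == 1
        assert calls[0].support == 13 and calls[0].depth == 19

    def test_alleles_tested_separately(self):
        rows = ["C"] * 13 + ["G"] * 2 + ["A"] * 15
        m = make_matrix("A", rows)
        sc.filter_candidate_columns(m, 0.05)
        calls = sc.call_obvious_snps(m, ErrorModel(divergence=0.05))
        assert [c.alt_base for c in calls] == ["C"]  # G count too low


class TestCorrelatedRescue:
    def _two_column_matrix(self, n_alt, n_ref):
        # col 0: confirmed SNP column; col 1: identical split
        rows = ["CC" + ""] * n_alt + ["AA"] * n_ref
        m = make_matrix("AA", rows)
        sc.filter_candidate_columns(m, 0.05)
        return m

    def test_identical_column_rescued(self):
        m = self._two_column_matrix(30, 30)
        calls = sc.rescue_correlated_loci(m, confirmed_columns=[0])
        assert len(calls) == 1
        c = calls[0]
        assert c.position == 1 and c.alt_base == "C" and c.status == RESCUED
        # chi2 = 60 on a perfect split -> p well below 1e-6
        assert c.log10_p < -6

    def test_independent_column_not_rescued(self):
        rng = np.random.default_rng(1)
        col0 = np.array(["C"] * 30 + ["A"] * 30)
        col1 = rng.permutation(col0)
        rows = [a + b for a, b in zip(col0, col1)]
        m = make_matrix("AA", rows)
        sc.filter_candidate_columns(m, 0.05)
        calls = sc.rescue_correlated_loci(m, confirmed_columns=[0])
        assert all(c.position != 1 for c in calls)

    def test_no_confirmed_columns_no_rescues(self):
        m = self._two_column_matrix(30, 30)
        assert sc.rescue_correlated_loci(m, confirmed_columns=[]) == []


class TestMasking:
    def test_masking_single_alt_clears_column(self):
        m = _matrix_with_counts(5, 20)
        call = sc.VariantCall("c1", 0, "A", "C", 5, 20, OBVIOUS, -5.0)
        sc.mask_called_variants(m, [call])
        assert np.all(m.entries == 1)
        sc.filter_candidate_columns(m, 0.05)
        assert m.m == 0

    def test_masking_is_per_allele(self):
        rows = ["G"] * 6 + ["T"] * 4 + ["A"] * 10
        m = make_matrix("A", rows)
        call = sc.VariantCall("c1", 0, "A", "G", 6, 20, OBVIOUS, -5.0)
        sc.mask_called_variants(m, [call])
        assert int((m.entries[:, 0] == 0).sum()) == 4  # T carriers untouched

    def test_empty_call_list_is_identity(self):
        m = _matrix_with_counts(5, 20)
        before = m.observed.copy()
        sc.mask_called_variants(m, [])
        assert np.array_equal(m.observed, before)


def _planted_matrix(rng, n=30, m=40, carriers=(), cols=(), alt="C", noise=0.0, ref="A"):
    obs = np.full((n, m), 0, dtype=np.uint8)  # ref A everywhere
    if noise:
        err = rng.random((n, m)) < noise
        obs[err] = rng.integers(1, 4, size=int(err.sum()))
    for j in cols:
        for i in carriers:
            obs[i, j] = "ACGT".index(alt)
    mat = make_matrix(ref * m, ["".join("ACGT"[c] for c in row) for row in obs])
    return mat


class TestIterativeCalling:
    def test_all_reference_window_no_calls_one_round(self):
        m = make_matrix("AAAA", ["AAAA"] * 20)
        calls = sc.iterate_calling(m, ErrorModel(divergence=0.02), _config())
        assert calls == []

    def test_biallelic_window_terminates_after_clean_round(self):
        rng = np.random.default_rng(5)
        m = _planted_matrix(rng, carriers=range(12), cols=(3, 9, 20), noise=0.01)
        calls = sc.iterate_calling(m, ErrorModel(divergence=0.02), _config())
        keys = {(c.position, c.alt_base) for c in calls}
        assert {(3, "C"), (9, "C"), (20, "C")} <= keys
        assert all(c.iteration == 1 for c in calls if c.position in (3, 9, 20))

    def test_triallelic_site_called_across_rounds(self):
        """Two alternative alleles at one locus: the second emerges after the
        dominant one is masked."""
        rng = np.random.default_rng(6)
        m = _planted_matrix(rng, n=50, carriers=range(10), cols=(5, 10, 15), alt="G")
        # minor strain (5 reads): T at locus 5, C at locus 20 — too few reads
        # for the binomial path, invisible while G dominates locus 5
        for i in range(10, 15):
            m.observed[i, 5] = 3
            m.observed[i, 20] = 1
        calls = sc.iterate_calling(m, ErrorModel(divergence=0.02), _config())
        at5 = sorted((c.alt_base, c.iteration) for c in calls if c.position == 5)
        assert [a for a, _ in at5] == ["G", "T"]
        assert at5[0][1] < at5[1][1]  # second allele needs a later round
        assert any(c.position == 20 and c.alt_base == "C" for c in calls)

    def test_masking_prevents_duplicate_calls(self):
        rng = np.random.default_rng(7)
        m = _planted_matrix(rng, carriers=range(12), cols=(3, 9, 20), noise=0.01)
        calls = sc.iterate_calling(m, ErrorModel(divergence=0.02), _config())
        keys = [(c.position, c.alt_base) for c in calls]
        assert len(keys) == len(set(keys))

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance_of_calls(self, seed):
        """Shuffling matrix rows and columns leaves the called set unchanged."""
        import copy

        rng = np.random.default_rng(seed)
        m = _planted_matrix(rng, carriers=range(10), cols=(2, 7, 13, 30), noise=0.02)
        perm_rows = rng.permutation(m.n)
        perm_cols = rng.permutation(m.m_all)
        m2 = copy.deepcopy(m)
        m2.observed = m2.observed[perm_rows][:, perm_cols]
        m2.positions = m2.positions[perm_cols]
        m2.ref_codes = m2.ref_codes[perm_cols]
        m2.extra_counts = m2.extra_counts[:, perm_cols]
        m2.read_ids = [m.read_ids[i] for i in perm_rows]
        err = ErrorModel(divergence=0.02)
        base = {
            (c.position, c.alt_base)
            for c in sc.iterate_calling(m, err, _config())
        }
        shuffled = {
            (c.position, c.alt_base)
            for c in sc.iterate_calling(m2, err, _config())
        }
        assert base == shuffled

    def test_status_precedence_on_dedupe(self):
        mk = lambda status, p: sc.VariantCall("c1", 10, "A", "C", 5, 20, status, p)
        calls = [mk(RESCUED, -9.0), mk(MULTILOCUS, -4.0), mk(OBVIOUS, -8.0)]
        out = dedupe_calls(calls)
        assert len(out) == 1 and out[0].status == MULTILOCUS
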