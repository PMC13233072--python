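"""Multi-locus validation of candidate variant groups.

Sequencing errors are (nearly) independent across reads, so correlated
non-reference patterns spanning several reads and several loci are far more
likely to reflect a co-occurring strain than coincidental errors.  Candidate
loci are grouped by pairwise chi-square association, each group's all-error
pattern (a reads x b loci, every cell non-reference) is extracted, and the
pattern is validated with a union bound: among the C(n,a)*C(m,b) possible
a x b submatrices of an n-read x m-locus matrix, the probability that at
least one is entirely sequencing errors is

    p <= s^(ab) * C(n,a) * C(m,b)

with s the (over-estimated) per-base error bound.  The null hypothesis
"errors only" is rejected when p <= alpha (default .001).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import erfc, gammaln

from .windows import BinaryMatrix

LN10 = np.log(10.0)


@dataclass(frozen=True)
class ColumnGroup:
    """Candidate columns whose every intra-pair p-value is <= the cutoff
    (the complete-linkage guarantee)."""

    members: tuple[int, ...]
    cutoff: float


@dataclass
class VariantPattern:
    """An a x b all-non-reference block: the unit the union bound tests."""

    read_indices: tuple[int, ...]
    column_indices: tuple[int, ...]
    n: int
    m: int

    @property
    def a(self) -> int:
        return len(self.read_indices)

    @property
    def b(self) -> int:
        return len(self.column_indices)


@dataclass(frozen=True)
class TestResult:
    log10_bound: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.log10_bound <= log10(self.alpha)


def _chi2_2x2(n11, n10, n01, n00):
    """Pearson chi-square p-value (1 d.f., no continuity correction) for a
    2x2 table; vectorised; degenerate margins give p = 1."""
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n00 = np.asarray(n00, dtype=float)
    total = n11 + n10 + n01 + n00
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, total * (n11 * n00 - n10 * n01) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = erfc(np.sqrt(stat / 2.0))  # chi-square survival at 1 d.f.
    return np.where(denom > 0, p, 1.0)


def chi2_pair_pvalue(
    col_u: np.ndarray,
    col_v: np.ndarray,
    shared_reads: np.ndarray | None = None,
    min_overlap: int = 10,
) -> float:
    """Association p-value between two binary columns over shared reads.

    A permissive symmetric dissimilarity for the grouping step: any zero
    marginal or fewer than ``min_overlap`` shared reads returns 1.0 (the
    final accept/reject decision rests on the union-bound test, not here).
    """
    u = np.asarray(col_u)
    v = np.asarray(col_v)
    if shared_reads is not None:
        idx = np.asarray(shared_reads)
        u, v = u[idx], v[idx]
    if len(u) < min_overlap:
        return 1.0
    n11 = int(np.sum((u == 0) & (v == 0)))
    n10 = int(np.sum((u == 0) & (v == 1)))
    n01 = int(np.sum((u == 1) & (v == 0)))
    n00 = int(np.sum((u == 1) & (v == 1)))
    return float(_chi2_2x2(n11, n10, n01, n00))


def pairwise_pvalues(entries: np.ndarray, min_overlap: int = 10) -> np.ndarray:
    """All-pairs chi-square p-value matrix for a full-coverage binary matrix.

    ``entries`` is n x k with 1 = reference; returns a symmetric k x k array
    with 1.0 on the diagonal.  Vectorised with matrix products, so the cost
    is one k x k gemm rather than k^2 scalar tests.
    """
    X = entries.astype(np.float64)  # 1 = ref
    Z = 1.0 - X  # 1 = alt
    n, k = X.shape
    if k == 0:
        return np.ones((0, 0))
    if n < min_overlap:
        return np.ones((k, k))
    n11 = Z.T @ Z
    n10 = Z.T @ X
    n01 = X.T @ Z
    n00 = X.T @ X
    p = _chi2_2x2(n11, n10, n01, n00)
    np.fill_diagonal(p, 1.0)
    return p


def complete_linkage_groups(pvals: np.ndarray, cutoff: float = 0.05) -> list[ColumnGroup]:
    """Cut a complete-linkage dendrogram over p-value distances at ``cutoff``.

    Complete linkage makes a cluster's height its diameter, so every flat
    cluster satisfies max intra-pair p <= cutoff: all member columns
    mutually correlate.  Groups of size >= 2 are returned (in order of their
    smallest member column); singletons fall through to the isolated-SNP and
    rescue paths.
    """
    k = pvals.shape[0]
    if k < 2:
        return []
    if k == 2:
        if pvals[0, 1] <= cutoff:
            return [ColumnGroup(members=(0, 1), cutoff=cutoff)]
        return []
    condensed = squareform(np.ascontiguousarray(pvals), checks=False)
    tree = linkage(condensed, method="complete")
    labels = fcluster(tree, t=cutoff, criterion="distance")
    groups: dict[int, list[int]] = {}
    for col, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(col)
    out = [
        ColumnGroup(members=tuple(cols), cutoff=cutoff)
        for cols in groups.values()
        if len(cols) >= 2
    ]
    out.sort(key=lambda g: g.members[0])
    return out


def extract_variant_pattern(
    group: ColumnGroup,
    entries: np.ndarray,
    coverage: np.ndarray,
    n: int,
    m: int,
    s: float,
) -> VariantPattern | None:
    """Best all-non-reference submatrix (subset of reads x subset of loci)
    within a correlated column group.

    Requiring every read to be non-reference at *every* group column is
    fragile: a noise column whose few alternative reads happen to be a
    subset of the true carriers correlates strongly enough to join the
    group, yet collapses the full-column intersection to one or zero reads.
    Instead, reads are ranked by how many group columns they are
    non-reference at; for each distinct count threshold t the candidate
    pattern is (reads with count >= t) x (columns where all those reads are
    non-reference), and the threshold minimising the union bound is kept.
    The bound is valid for any a x b all-error submatrix, so this selection
    cannot inflate the test's type-I error; thresholding on counts (never on
    read order) keeps the choice invariant under row/column permutations.

    Returns None when no threshold yields a non-empty pattern (e.g. group
    columns with disjoint read sets); those columns stay eligible for the
    isolated-SNP and rescue paths.
    """
    cols = np.asarray(group.members)
    alt = (entries[:, cols] == 0) & coverage[:, cols]  # (n, b) read is alt
    counts = alt.sum(axis=1)
    best: tuple[float, int] | None = None
    best_pattern: VariantPattern | None = None
    for t in sorted(set(counts[counts > 0]), reverse=True):
        rows = counts >= t
        col_mask = np.all(alt[rows], axis=0)
        b = int(col_mask.sum())
        if b == 0:
            continue
        a = int(rows.sum())
        bound = log10_pattern_bound(n, m, a, b, s)
        if best is None or bound < best[0]:
            best = (bound, int(t))
            best_pattern = VariantPattern(
                read_indices=tuple(int(i) for i in np.flatnonzero(rows)),
                column_indices=tuple(int(c) for c in cols[col_mask]),
                n=n,
                m=m,
            )
    return best_pattern


def log10_binomial_coef(n: int, k: int) -> float:
    """log10 C(n, k) via log-gamma; exact enough for any realistic n."""
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / LN10)


def log10_pattern_bound(n: int, m: int, a: int, b: int, s: float) -> float:
    """log10 of the union bound s^(ab) * C(n,a) * C(m,b).

    Computed in log space so that even astronomically small bounds (or huge
    binomial coefficients) never overflow.
    """
    if not (1 <= a <= n and 1 <= b <= m):
        raise ValueError(f"pattern {a}x{b} does not fit a {n}x{m} matrix")
    if not 0.0 < s < 1.0:
        raise ValueError(f"error bound s={s} outside (0, 1)")
    return a * b * log10(s) + log10_binomial_coef(n, a) + log10_binomial_coef(m, b)


def test_pattern(pattern: VariantPattern, s: float, alpha: float = 1e-3) -> TestResult:
    """Union-bound significance of a pattern; reject errors-only when the
    bound is <= alpha."""
    bound = log10_pattern_bound(pattern.n, pattern.m, pattern.a, pattern.b, s)
    return TestResult(log10_bound=bound, alpha=alpha)
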