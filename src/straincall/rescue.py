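"""Rescue paths and the per-window iterative caller.

Three mechanisms recover SNPs the multi-locus test misses:

* isolated SNPs — no correlated partner loci, so no multi-locus power.  A
  per-position binomial model (coverage c, error bound s) flags "obvious"
  SNPs whose per-allele count is implausible as errors (p < .001);
* high-noise loci — excluded from groups during clustering to protect the
  test's power, but rescued afterwards if they correlate strongly
  (p < 1e-6) with an already-confirmed SNP;
* multi-allelic sites — the dominant alternative allele masks secondary
  ones, so called variants are converted to reference-like status and the
  whole caller re-runs until a round adds nothing new.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10

import numpy as np
from scipy.special import betainc

from . import multilocus as ml
from .windows import BinaryMatrix, ErrorModel, N_CODES, decode_base

MULTILOCUS = "MULTILOCUS"
OBVIOUS = "OBVIOUS"
RESCUED = "RESCUED"
_STATUS_RANK = {MULTILOCUS: 0, OBVIOUS: 1, RESCUED: 2}


@dataclass(frozen=True)
class IsolatedCandidate:
    """A single-position alternative allele scored under Binomial(c, s)."""

    position: int
    allele: str
    k: int
    c: int
    p: float


@dataclass(frozen=True)
class VariantCall:
    """A called SNP.  ``position`` is 0-based internally; VCF emission
    shifts to 1-based.  ``alt_base`` may be '-' (deletion observed in the
    matrix) — such calls are kept for masking but never written to VCF."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    support: int
    depth: int
    status: str
    log10_p: float
    iteration: int = 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.alt_base)


def binomial_tail_pvalue(k: int, c: int, s: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(c, s).

    Evaluated through the regularised incomplete beta function
    P(X >= k) = I_s(k, c - k + 1), the exact survival function of the
    binomial (equivalent to direct pmf summation).
    """
    if not (0 <= k <= c):
        raise ValueError(f"k={k} outside [0, c={c}]")
    if not 0.0 < s < 1.0:
        raise ValueError(f"s={s} outside (0, 1)")
    if k == 0:
        return 1.0
    return float(betainc(k, c - k + 1, s))


def call_obvious_snps(
    matrix: BinaryMatrix,
    error: ErrorModel,
    alpha: float = 1e-3,
    already_called: set[tuple[int, str]] | None = None,
    iteration: int = 1,
) -> list[VariantCall]:
    """Binomial test per candidate column and alternative allele.

    Coverage c counts matrix rows plus residual partial reads; k is the
    per-allele count (alleles are tested separately — pooling would conflate
    multi-allelic noise).  Strict p < alpha, per the obvious-SNP rule.
    """
    already = already_called or set()
    cand = np.flatnonzero(matrix.candidate_mask)
    if cand.size == 0:
        return []
    counts = matrix.total_base_counts()[:, cand]  # (codes, n_cand)
    depth = counts.sum(axis=0)
    refc = matrix.ref_codes[cand]
    is_alt = np.arange(N_CODES)[:, None] != refc[None, :]
    k = np.where(is_alt, counts, 0)
    # exact binomial upper tail, vectorised over (allele, column)
    with np.errstate(invalid="ignore"):
        p = np.where(
            (k > 0) & (depth > 0), betainc(np.maximum(k, 1), depth - k + 1, error.s), 1.0
        )
    calls: list[VariantCall] = []
    for code, jc in zip(*np.nonzero(p < alpha)):
        j = int(cand[jc])
        alt = decode_base(int(code))
        pos = int(matrix.positions[j])
        if (pos, alt) in already:
            continue
        pv = float(p[code, jc])
        calls.append(
            VariantCall(
                contig=matrix.window.contig,
                position=pos,
                ref_base=decode_base(int(refc[jc])),
                alt_base=alt,
                support=int(k[code, jc]),
                depth=int(depth[jc]),
                status=OBVIOUS,
                log10_p=log10(pv) if pv > 0 else -320.0,
                iteration=iteration,
            )
        )
    return calls


def rescue_correlated_loci(
    matrix: BinaryMatrix,
    confirmed_columns: list[int],
    threshold: float = 1e-6,
    min_overlap: int = 10,
    already_called: set[tuple[int, str]] | None = None,
    iteration: int = 1,
) -> list[VariantCall]:
    """Rescue loci strongly correlated with confirmed SNP columns.

    Every not-yet-called pileup column (candidates or not: high-noise loci
    usually fail the 5% filter or the clustering) is chi-square-tested
    against each confirmed column; min p strictly below ``threshold``
    rescues it.  The reported allele is the majority alternative base among
    reads that are non-reference at the best-correlated confirmed column.
    """
    if not confirmed_columns:
        return []
    already = already_called or set()
    entries = matrix.entries
    cov = matrix.coverage_rows
    conf = np.asarray(sorted(confirmed_columns))
    Xc = entries[:, conf].astype(np.float64)
    Zc = 1.0 - Xc
    X = entries.astype(np.float64)
    Z = 1.0 - X
    if matrix.n < min_overlap:
        return []
    # all columns vs confirmed columns, vectorised 2x2 chi-square
    n11 = Z.T @ Zc
    n10 = Z.T @ Xc
    n01 = X.T @ Zc
    n00 = X.T @ Xc
    p = ml._chi2_2x2(n11, n10, n01, n00)  # (m_all, n_conf)
    p[conf, :] = 1.0  # a confirmed column cannot rescue itself
    best = p.argmin(axis=1)
    pmin = p[np.arange(p.shape[0]), best]
    depth = matrix.column_depth()
    calls: list[VariantCall] = []
    for j in np.flatnonzero(pmin < threshold):
        ref_code = int(matrix.ref_codes[j])
        partner = int(conf[best[j]])
        # reads sharing the partner's alternative state
        carriers = np.flatnonzero((entries[:, partner] == 0) & cov[:, partner] & cov[:, j])
        if carriers.size == 0:
            continue
        obs = matrix.observed[carriers, j]
        alt_counts = np.array(
            [(obs == code).sum() if code != ref_code else 0 for code in range(N_CODES)]
        )
        if alt_counts.sum() == 0:
            continue
        code = int(alt_counts.argmax())  # argmax ties -> alphabetical (lowest code)
        alt = decode_base(code)
        pos = int(matrix.positions[j])
        if (pos, alt) in already:
            continue
        pj = float(pmin[j])
        calls.append(
            VariantCall(
                contig=matrix.window.contig,
                position=pos,
                ref_base=decode_base(ref_code),
                alt_base=alt,
                support=int((matrix.observed[:, j] == code).sum()) + int(matrix.extra_counts[code, j]),
                depth=int(depth[j]),
                status=RESCUED,
                log10_p=log10(pj) if pj > 0 else -320.0,
                iteration=iteration,
            )
        )
    return calls


def mask_called_variants(matrix: BinaryMatrix, calls: list[VariantCall]) -> BinaryMatrix:
    """Convert called alleles to reference-like status, in place.

    Only cells showing the called alternative base are touched (other
    alternative alleles at the column stay visible for the next round);
    residual-read counts for that allele are cleared likewise.
    """
    pos_index = {int(p): j for j, p in enumerate(matrix.positions)}
    for call in calls:
        j = pos_index.get(call.position)
        if j is None:
            continue
        code = np.uint8("ACGT-".index(call.alt_base))
        col = matrix.observed[:, j]
        col[col == code] = matrix.ref_codes[j]
        matrix.extra_counts[matrix.ref_codes[j], j] += matrix.extra_counts[int(code), j]
        matrix.extra_counts[int(code), j] = 0
    return matrix


def _multilocus_calls(
    matrix: BinaryMatrix,
    error: ErrorModel,
    config,
    already: set[tuple[int, str]],
    iteration: int,
) -> list[VariantCall]:
    """One pass of the grouped multi-locus test over candidate columns."""
    cand = np.flatnonzero(matrix.candidate_mask)
    if cand.size < 2:
        return []
    entries = matrix.entries
    cov = matrix.coverage_rows
    pvals = ml.pairwise_pvalues(entries[:, cand], min_overlap=config.min_pair_overlap)
    groups = ml.complete_linkage_groups(pvals, cutoff=config.pair_pvalue_cutoff)
    depth = matrix.column_depth()
    calls: list[VariantCall] = []
    for group in groups:
        full_cols = tuple(int(cand[i]) for i in group.members)
        pattern = ml.extract_variant_pattern(
            ml.ColumnGroup(members=full_cols, cutoff=group.cutoff),
            entries,
            cov,
            n=matrix.n,
            m=int(cand.size),
            s=error.s,
        )
        if pattern is None:
            continue
        result = ml.test_pattern(pattern, s=error.s, alpha=config.alpha)
        if not result.significant:
            continue
        rows = np.asarray(pattern.read_indices)
        for j in pattern.column_indices:
            ref_code = int(matrix.ref_codes[j])
            obs = matrix.observed[rows, j]
            alt_counts = np.array(
                [(obs == code).sum() if code != ref_code else 0 for code in range(N_CODES)]
            )
            if alt_counts.sum() == 0:
                continue
            code = int(alt_counts.argmax())
            alt = decode_base(code)
            pos = int(matrix.positions[j])
            if (pos, alt) in already:
                continue
            calls.append(
                VariantCall(
                    contig=matrix.window.contig,
                    position=pos,
                    ref_base=decode_base(ref_code),
                    alt_base=alt,
                    support=pattern.a,
                    depth=int(depth[j]),
                    status=MULTILOCUS,
                    log10_p=result.log10_bound,
                    iteration=iteration,
                )
            )
    return calls


def dedupe_calls(calls: list[VariantCall]) -> list[VariantCall]:
    """One call per (contig, position, alt): strongest status wins
    (MULTILOCUS > OBVIOUS > RESCUED), then smallest log10_p."""
    best: dict[tuple[str, int, str], VariantCall] = {}
    for call in calls:
        cur = best.get(call.key)
        if cur is None or (_STATUS_RANK[call.status], call.log10_p) < (
            _STATUS_RANK[cur.status],
            cur.log10_p,
        ):
            best[call.key] = call
    return sorted(best.values(), key=lambda c: (c.contig, c.position, c.alt_base))


def iterate_calling(matrix: BinaryMatrix, error: ErrorModel, config) -> list[VariantCall]:
    """Full per-window pipeline with iterative masking.

    Each round: refresh the candidate filter, group and test patterns, add
    obvious SNPs, rescue correlated loci, then mask everything newly called
    and repeat.  Masking strictly reduces the number of non-reference cells,
    so the loop terminates; ``config.max_rounds`` caps it regardless.
    """
    from .windows import filter_candidate_columns  # cycle-free local import

    if matrix.n == 0 or matrix.m_all == 0:
        return []
    all_calls: list[VariantCall] = []
    called: set[tuple[int, str]] = set()
    pos_index = {int(p): j for j, p in enumerate(matrix.positions)}
    for round_no in range(1, config.max_rounds + 1):
        filter_candidate_columns(matrix, config.min_alt_frac)
        new_calls = _multilocus_calls(matrix, error, config, called, round_no)
        called_round = called | {(c.position, c.alt_base) for c in new_calls}
        new_calls += call_obvious_snps(
            matrix, error, alpha=config.alpha, already_called=called_round, iteration=round_no
        )
        called_round |= {(c.position, c.alt_base) for c in new_calls}
        # Recovery tests correlation against variants in the state they were
        # confirmed: only this round's columns, before masking.  A previously
        # masked column retains nothing but stray error reads, and a 2x2
        # chi-square against a near-empty column degenerates into spurious
        # "perfect" correlation.
        confirmed_cols = sorted(
            {pos_index[c.position] for c in new_calls if c.position in pos_index}
        )
        new_calls += rescue_correlated_loci(
            matrix,
            confirmed_cols,
            threshold=config.rescue_pvalue,
            min_overlap=config.min_pair_overlap,
            already_called=called_round,
            iteration=round_no,
        )
        new_calls = [c for c in new_calls if (c.position, c.alt_base) not in called]
        if not new_calls:
            break
        all_calls.extend(new_calls)
        called |= {(c.position, c.alt_base) for c in new_calls}
        mask_called_variants(matrix, new_calls)
    return dedupe_calls(all_calls)
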