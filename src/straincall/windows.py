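"""Windowed pileup construction: reads -> per-window binary matrices.

Alignments are converted, window by window, into a read x locus matrix of
reference / non-reference observations.  Rows are restricted to reads that
span the whole window so that every locus in a window is covered by the same
read set, which is what the multi-locus test downstream requires.  Partial
reads are either grouped into coordinate clusters (>= 5 reads with identical
mapping coordinates, analysed as their own matrices) or kept aside as
residual reads that still contribute to per-column coverage.

Coordinates are 0-based half-open throughout; VCF emission shifts to 1-based.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

# Base encoding shared across the package.  Deletions are a fifth "allele"
# for matrix purposes (a non-reference observation) but are never emitted in
# the VCF, which reports SNPs only.  Insertions are ignored entirely.
A, C, G, T, DEL = 0, 1, 2, 3, 4
NONE = 255  # position not covered by the read
BASES = "ACGT-"
N_CODES = 5

_ENCODE = np.full(256, NONE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("-")] = DEL


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string to uint8 codes (A=0..T=3, '-'=4, other=NONE)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_base(code: int) -> str:
    return BASES[code]


class NoReadsError(ValueError):
    """Raised when an operation needs reads but none are usable."""


@dataclass(frozen=True)
class WindowSpec:
    """A fixed-length tile of the reference.

    Windows on one contig are non-overlapping and tile it in order; only the
    terminal window of a contig may be shorter than the configured length.
    """

    contig: str
    start: int
    end: int
    index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentView:
    """One read's alignment, reduced to what the caller needs.

    ``bases`` holds the observed base code at every reference position in
    ``[start, end)``: A/C/G/T codes for aligned query bases, ``DEL`` where
    the read has a deletion (deletions count as coverage), ``NONE`` where
    the alignment skips the reference.  Exactly one view per read survives
    best-alignment selection.
    """

    read_id: str
    contig: str
    start: int
    end: int
    bases: np.ndarray
    alignment_score: float = 0.0
    mismatch_count: int = 0
    aligned_length: int = 0

    def window_slice(self, lo: int, hi: int) -> np.ndarray:
        """Observed codes over [lo, hi); NONE outside the alignment span."""
        lo_c, hi_c = max(lo, self.start), min(hi, self.end)
        if lo_c >= hi_c:
            return np.full(hi - lo, NONE, dtype=np.uint8)
        out = np.full(hi - lo, NONE, dtype=np.uint8)
        out[lo_c - lo : hi_c - lo] = self.bases[lo_c - self.start : hi_c - self.start]
        return out

    def covers(self, lo: int, hi: int) -> bool:
        """True if every reference position in [lo, hi) is aligned (deletions
        count as coverage, reference skips do not)."""
        if self.start > lo or self.end < hi:
            return False
        seg = self.bases[lo - self.start : hi - self.start]
        return not np.any(seg == NONE)


@dataclass
class ErrorModel:
    """Inflated per-base error bound.

    ``divergence`` is the fraction of aligned read bases disagreeing with the
    reference in the window; ``s = clamp(multiplier * divergence, floor, cap)``
    deliberately over-estimates the local error rate so the union-bound test
    stays conservative in error-prone regions.
    """

    divergence: float
    multiplier: float = 3.0
    floor: float = 0.01
    cap: float = 0.95
    s: float = field(init=False)

    def __post_init__(self) -> None:
        self.s = min(max(self.multiplier * self.divergence, self.floor), self.cap)


@dataclass
class ReadClusterSet:
    """Reads grouped by exact (start, end) mapping coordinates.

    Groups of at least ``min_size`` reads become clusters (each analysed as
    its own matrix over its common span — such reads plausibly come from one
    strain with a structural difference to the reference); everything else is
    residual.  Residual reads are excluded from multi-locus analysis but still
    count toward per-column coverage for the binomial test.
    """

    clusters: list[list[str]]
    coordinates: list[tuple[int, int]]
    residual: list[str]
    min_size: int = 5


@dataclass
class BinaryMatrix:
    """Per-window read x locus matrix.

    ``observed[i, j]`` is the base code read ``i`` shows at ``positions[j]``;
    the binary entry M_ij = 1 iff it equals ``ref_codes[j]``.  ``extra_counts``
    accumulates per-column base counts from overlapping reads that are not
    rows (residual / partial reads): they contribute to coverage ``c`` and to
    per-allele counts of the binomial test, never to the multi-locus matrix.
    """

    window: WindowSpec
    read_ids: list[str]
    positions: np.ndarray  # (m_all,) reference positions
    ref_codes: np.ndarray  # (m_all,) uint8
    observed: np.ndarray  # (n, m_all) uint8
    extra_counts: np.ndarray  # (N_CODES, m_all) int64
    candidate_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.candidate_mask is None:
            self.candidate_mask = np.zeros(self.m_all, dtype=bool)

    @property
    def n(self) -> int:
        return self.observed.shape[0]

    @property
    def m_all(self) -> int:
        return len(self.positions)

    @property
    def m(self) -> int:
        return int(self.candidate_mask.sum())

    @property
    def entries(self) -> np.ndarray:
        """Binary matrix: 1 = reference allele, 0 = alternative; rows not
        covering a column (never the case for spanning reads) are 0-depth."""
        return (self.observed == self.ref_codes[None, :]).astype(np.int8)

    @property
    def coverage_rows(self) -> np.ndarray:
        """(n, m_all) bool — row covers column (deletion counts)."""
        return self.observed != NONE

    def column_base_counts(self) -> np.ndarray:
        """(N_CODES, m_all) counts of observed bases among matrix rows."""
        counts = np.zeros((N_CODES, self.m_all), dtype=np.int64)
        for code in range(N_CODES):
            counts[code] = (self.observed == code).sum(axis=0)
        return counts

    def total_base_counts(self) -> np.ndarray:
        """Row counts plus residual-read counts (for coverage/binomial)."""
        return self.column_base_counts() + self.extra_counts

    def column_depth(self) -> np.ndarray:
        """Coverage c per column, matrix rows plus residual reads."""
        return self.total_base_counts().sum(axis=0)


def compute_window_length(read_lengths: list[int], min_window_length: int = 500) -> int:
    """Window length = floor(median read length / 2), floored at a minimum.

    Half the median read length balances windows long enough to contain
    several loci against keeping enough full-window-spanning reads.  Even
    counts use the mean of the two middle values.
    """
    if not read_lengths:
        raise NoReadsError("cannot size windows: no usable reads")
    med = statistics.median(read_lengths)
    return max(int(med // 2), min_window_length)


def select_best_alignments(alignments: list[AlignmentView]) -> list[AlignmentView]:
    """Keep exactly one alignment per read: highest score, ties broken by
    lexicographically smallest (contig, start)."""
    best: dict[str, AlignmentView] = {}
    for aln in alignments:
        cur = best.get(aln.read_id)
        if cur is None:
            best[aln.read_id] = aln
            continue
        if (-aln.alignment_score, aln.contig, aln.start) < (
            -cur.alignment_score,
            cur.contig,
            cur.start,
        ):
            best[aln.read_id] = aln
    # preserve first-seen read order for determinism
    seen: list[AlignmentView] = []
    emitted: set[str] = set()
    for aln in alignments:
        if aln.read_id not in emitted:
            seen.append(best[aln.read_id])
            emitted.add(aln.read_id)
    return seen


def build_binary_matrix(
    window: WindowSpec,
    alignments: list[AlignmentView],
    ref_codes: np.ndarray,
    extra_alignments: list[AlignmentView] = (),
) -> BinaryMatrix:
    """Build the window matrix from full-window-spanning reads.

    ``ref_codes`` are the reference base codes over ``[window.start,
    window.end)``.  Reads in ``alignments`` that do not span the window are
    ignored; ``extra_alignments`` contribute only to per-column auxiliary
    counts (coverage for the binomial test).  Zero spanning reads give a
    valid empty matrix which downstream stages skip.
    """
    lo, hi = window.start, window.end
    rows = [a for a in alignments if a.covers(lo, hi)]
    positions = np.arange(lo, hi, dtype=np.int64)
    valid = ref_codes < 4  # drop ambiguous reference bases (N)
    positions = positions[valid]
    refc = ref_codes[valid]
    observed = np.empty((len(rows), len(positions)), dtype=np.uint8)
    for i, aln in enumerate(rows):
        observed[i] = aln.window_slice(lo, hi)[valid]
    extra = np.zeros((N_CODES, len(positions)), dtype=np.int64)
    for aln in extra_alignments:
        sl = aln.window_slice(lo, hi)[valid]
        for code in range(N_CODES):
            extra[code] += sl == code
    return BinaryMatrix(
        window=window,
        read_ids=[a.read_id for a in rows],
        positions=positions,
        ref_codes=refc,
        observed=observed,
        extra_counts=extra,
    )


def error_model_from_counts(
    nonref_bases: int,
    aligned_bases: int,
    multiplier: float = 3.0,
    floor: float = 0.01,
    cap: float = 0.95,
) -> ErrorModel:
    """Error bound from raw counts: divergence = nonref / aligned, s = 3x."""
    if aligned_bases <= 0:
        raise NoReadsError("cannot estimate divergence: zero aligned bases")
    return ErrorModel(
        divergence=nonref_bases / aligned_bases,
        multiplier=multiplier,
        floor=floor,
        cap=cap,
    )


def estimate_error_rate(
    window_alignments: list[AlignmentView],
    window: WindowSpec,
    ref_codes: np.ndarray,
    multiplier: float = 3.0,
    floor: float = 0.01,
    cap: float = 0.95,
) -> ErrorModel:
    """Per-window divergence of reads vs reference, inflated threefold.

    Divergence is measured locally (per window, over every aligned base of
    every overlapping read, partial reads included) so that s tracks local
    error-prone context rather than a genome-wide average.
    """
    lo, hi = window.start, window.end
    aligned = 0
    nonref = 0
    for aln in window_alignments:
        sl = aln.window_slice(lo, hi)
        cov = sl != NONE
        aligned += int(cov.sum())
        nonref += int((cov & (sl != ref_codes)).sum())
    return error_model_from_counts(nonref, aligned, multiplier, floor, cap)


def filter_candidate_columns(matrix: BinaryMatrix, min_alt_frac: float = 0.05) -> BinaryMatrix:
    """Mark candidate loci: alternative alleles in strictly more than
    ``min_alt_frac`` of the matrix reads covering the column.

    Filtering shrinks m, which both speeds up the pairwise correlations and
    strengthens the union bound.  Updates ``candidate_mask`` in place and
    returns the matrix.
    """
    cov = matrix.coverage_rows.sum(axis=0)
    alt = ((matrix.observed != NONE) & (matrix.observed != matrix.ref_codes[None, :])).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov > 0, alt / np.maximum(cov, 1), 0.0)
    matrix.candidate_mask = frac > min_alt_frac
    return matrix


def cluster_reads_by_coordinates(
    window: WindowSpec,
    alignments: list[AlignmentView],
    min_size: int = 5,
) -> ReadClusterSet:
    """Group reads sharing exactly the same (start, end) mapping coordinates.

    Reads clipped to identical sub-intervals of the reference plausibly come
    from one strain whose genome structurally differs from the reference, so
    each qualifying group (>= min_size) is analysed as its own matrix.
    """
    by_coord: dict[tuple[int, int], list[str]] = {}
    for aln in alignments:
        by_coord.setdefault((aln.start, aln.end), []).append(aln.read_id)
    clusters: list[list[str]] = []
    coords: list[tuple[int, int]] = []
    residual: list[str] = []
    for key in sorted(by_coord):
        ids = by_coord[key]
        if len(ids) >= min_size:
            clusters.append(ids)
            coords.append(key)
        else:
            residual.extend(ids)
    return ReadClusterSet(clusters=clusters, coordinates=coords, residual=residual, min_size=min_size)
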