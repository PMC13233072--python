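# Methods

## Model and assumptions

`straincall` detects single-nucleotide variants in long-read alignments to a
metagenomic reference (typically a MAG or collapsed assembly). Its single
statistical assumption is that sequencing errors arise independently across
reads. No assumption is made about the number of haplotypes present, their
relative abundances, or their evolutionary relationship — which is what
breaks ploidy-based callers on metagenomes.

### Windowed binary matrices

The reference is tiled into fixed, non-overlapping windows of half the
median read length (floored at 500 bp). Halving the median balances two
pressures: windows must contain enough loci for multi-locus evidence, yet
enough reads must span a whole window, because the test requires all loci of
a group to be covered by the same read set. Only the best alignment per read
is kept (highest alignment score; ties broken by lexicographically smallest
(contig, start)), and secondary/supplementary records are dropped first.

Reads spanning the whole window form the rows of a binary matrix: entry 1
when the read shows the reference base, 0 for any alternative base or a
deletion. Deletions are treated as a fifth allele for matrix purposes —
they are real non-reference observations and carry correlation signal — but
are never emitted, as the caller reports SNPs only; insertions are ignored.
Reads that do not span the window are either grouped by exact mapping
coordinates (≥ 5 reads sharing an identical (start, end) — plausibly one
strain with a structural difference — analysed as an independent matrix over
their common span) or kept as residual reads that contribute to per-column
coverage only.

### The error bound s

The per-base error bound is estimated per window as

    s = clamp(3 × divergence, 0.01, 0.95)

where divergence is the fraction of aligned bases (partial reads included)
disagreeing with the reference. Estimating locally rather than genome-wide
lets s track error-prone contexts (e.g. homopolymer-rich windows); the
threefold inflation keeps s above the true local error rate, which makes
every downstream test conservative. The floor avoids a degenerate s = 0 on
error-free simulated data; the cap keeps s a valid probability. Note that
in windows containing true variants the divergence — and hence s — is
inflated further by the variants themselves, which again only makes the
test more conservative.

### Candidate loci and grouping

Only columns where alternative alleles appear in strictly more than 5% of
the covering matrix reads enter the multi-locus stage. This reduces m (the
locus dimension of the union bound) and the quadratic pairwise work.
Pairwise association between candidate columns is the Pearson chi-square
p-value (1 d.f., no continuity correction) of the 2×2 reference/alternative
table; tables with a zero marginal, or matrices with fewer than 10 shared
reads, get p = 1. These p-values are deliberately permissive: they only
steer grouping, the accept/reject decision rests entirely on the union
bound. Complete-linkage hierarchical clustering over p-value distances, cut
at p ≤ .05, groups the columns; complete linkage makes a cluster's height
its diameter, so every intra-group pair is guaranteed to meet the cutoff.

### Pattern extraction

Within a group the variant pattern is an all-non-reference submatrix:
a reads × b loci. Requiring the pattern's reads to be non-reference at
*every* group column proved fragile: a noise column whose few alternative
reads happen to be a subset of the true carriers correlates well enough to
join the group, yet collapses the full intersection to one or zero reads.
Extraction therefore selects a subset of loci as well as reads: reads are
ranked by the number of group columns at which they are non-reference, and
for each distinct count threshold t the candidate pattern is (reads with
count ≥ t) × (columns where all those reads are non-reference); the
threshold minimising the union bound is kept. Thresholding on counts, never
on read order, keeps the choice invariant under row/column permutations.
Because the union bound is a valid bound for the existence of *any* a×b
all-error submatrix, optimising the selection cannot inflate the type-I
error — a claim the null-data experiment verifies empirically.

### The union-bound test

For a pattern of a reads × b loci in an n × m matrix (m = candidate columns
after the 5% filter), the probability that some a×b all-error submatrix
exists under independent errors at rate ≤ s is bounded by

    p ≤ s^(ab) · C(n,a) · C(m,b)

The null hypothesis is rejected when p ≤ .001, and each of the pattern's
loci becomes a MULTILOCUS call; the reported allele is the majority observed
base among the pattern's reads (ties alphabetical). The bound is computed in
log10 space via log-gamma, so no configuration overflows. For the reference
configuration (n=100, m=500, a=5, b=10, s=0.15) exact arbitrary-precision
evaluation gives 1.1800×10⁻¹³ (log₁₀ = −12.9281); the test suite pins the
implementation to that oracle at 10⁻⁹ relative in log space.

### Rescue paths

* **Isolated SNPs.** Without correlated partners the multi-locus test has
  little power at a single locus. Each candidate column's alternative
  alleles are therefore tested per allele against Binomial(c, s), where c is
  the coverage (matrix rows plus residual partial reads); an upper-tail
  p < .001 yields an OBVIOUS call. Alleles are tested separately rather than
  pooled, since the null models one allele's recurrence and pooling would
  conflate multi-allelic noise. The tail is evaluated through the
  regularised incomplete beta function — the exact binomial survival
  function (verified to 10⁻¹² against integer-rational direct summation for
  all coverages up to 200).
* **High-noise loci.** Loci excluded from groups (often because local noise
  weakened their pairwise p-values or they failed the 5% filter) are tested
  by chi-square against every column confirmed in the current round; a
  minimum p strictly below 10⁻⁶ rescues the locus (RESCUED). The reported
  allele is the majority alternative base among reads sharing the partner
  column's alternative state. Rescue uses the confirmed columns in the state
  they were confirmed — before masking — because a masked column retains
  only stray error reads and a 2×2 chi-square against a near-empty column
  degenerates into spurious "perfect" correlation.
* **Multi-allelic sites.** All calls of a round are masked (cells showing
  the called alternative base become reference-like; other alternative
  bases at the column are untouched) and the whole per-window pipeline
  re-runs. Masking strictly decreases the number of non-reference cells, so
  iteration terminates; a default cap of 5 rounds reflects that only a
  handful of alternative alleles can exist per site. Calls are deduplicated
  by (position, alt) with status precedence MULTILOCUS > OBVIOUS > RESCUED.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | auto | half the median read length, min 500 bp |
| `min_alt_frac` | 0.05 | candidate filter, strict "greater than" |
| `pair_pvalue_cutoff` | 0.05 | complete-linkage grouping cutoff |
| `alpha` | 0.001 | union-bound (≤) and binomial (<) rejection level |
| `rescue_pvalue` | 10⁻⁶ | correlation rescue threshold, strict "<" |
| `error_multiplier` | 3 | divergence → s inflation |
| `s_floor`, `s_cap` | 0.01, 0.95 | clamp on s |
| `min_cluster_size` | 5 | reads with identical coordinates forming a cluster |
| `min_pair_overlap` | 10 | shared reads below which chi-square returns 1 |
| `max_rounds` | 5 | masking/re-calling iterations per window |

The inequality directions (≤ for the union bound, strict < for the binomial
and rescue thresholds, strict > for the candidate filter) follow the rule
statements exactly.

## Simulator

The generator emulates a strain community: a random ancestor sequence, k
haplotypes created by independent per-base substitutions at the configured
divergence (uniform over the three other bases), strain 0 designated the
reference, fixed-length reads placed uniformly per strain at the configured
coverages, and i.i.d. per-base substitution errors. Reads are emitted
pre-aligned at their true coordinates (pure-match CIGAR, NM tags set), which
makes the alignment exact by construction and isolates the calling
statistics from aligner behaviour. An optional partial-read mode emits
groups of ≥ 5 identically clipped reads to exercise coordinate clustering.

What it deliberately does not model: indels, homopolymer-dependent error
profiles, chimeric reads, base qualities, or structural variation. Passing
tests on this generator therefore demonstrate the statistical machinery
under the stated independence assumption, not robustness to real nanopore
artefact structure — on real data, alignment noise around homopolymers and
indels is absorbed only insofar as the threefold s inflation covers it.
Defaults are a 4,000 bp read length (giving 2 kb windows under the
half-median rule), 1% divergence between strains and 20× per-strain
coverage; the two benchmark mixtures use 5% (balanced two-strain case) and
1% (four-strain uneven case) read error, the latter matching
recent-chemistry nanopore accuracy.

## Benchmark experiments and problem sizes

`straincall.experiments` fixes three study conditions, used by the test
suite and `scripts/acceptance.py`:

* **Null type-I**: one reference strain, 50×, 3% error (s = 0.09), 1,000
  windows of 2 kb; reports the fraction of windows emitting any call.
* **Balanced mixture**: 2 strains, 1% divergence, 20× each, 5% error,
  100 kb contig; recall/precision against truth.
* **Uneven mixture**: 4 strains at 20×/20×/20×/5×, 1% divergence, 1% error,
  100 kb contig; overall metrics plus recall restricted to the 5× strain's
  private SNPs.

These sizes give stable rates (≈ 2,000–4,000 truth variants; Monte-Carlo
error on rates well under a percentage point) while keeping each experiment
within minutes on a single CPU.

## Numerical and degenerate-input choices

* Chi-square p-values use the closed-form 2×2 statistic and the 1-d.f.
  survival function `erfc(√(x/2))`; all-pairs matrices are computed with
  matrix products rather than per-pair loops.
* Empty matrices (no spanning reads — e.g. the first and last window of a
  contig, which no read can span entirely) yield no calls; their positions
  remain callable only through windows that reads do span. This is the main
  recall loss on short contigs.
* Reference positions with ambiguous bases (N) are dropped from matrices.
* Agglomerative merges use scipy's deterministic complete-linkage
  implementation; observation order is column order, so grouping is
  reproducible byte-for-byte.
* Windows are independent work units; with `thread_count > 1` they are
  mapped over a thread pool and merged in genomic order, so the VCF is
  identical for any thread count.
* VCF output is site-only v4.2, 1-based positions, co-located alternative
  alleles merged into one record (alphabetical ALT order) with per-allele
  INFO fields DP/SR/LP/ST/IT; deletion "alleles" used internally for
  masking are never written.

## Known limitations

* No indel calling, genotype likelihoods, phasing or strain-count
  estimation.
* Contig-terminal windows cannot be analysed (no spanning reads).
* The binomial and union-bound tests share the inflated s; when local noise
  exceeds three times the window average (long homopolymers), both lose
  power and the rescue path is the only recovery mechanism.
* The chi-square association p-values are asymptotic and anti-conservative
  for sparse 2×2 tables; they are used only as a grouping distance and for
  the 10⁻⁶ rescue rule, where the required statistic exceeds the matrix
  row count unless correlation is near-perfect.
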