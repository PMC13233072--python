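"""Multi-strain long-read simulator with ground truth.

Generates k closely related strain haplotypes from a common ancestor (i.i.d.
per-base substitutions at a configurable divergence), samples substitution-
only reads per strain at configurable, possibly uneven, coverages, corrupts
them with i.i.d. per-base errors, and writes the result as a reference FASTA
plus a coordinate-sorted, indexed BAM with reads placed at their true
coordinates.  Strain 0 is the reference; the truth set lists every position
where another strain differs from it.

Substitution-only reads make the alignment exact by construction, which
isolates the calling statistics from aligner behaviour; an optional
partial-read mode emits groups of reads clipped to identical sub-intervals
to exercise coordinate clustering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .rescue import VariantCall
from .windows import BASES

_BASES4 = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class StrainConfig:
    """Study conditions for one simulated community.

    ``divergence`` is the per-base substitution probability applied
    independently to each strain's copy of the ancestor; ``coverages`` gives
    each strain's mean depth (uneven mixtures are the interesting case);
    ``error_rate`` is the per-base i.i.d. read error.  Everything is
    deterministic for a fixed ``seed``.
    """

    strain_count: int = 2
    divergence: float = 0.01
    coverages: tuple[float, ...] = (20.0, 20.0)
    read_length: int = 4000
    error_rate: float = 0.05
    seed: int = 0
    contig_name: str = "contig_1"
    partial_clusters: int = 0  # groups of >=5 identically clipped reads

    def __post_init__(self) -> None:
        if len(self.coverages) != self.strain_count:
            raise ValueError("one coverage per strain required")
        for r in (self.divergence, self.error_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if any(c <= 0 for c in self.coverages):
            raise ValueError("coverages must be positive")


@dataclass
class SimTruth:
    """Simulated haplotypes plus the ground-truth variant set."""

    reference: np.ndarray  # uint8 codes, strain 0
    haplotypes: list[np.ndarray]
    variants: list[tuple[int, str, str, tuple[int, ...]]]  # (pos, ref, alt, carrier strains)
    config: StrainConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def reference_seq(self) -> str:
        return "".join(BASES[c] for c in self.reference)

    @property
    def variant_keys(self) -> set[tuple[int, str]]:
        return {(pos, alt) for pos, _ref, alt, _who in self.variants}


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a uniformly chosen
    different base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        # shift by 1..3 within the 4-letter alphabet: uniform over other bases
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def simulate_haplotypes(ancestor_length: int, config: StrainConfig) -> SimTruth:
    """Random ancestor, k independently mutated strains, truth by comparison."""
    if ancestor_length < 1:
        raise ValueError("ancestor_length must be >= 1")
    rng = np.random.default_rng(config.seed)
    ancestor = rng.integers(0, 4, size=ancestor_length, dtype=np.uint8)
    haplotypes = [_mutate(ancestor, config.divergence, rng) for _ in range(config.strain_count)]
    reference = haplotypes[0]
    carriers: dict[tuple[int, int], list[int]] = {}
    for k in range(1, config.strain_count):
        for pos in np.flatnonzero(haplotypes[k] != reference):
            carriers.setdefault((int(pos), int(haplotypes[k][pos])), []).append(k)
    variants = [
        (pos, BASES[reference[pos]], BASES[alt], tuple(who))
        for (pos, alt), who in sorted(carriers.items())
    ]
    return SimTruth(reference=reference, haplotypes=haplotypes, variants=variants, config=config)


def _sample_strain_reads(
    hap: np.ndarray, coverage: float, config: StrainConfig, rng: np.random.Generator
):
    """Uniformly placed fixed-length reads with i.i.d. substitution errors.

    Yields (start, codes) pairs; read count targets ``coverage`` in the
    contig interior.
    """
    L = len(hap)
    rl = min(config.read_length, L)
    n_reads = int(round(coverage * (L - rl + 1) / rl)) if L > rl else max(1, int(round(coverage)))
    starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
    for start in starts:
        codes = _mutate(hap[start : start + rl], config.error_rate, rng)
        yield int(start), codes


def simulate_reads(truth: SimTruth, out_dir: str, prefix: str = "sim") -> dict:
    """Write reference FASTA (+ .fai) and a sorted, indexed BAM of reads.

    Reads are emitted pre-aligned at their true coordinates with a pure-match
    CIGAR (substitution-only simulation), NM set to the true mismatch count
    against the reference.  Returns the file paths and read count.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, f"{prefix}.fa")
    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    ref = truth.reference
    with open(fasta_path, "w") as fh:
        fh.write(f">{config.contig_name}\n")
        seq = truth.reference_seq
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(fasta_path)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.contig_name, "LN": len(ref)}],
    }
    unsorted = bam_path + ".unsorted.bam"
    n_reads = 0
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for strain, coverage in enumerate(config.coverages):
            hap = truth.haplotypes[strain]
            for start, codes in _sample_strain_reads(hap, coverage, config, rng):
                _write_read(bam, f"s{strain}_r{n_reads}", start, codes, ref)
                n_reads += 1
        for g in range(config.partial_clusters):
            strain = int(rng.integers(0, config.strain_count))
            hap = truth.haplotypes[strain]
            size = int(rng.integers(5, 9))
            rl = max(200, config.read_length // 2)
            rl = min(rl, len(hap))
            start = int(rng.integers(0, len(hap) - rl + 1))
            for j in range(size):
                codes = _mutate(hap[start : start + rl], config.error_rate, rng)
                _write_read(bam, f"pc{g}_s{strain}_r{j}", start, codes, ref)
                n_reads += 1
    pysam.sort("--no-PG", "-o", bam_path, unsorted)
    os.remove(unsorted)
    pysam.index(bam_path)
    return {"fasta": fasta_path, "bam": bam_path, "reads": n_reads}


def _write_read(bam, name: str, start: int, codes: np.ndarray, ref: np.ndarray) -> None:
    read = pysam.AlignedSegment(bam.header)
    read.query_name = name
    read.query_sequence = "".join(BASES[c] for c in codes)
    read.flag = 0
    read.reference_id = 0
    read.reference_start = start
    read.mapping_quality = 60
    read.cigartuples = [(0, len(codes))]
    nm = int(np.sum(codes != ref[start : start + len(codes)]))
    read.set_tag("NM", nm)
    read.set_tag("AS", len(codes) - nm)
    bam.write(read)


def simulate_dataset(ancestor_length: int, config: StrainConfig, out_dir: str, prefix: str = "sim"):
    """Convenience: haplotypes + reads in one call."""
    truth = simulate_haplotypes(ancestor_length, config)
    paths = simulate_reads(truth, out_dir, prefix)
    return truth, paths


def write_truth_vcf(truth: SimTruth, out_path: str) -> None:
    """Ground-truth variants as a minimal VCF v4.2 (1-based positions)."""
    name = truth.config.contig_name
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={name},length={len(truth.reference)}>\n")
        fh.write('##INFO=<ID=CARRIERS,Number=1,Type=String,Description="Strains carrying the allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt, who in truth.variants:
            carriers = ",".join(str(w) for w in who)
            fh.write(f"{name}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\tCARRIERS={carriers}\n")


def evaluate_calls(calls: list[VariantCall], truth: SimTruth) -> dict:
    """Recall and precision against the truth set, matching exact
    (position, alt); SNPs only.  Empty call sets report precision 1.0 with
    the zero denominator flagged."""
    truth_keys = truth.variant_keys
    call_keys = {(c.position, c.alt_base) for c in calls if c.alt_base in "ACGT"}
    matched = truth_keys & call_keys
    recall = len(matched) / len(truth_keys) if truth_keys else 1.0
    precision = len(matched) / len(call_keys) if call_keys else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(truth_keys),
        "n_calls": len(call_keys),
        "n_matched": len(matched),
        "empty_calls": not call_keys,
    }
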