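"""Alignment ingestion, window orchestration and VCF emission.

The caller walks each contig in fixed-length windows (half the median read
length by default), turns the overlapping alignments into matrices, runs the
iterative multi-locus caller per matrix, and writes the merged calls as a
site-only VCF v4.2.  Windows are independent work units, so they can be
processed by a thread pool and merged in genomic order — the output is
identical for any thread count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pysam

from . import rescue as rs
from .windows import (
    AlignmentView,
    NoReadsError,
    WindowSpec,
    build_binary_matrix,
    cluster_reads_by_coordinates,
    compute_window_length,
    encode_bases,
    estimate_error_rate,
    select_best_alignments,
)

logger = logging.getLogger("straincall")


@dataclass
class CallerConfig:
    """Every tunable of the caller, with the framework's defaults.

    ``window_length`` of None means auto (half the median read length,
    floored at ``min_window_length``).  ``error_multiplier`` inflates the
    measured divergence into the error bound s, clamped to
    [``s_floor``, ``s_cap``].
    """

    window_length: int | None = None
    min_window_length: int = 500
    min_alt_frac: float = 0.05
    pair_pvalue_cutoff: float = 0.05
    alpha: float = 1e-3
    rescue_pvalue: float = 1e-6
    error_multiplier: float = 3.0
    s_floor: float = 0.01
    s_cap: float = 0.95
    min_cluster_size: int = 5
    min_pair_overlap: int = 10
    max_rounds: int = 5
    thread_count: int = 1
    random_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_alt_frac", "pair_pvalue_cutoff", "alpha", "rescue_pvalue", "s_floor", "s_cap"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.error_multiplier <= 0:
            raise ValueError("error_multiplier must be positive")


def _view_from_read(read: pysam.AlignedSegment) -> AlignmentView:
    """Project one aligned read onto reference coordinates."""
    start, end = read.reference_start, read.reference_end
    from .windows import DEL, NONE, _ENCODE

    seq = read.query_sequence or ""
    cig = read.cigartuples or []
    if len(cig) == 1 and cig[0][0] == 0:  # single M op: pure substitutions
        bases = encode_bases(seq)
    else:
        bases = np.full(end - start, NONE, dtype=np.uint8)
        qcodes = encode_bases(seq) if seq else np.empty(0, dtype=np.uint8)
        for qpos, rpos in read.get_aligned_pairs():
            if rpos is None or rpos < start or rpos >= end:
                continue
            bases[rpos - start] = DEL if qpos is None else qcodes[qpos]
    aligned = int(np.sum(bases != NONE))
    try:
        nm = int(read.get_tag("NM"))
    except KeyError:
        nm = 0
    try:
        score = float(read.get_tag("AS"))
    except KeyError:
        score = float(aligned - nm)
    return AlignmentView(
        read_id=read.query_name,
        contig=read.reference_name,
        start=start,
        end=end,
        bases=bases,
        alignment_score=score,
        mismatch_count=nm,
        aligned_length=aligned,
    )


def resolve_window_length(bam: pysam.AlignmentFile, config: CallerConfig, sample: int = 10000) -> int:
    """Configured window length, or half the median mapped read length."""
    if config.window_length is not None:
        return config.window_length
    lengths = []
    for read in bam.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        lengths.append(read.query_length or read.infer_query_length() or 0)
        if len(lengths) >= sample:
            break
    bam.reset()
    return compute_window_length([l for l in lengths if l > 0], config.min_window_length)


def stream_windows(
    alignment_path: str,
    reference_path: str,
    config: CallerConfig,
) -> Iterator[tuple[WindowSpec, list[AlignmentView]]]:
    """Yield each contig's windows in order with their overlapping reads.

    Secondary and supplementary alignments are dropped before best-alignment
    selection, so each window sees at most one alignment per read.
    """
    with pysam.AlignmentFile(alignment_path, "rb") as bam, pysam.FastaFile(reference_path) as fasta:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{alignment_path} has no index; run `samtools index` on a coordinate-sorted BAM"
            )
        ref_names = set(fasta.references)
        missing = [c for c in bam.references if c not in ref_names]
        if missing:
            raise ValueError(
                f"contigs {missing[:5]} present in {alignment_path} but absent from "
                f"{reference_path}; BAM and FASTA must share contig names"
            )
        wlen = resolve_window_length(bam, config)
        if bam.mapped == 0:
            logger.warning("no mapped reads in %s; zero windows to process", alignment_path)
        for contig in bam.references:
            clen = fasta.get_reference_length(contig)
            for idx, lo in enumerate(range(0, clen, wlen)):
                window = WindowSpec(contig=contig, start=lo, end=min(lo + wlen, clen), index=idx)
                views = [
                    _view_from_read(read)
                    for read in bam.fetch(contig, window.start, window.end)
                    if not (read.is_unmapped or read.is_secondary or read.is_supplementary)
                ]
                yield window, select_best_alignments(views)


def process_window(
    window: WindowSpec,
    alignments: list[AlignmentView],
    ref_codes: np.ndarray,
    config: CallerConfig,
) -> tuple[list[rs.VariantCall], dict]:
    """Run the full caller on one window; returns (calls, log record)."""
    stats = {"window": window, "n": 0, "m_all": 0, "m": 0, "clusters": 0, "calls": 0}
    if not alignments:
        return [], stats
    try:
        error = estimate_error_rate(
            alignments, window, ref_codes,
            multiplier=config.error_multiplier, floor=config.s_floor, cap=config.s_cap,
        )
    except NoReadsError:
        return [], stats
    spanning = [a for a in alignments if a.covers(window.start, window.end)]
    partial = [a for a in alignments if not a.covers(window.start, window.end)]
    calls: list[rs.VariantCall] = []

    matrix = build_binary_matrix(window, spanning, ref_codes, extra_alignments=partial)
    stats.update(n=matrix.n, m_all=matrix.m_all)
    if matrix.n:
        calls.extend(rs.iterate_calling(matrix, error, config))
        stats["m"] = matrix.m

    # partial reads with identical coordinates: independent per-cluster matrices
    clusters = cluster_reads_by_coordinates(window, partial, min_size=config.min_cluster_size)
    stats["clusters"] = len(clusters.clusters)
    by_id = {a.read_id: a for a in partial}
    for ids, (cs, ce) in zip(clusters.clusters, clusters.coordinates):
        lo, hi = max(cs, window.start), min(ce, window.end)
        if hi - lo < 1:
            continue
        sub = WindowSpec(contig=window.contig, start=lo, end=hi, index=window.index)
        members = [by_id[i] for i in ids]
        others = [a for a in alignments if a.read_id not in set(ids)]
        cmatrix = build_binary_matrix(
            sub, members, ref_codes[lo - window.start : hi - window.start], extra_alignments=others
        )
        if cmatrix.n:
            calls.extend(rs.iterate_calling(cmatrix, error, config))

    calls = rs.dedupe_calls(calls)
    stats["calls"] = len(calls)
    return calls, stats


def write_vcf(calls: list[rs.VariantCall], reference_path: str, out_path: str) -> None:
    """Emit calls as a site-only VCF v4.2.

    Deletion-allele calls (matrix bookkeeping only) are dropped; co-located
    alternative alleles are merged into one record with alphabetically
    ordered comma-separated ALT and per-allele INFO fields.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=straincall')
    with pysam.FastaFile(reference_path) as fasta:
        for name in fasta.references:
            header.contigs.add(name, length=fasta.get_reference_length(name))
    header.add_meta(
        "INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Total read depth at the site")]
    )
    header.add_meta(
        "INFO", items=[("ID", "SR"), ("Number", "A"), ("Type", "Integer"), ("Description", "Reads supporting each alternative allele")]
    )
    header.add_meta(
        "INFO", items=[("ID", "LP"), ("Number", "A"), ("Type", "Float"), ("Description", "log10 evidence bound or p-value per allele")]
    )
    header.add_meta(
        "INFO", items=[("ID", "ST"), ("Number", "A"), ("Type", "String"), ("Description", "Call status per allele: MULTILOCUS, OBVIOUS or RESCUED")]
    )
    header.add_meta(
        "INFO", items=[("ID", "IT"), ("Number", "A"), ("Type", "Integer"), ("Description", "Masking round that produced each allele")]
    )
    snps = [c for c in calls if c.alt_base in "ACGT"]
    by_site: dict[tuple[str, int], list[rs.VariantCall]] = {}
    for call in snps:
        by_site.setdefault((call.contig, call.position), []).append(call)
    contig_order = {name: i for i, name in enumerate(header.contigs)}
    with pysam.VariantFile(out_path, "w", header=header) as vcf:
        for (contig, pos), site_calls in sorted(
            by_site.items(), key=lambda kv: (contig_order[kv[0][0]], kv[0][1])
        ):
            site_calls.sort(key=lambda c: c.alt_base)
            rec = vcf.new_record(
                contig=contig,
                start=pos,  # pysam start is 0-based; POS printed 1-based
                alleles=(site_calls[0].ref_base, *[c.alt_base for c in site_calls]),
            )
            rec.info["DP"] = max(c.depth for c in site_calls)
            rec.info["SR"] = tuple(c.support for c in site_calls)
            rec.info["LP"] = tuple(round(c.log10_p, 4) for c in site_calls)
            rec.info["ST"] = tuple(c.status for c in site_calls)
            rec.info["IT"] = tuple(c.iteration for c in site_calls)
            vcf.write(rec)


def run_caller(
    alignment_path: str,
    reference_path: str,
    out_path: str,
    config: CallerConfig | None = None,
) -> dict:
    """Orchestrate stream -> matrices -> iterative calling -> merged VCF.

    Returns a run summary: windows processed and call counts by status.
    """
    config = config or CallerConfig()
    all_calls: list[rs.VariantCall] = []
    n_windows = 0

    with pysam.FastaFile(reference_path) as fasta:
        ref_cache = {name: encode_bases(fasta.fetch(name)) for name in fasta.references}

    def work(item):
        window, alignments = item
        codes = ref_cache[window.contig][window.start : window.end]
        return process_window(window, alignments, codes, config)

    stream = stream_windows(alignment_path, reference_path, config)
    if config.thread_count > 1:
        with ThreadPoolExecutor(max_workers=config.thread_count) as pool:
            results = pool.map(work, stream)
            for calls, stats in results:
                n_windows += 1
                _log_window(stats)
                all_calls.extend(calls)
    else:
        for item in stream:
            calls, stats = work(item)
            n_windows += 1
            _log_window(stats)
            all_calls.extend(calls)

    all_calls = rs.dedupe_calls(all_calls)
    write_vcf(all_calls, reference_path, out_path)
    by_status = {s: 0 for s in (rs.MULTILOCUS, rs.OBVIOUS, rs.RESCUED)}
    for call in all_calls:
        by_status[call.status] += 1
    return {
        "windows": n_windows,
        "calls": len(all_calls),
        "by_status": by_status,
        "variant_calls": all_calls,
    }


def _log_window(stats: dict) -> None:
    w = stats["window"]
    if w is None:
        return
    logger.info(
        "window %s:%d-%d n=%d m_all=%d m=%d clusters=%d calls=%d",
        w.contig, w.start, w.end, stats["n"], stats["m_all"], stats["m"],
        stats["clusters"], stats["calls"],
    )
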