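"""Canned benchmark experiments on simulated communities.

These fix the study conditions used to characterise the caller: a null
single-strain run for type-I error, a balanced two-strain mixture, and an
uneven four-strain mixture with one low-coverage strain.  Problem sizes are
chosen so each experiment finishes in minutes on one CPU while leaving
enough windows/variants for stable rates (see docs/methods.md).
"""

from __future__ import annotations

import os
import tempfile

import pysam

from .io import CallerConfig, process_window, stream_windows
from .rescue import dedupe_calls
from .simulate import StrainConfig, evaluate_calls, simulate_dataset
from .windows import encode_bases


def _run_calls(paths, config: CallerConfig):
    with pysam.FastaFile(paths["fasta"]) as fa:
        ref = {name: encode_bases(fa.fetch(name)) for name in fa.references}
    calls = []
    windows_with_call = 0
    n_windows = 0
    for window, alignments in stream_windows(paths["bam"], paths["fasta"], config):
        wcalls, _stats = process_window(
            window, alignments, ref[window.contig][window.start : window.end], config
        )
        n_windows += 1
        windows_with_call += bool(wcalls)
        calls.extend(wcalls)
    return dedupe_calls(calls), n_windows, windows_with_call


def null_window_call_rate(
    seed: int,
    n_windows: int = 1000,
    depth: float = 50.0,
    error_rate: float = 0.03,
    window_length: int = 2000,
    workdir: str | None = None,
) -> dict:
    """Type-I error of the whole caller on variant-free data.

    One reference strain sequenced at ``depth`` with ``error_rate`` i.i.d.
    errors, over a contig tiled into ``n_windows`` windows (read length is
    twice the window so the half-median rule reproduces ``window_length``).
    Reports the fraction of windows emitting at least one call of any
    status; the union bound plus the threefold s inflation make the caller
    strongly conservative, so this should sit well below alpha.
    """
    cfg = StrainConfig(
        strain_count=1,
        divergence=0.0,
        coverages=(depth,),
        read_length=2 * window_length,
        error_rate=error_rate,
        seed=seed,
    )
    with _scratch(workdir) as d:
        _truth, paths = simulate_dataset(window_length * n_windows, cfg, d, "null")
        calls, n_win, with_call = _run_calls(paths, CallerConfig())
    return {
        "windows": n_win,
        "windows_with_call": with_call,
        "window_call_rate": with_call / n_win,
        "total_calls": len(calls),
    }


def two_strain_benchmark(
    seed: int,
    contig_length: int = 100_000,
    divergence: float = 0.01,
    depth: float = 20.0,
    error_rate: float = 0.05,
    workdir: str | None = None,
) -> dict:
    """Recall/precision on a balanced two-strain mixture (20x + 20x, 1%
    divergence, 5% read error by default)."""
    cfg = StrainConfig(
        strain_count=2,
        divergence=divergence,
        coverages=(depth, depth),
        read_length=4000,
        error_rate=error_rate,
        seed=seed,
    )
    with _scratch(workdir) as d:
        truth, paths = simulate_dataset(contig_length, cfg, d, "two")
        calls, n_win, _wc = _run_calls(paths, CallerConfig())
        ev = evaluate_calls(calls, truth)
    ev["windows"] = n_win
    return ev


def uneven_coverage_benchmark(
    seed: int,
    contig_length: int = 100_000,
    divergence: float = 0.01,
    low_depth: float = 5.0,
    error_rate: float = 0.01,
    workdir: str | None = None,
) -> dict:
    """Four strains, three at 20x and one at ``low_depth``: measures overall
    recall/precision plus recall restricted to the low-coverage strain's
    private SNPs — the hard case for ploidy-assuming callers."""
    cfg = StrainConfig(
        strain_count=4,
        divergence=divergence,
        coverages=(20.0, 20.0, 20.0, low_depth),
        read_length=4000,
        error_rate=error_rate,
        seed=seed,
    )
    with _scratch(workdir) as d:
        truth, paths = simulate_dataset(contig_length, cfg, d, "uneven")
        calls, _n, _wc = _run_calls(paths, CallerConfig())
        ev = evaluate_calls(calls, truth)
    low = len(cfg.coverages) - 1
    private = {
        (pos, alt) for pos, _ref, alt, who in truth.variants if who == (low,)
    }
    called = {(c.position, c.alt_base) for c in calls if c.alt_base in "ACGT"}
    ev["private_truth"] = len(private)
    ev["private_recall"] = len(private & called) / len(private) if private else 1.0
    return ev


class _scratch:
    """Temporary directory unless the caller supplies one."""

    def __init__(self, workdir: str | None):
        self.workdir = workdir
        self._tmp = None

    def __enter__(self) -> str:
        if self.workdir is not None:
            os.makedirs(self.workdir, exist_ok=True)
            return self.workdir
        self._tmp = tempfile.TemporaryDirectory(prefix="straincall_")
        return self._tmp.name

    def __exit__(self, *exc):
        if self._tmp is not None:
            self._tmp.cleanup()
        return False
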