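import numpy as np
import pytest

from straincall import AlignmentView, BinaryMatrix, WindowSpec, encode_bases


def make_view(
    read_id: str,
    start: int,
    seq: str,
    contig: str = "c1",
    score: float | None = None,
    mismatches: int = 0,
) -> AlignmentView:
    bases = encode_bases(seq)
    return AlignmentView(
        read_id=read_id,
        contig=contig,
        start=start,
        end=start + len(seq),
        bases=bases,
        alignment_score=score if score is not None else float(len(seq)),
        mismatch_count=mismatches,
        aligned_length=len(seq),
    )


def make_matrix(ref: str, rows: list[str], contig: str = "c1", start: int = 0) -> BinaryMatrix:
    """Matrix straight from observed-base strings (all reads span the window)."""
    m = len(ref)
    window = WindowSpec(contig=contig, start=start, end=start + m, index=0)
    observed = np.stack([encode_bases(r) for r in rows]) if rows else np.empty((0, m), np.uint8)
    from straincall.windows import N_CODES

    return BinaryMatrix(
        window=window,
        read_ids=[f"r{i}" for i in range(len(rows))],
        positions=np.arange(start, start + m, dtype=np.int64),
        ref_codes=encode_bases(ref),
        observed=observed,
        extra_counts=np.zeros((N_CODES, m), dtype=np.int64),
    )


@pytest.fixture(scope="session")
def two_strain_dataset(tmp_path_factory):
    """Small two-strain simulation shared by IO/pipeline tests."""
    import straincall as sc

    out = tmp_path_factory.mktemp("twostrain")
    cfg = sc.StrainConfig(
        strain_count=2,
        divergence=0.01,
        coverages=(20.0, 20.0),
        read_length=4000,
        error_rate=0.05,
        seed=42,
    )
    truth, paths = sc.simulate_dataset(20000, cfg, str(out))
    return truth, paths
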