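import numpy as np
import pytest

from synqtl.model import AnchorHit


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_hits(rng, n, n_chrom=4, chrom_len=10_000_000, with_query=False):
    """Uniformly random anchor hits, optionally carrying query coordinates."""
    hits = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 5000))
        length = int(rng.integers(100, 3000))
        identity = float(rng.uniform(0.5, 1.0))
        coverage = float(rng.uniform(0.2, 1.0))
        match = int(identity * length)
        kw = {}
        if with_query:
            qs = int(rng.integers(0, chrom_len))
            kw = dict(
                query_chrom=f"Q{int(rng.integers(n_chrom)) + 1:02d}",
                query_start=float(qs), query_end=float(qs + length),
            )
        hits.append(AnchorHit(
            query_id=f"q{i:04d}",
            target_chrom=f"T{int(rng.integers(n_chrom)) + 1:02d}",
            target_start=start,
            target_end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            identity=identity, coverage=coverage,
            aligned_length=length, match_bp=match, mismatch_bp=length - match,
            **kw,
        ))
    return hits


@pytest.fixture
def gmap_gff3(tmp_path):
    """Small GMAP-style alignment GFF3: one mRNA feature at 1001..2000."""
    text = (
        "##gff-version 3\n"
        "chr01\tgmap\tgene\t1001\t2000\t.\t+\t.\tID=gene1;Name=CDS001\n"
        "chr01\tgmap\tmRNA\t1001\t2000\t.\t+\t.\t"
        "ID=mrna1;Name=CDS001;Parent=gene1;coverage=80.0;identity=95.0;"
        "matches=950;mismatches=50;Target=CDS001 1 1000\n"
    )
    path = tmp_path / "aln.gff3"
    path.write_text(text)
    return path
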