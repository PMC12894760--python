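import numpy as np
import pytest

from ecordkit.genome_model import DEGRecord, GeneRecord, TadInterval, classify_gene


def make_deg(gene_id: str, klass: str) -> DEGRecord:
    """Build a DEGRecord of a requested class with representative stats."""
    stats = {
        "DEG_UP": (2.0, 0.01), "DEG_DOWN": (-2.0, 0.01),
        "BREAKER_UP": (0.5, 0.01), "BREAKER_DOWN": (-0.5, 0.01),
        "STATIC": (0.1, 0.5), "UNEXPRESSED": (0.0, None),
    }
    lfc, padj = stats[klass]
    rec = DEGRecord.from_stats(gene_id, lfc, padj)
    assert rec.klass == klass
    return rec


def linear_genes(classes, chrom="chr1", gene_len=1000, gap=1000):
    """Equally spaced plus-strand genes, one per class label."""
    genes, degs = [], {}
    pos = 0
    for i, klass in enumerate(classes):
        gid = f"g{i + 1}"
        genes.append(GeneRecord(gid, chrom, pos, pos + gene_len, "+"))
        if klass is not None:
            degs[gid] = make_deg(gid, klass)
        pos += gene_len + gap
    return genes, degs


@pytest.fixture
def one_tad():
    return [TadInterval("chr1", 0, 10_000_000, "tad1")]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
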