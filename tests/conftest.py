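import io

import numpy as np
import pandas as pd
import pytest

from omicpipe import gene_model as gm

TOY_GTF = """\
chr1\tsrc\tgene\t100\t299\t.\t+\t.\tgene_id "g1"; gene_type "protein_coding";
chr1\tsrc\texon\t100\t199\t.\t+\t.\tgene_id "g1";
chr1\tsrc\texon\t150\t299\t.\t+\t.\tgene_id "g1";
chr1\tsrc\tgene\t1000\t1999\t.\t-\t.\tgene_id "g2"; gene_type "protein_coding";
chr1\tsrc\texon\t1000\t1999\t.\t-\t.\tgene_id "g2";
chr2\tsrc\tgene\t1\t500\t.\t+\t.\tgene_id "g3"; gene_type "lincRNA";
chr2\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g3";
chr2\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "g3";
"""


@pytest.fixture
def toy_model() -> gm.GeneModel:
    return gm.parse_gtf(io.StringIO(TOY_GTF))


def random_model(n_genes: int, rng: np.random.Generator, pc_frac: float = 0.8) -> gm.GeneModel:
    """Random single-exon gene model; most genes protein-coding."""
    records = {}
    for i in range(n_genes):
        gid = f"G{i:04d}"
        start = int(rng.integers(1, 1_000_000))
        length = int(rng.integers(200, 5000))
        biotype = "protein_coding" if rng.random() < pc_frac else "lincRNA"
        records[gid] = gm.GeneRecord(
            gene_id=gid, biotype=biotype, chrom="chr1", strand="+",
            exons=[(start, start + length - 1)],
        )
    return gm.GeneModel(records=records)


def random_counts(model: gm.GeneModel, n_samples: int, rng: np.random.Generator) -> pd.DataFrame:
    genes = list(model.records)
    counts = rng.integers(0, 500, size=(len(genes), n_samples))
    return pd.DataFrame(counts, index=genes, columns=[f"S{j}" for j in range(n_samples)])
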