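from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan.panel import GenotypePanel


def make_panel(genotypes, positions=None, chrom="1", individuals=None, qual=None):
    """Small-panel builder: genotype rows are individuals, columns are sites."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_site = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_site + 1) * 1000
    if individuals is None:
        individuals = [f"s{i + 1}" for i in range(n_ind)]
    if np.isscalar(chrom):
        chroms = [str(chrom)] * n_site
    else:
        chroms = [str(c) for c in chrom]
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "C",
            "qual": qual if qual is not None else [None] * n_site,
        }
    )
    return GenotypePanel(sites=sites, individuals=list(individuals), genotypes=genotypes)


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples x 5 biallelic SNPs on chromosome 1, plus writer conveniences."""
    path = tmp_path / "tiny.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=100000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
        "1\t100\t.\tA\tC\t60\t.\t.\tGT\t0/0\t0/1\t1/1",
        "1\t200\t.\tG\tT\t60\t.\t.\tGT\t0|1\t1/0\t0/0",
        "1\t300\t.\tA\tG\t60\t.\t.\tGT\t./.\t0/0\t1/1",
        "1\t400\t.\tC\tT\t60\t.\t.\tGT\t1/1\t1/1\t1/1",
        "1\t500\t.\tT\tA\t60\t.\t.\tGT\t0/0\t0/0\t0/1",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def random_genotype_column(rng, n, missing_rate=0.1):
    col = rng.choice([0, 1, 2], size=n)
    col[rng.random(n) < missing_rate] = -1
    return col.astype(np.int8)
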