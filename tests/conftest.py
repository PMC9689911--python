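import numpy as np
import pandas as pd
import pytest

from prscape.catalog import RiskModel


def make_model(betas, alleles=None, rsids=None, chroms=None) -> RiskModel:
    """Build a small risk model directly from weights."""
    betas = np.asarray(betas, dtype=float)
    n = len(betas)
    rsids = rsids or [f"rs{i + 1}" for i in range(n)]
    alleles = alleles or ["G"] * n
    chroms = chroms or ["1"] * n
    return RiskModel(
        pd.DataFrame(
            {
                "rsid": rsids,
                "chrom": chroms,
                "pos": [1000 * (i + 1) for i in range(n)],
                "effect_allele": alleles,
                "beta_i": betas,
                "n_studies": 1,
                "flags": "",
            }
        )
    )


def write_vcf(path, records, samples):
    """Write a minimal VCF; records are (chrom, pos, rsid, ref, alt, gt_strings)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, rsid, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


@pytest.fixture
def simple_model():
    return make_model([1.2, 1.8], alleles=["G", "T"])
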