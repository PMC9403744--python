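"""Shared fixtures: tiny genomes, in-memory variant sites, text VCF writer."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from selfco.variant_io import ChromTable, GenotypeState, SampleCall, VariantSite

VCF_META = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def make_vcf(path: Path, records: list[tuple], samples: list[str],
             contigs: dict[str, int]) -> Path:
    """Write a minimal text VCF.

    Each record is (chrom, pos, ref, alt, qual, [per-sample "GT:DP:AD" strings]).
    """
    lines = [VCF_META.rstrip()]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for chrom, pos, ref, alt, qual, fields in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:DP:AD\t"
                     + "\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def site(chrom="chr1", pos=100, ref="G", alt="A", qual=50.0,
         state=GenotypeState.HET, depth=20, alt_count=10,
         sample="M2") -> VariantSite:
    return VariantSite(chrom, pos, ref, alt, qual,
                       {sample: SampleCall(state, depth, alt_count)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_chroms():
    return ChromTable([("chrA", 60_000_000), ("chrB", 40_000_000)])
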