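"""Shared fixtures: toy reference genomes and hand-built VCF files."""

import numpy as np
import pytest
from pyfaidx import Faidx

from mutaccum.io import ReferenceGenome
from mutaccum.simulate import make_toy_genome


def write_fasta(path, seq, name="chr1"):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    Faidx(str(path)).close()
    return path


@pytest.fixture(scope="session")
def toy_genome_seq():
    return make_toy_genome(20_000, np.random.default_rng(123))


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory, toy_genome_seq):
    path = tmp_path_factory.mktemp("ref") / "toy.fa"
    write_fasta(path, toy_genome_seq)
    return ReferenceGenome(path)


def make_vcf(path, rows, contig="chr1", contig_len=2**28):
    """Write a minimal VCF from (chrom, pos, ref, alt, filter, info) tuples."""
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_len}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="e">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">',
        '##FILTER=<ID=LowQual,Description="lq">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = [
        f"{c}\t{p}\t.\t{r}\t{a}\t.\t{flt}\t{info}"
        for c, p, r, a, flt, info in rows
    ]
    path.write_text("\n".join(header + body) + "\n")
    return path
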