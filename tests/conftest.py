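import numpy as np
import pytest

from admixscan.core_io import HaplotypeMatrix, PopulationMap

TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t0|0
chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1|1\t0|1
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0|0\t.|.
"""


@pytest.fixture
def toy_vcf_text():
    return TOY_VCF


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def make_hm():
    """Factory building a HaplotypeMatrix from an allele row list."""

    def build(alleles, positions=None, samples=None, scaffold="scaf1"):
        alleles = np.asarray(alleles, dtype=np.int8)
        n_hap, n_sites = alleles.shape
        assert n_hap % 2 == 0
        if positions is None:
            positions = np.arange(n_sites, dtype=np.int64)
        if samples is None:
            samples = [f"s{i}" for i in range(n_hap // 2)]
        return HaplotypeMatrix(
            scaffold=scaffold,
            positions=np.asarray(positions),
            alleles=alleles,
            samples=samples,
        )

    return build


@pytest.fixture
def make_popmap():
    def build(assignments):
        """assignments: {sample: pop} or {sample: (pop, sex)}"""
        entries = {}
        for s, v in assignments.items():
            if isinstance(v, str):
                entries[s] = (v, "unknown")
            else:
                entries[s] = tuple(v)
        return PopulationMap(entries)

    return build
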