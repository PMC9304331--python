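import numpy as np
import pytest

from jointgp.breedsim import SimConfig, run_breeding_program

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\tm1\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:30,30\t0/0:50,0
chr1\t200\tm2\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:20,25\t1/1:0,60
chr1\t300\tm3\tG\tA,T\t.\tPASS\t.\tGT:AD\t0/1:40,20\t0/1:25,30
"""


@pytest.fixture
def vcf_path(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def mini_sim():
    """A small but structurally complete breeding program (fast)."""
    cfg = SimConfig(
        chromosomes=3,
        snps_per_chrom=80,
        qtl_per_chrom=10,
        founders=20,
        burn_in_years=2,
        recorded_years=3,
        families=10,
        family_size=20,
        select_per_family=5,
        ayt_size=10,
        eyt_size=3,
        seed=7,
    )
    return cfg, run_breeding_program(cfg)
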