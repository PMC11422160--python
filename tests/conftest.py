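import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """A hand-sized simulated panel shared by cheap unit tests."""
    from hapnn.sim import SimConfig, simulate_panel

    return simulate_panel(SimConfig(n_sites=120, n_samples=40, seed=7))


@pytest.fixture
def phased_vcf(tmp_path):
    """Hand-written 3-site, 2-sample fully phased VCF fixture.

    Expected allele matrix (sites x haplotypes):
        [[0,1,0,0],
         [1,1,1,0],
         [0,0,0,1]]
    """
    text = """\
##fileformat=VCFv4.2
##contig=<ID=22,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2
22\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t0|0
22\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1|1\t1|0
22\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0|0\t0|1
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
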