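import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import beaconkit as bk
from beaconkit import access_control as ac
from beaconkit.beacon_core import Beacon

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The single worked-example fixture: a dataset that has observed nucleotide C at
# (1-based) position 32,936,732 on chromosome 13.
EXAMPLE_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=13>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
13\t32936732\t.\tG\tC\t.\t.\t.
"""


@pytest.fixture(scope="session")
def example_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "example.vcf"
    path.write_text(EXAMPLE_VCF)
    return path


@pytest.fixture(scope="session")
def small_population():
    return bk.simulate_population(60, 400, seed=123)


@pytest.fixture(scope="session")
def mid_population():
    """Shared by the attack-scaling and defense tests (1,500 x 20,000 sites)."""
    return bk.simulate_population(1500, 20000, seed=11)


@pytest.fixture(scope="session")
def small_vcf(tmp_path_factory, small_population):
    path = tmp_path_factory.mktemp("fixtures") / "small.vcf"
    bk.write_vcf(small_population, range(30), path)
    return path


@pytest.fixture()
def small_index(small_vcf):
    return bk.ingest_vcf(small_vcf, "small", "SYNTH")


@pytest.fixture()
def example_beacon(example_vcf):
    beacon = Beacon("beacon-example", organization="Example Org")
    beacon.add_dataset(bk.ingest_vcf(example_vcf, "ds-example", "GRCh37"))
    return beacon


def random_allele_keys(rng: np.random.Generator, n: int, assembly: str = "SYNTH"):
    """Random SNV keys in the coordinate space the VCF fixture writer uses."""
    bases = np.array(list("ACGT"))
    starts = rng.integers(0, 5000, size=n)
    refs = bases[rng.integers(0, 4, size=n)]
    alt_offsets = rng.integers(1, 4, size=n)
    keys = []
    for start, ref, off in zip(starts, refs, alt_offsets):
        alt = bases[(np.flatnonzero(bases == ref)[0] + off) % 4]
        keys.append(
            bk.AlleleKey(
                assembly_id=assembly,
                chromosome="1",
                start=int(start),
                ref_bases=str(ref),
                alt_bases=str(alt),
            )
        )
    return keys
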