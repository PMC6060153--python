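import numpy as np
import pandas as pd
import pytest

from hqtlnet import simulate as sim
from hqtlnet.types import GenotypeTable


@pytest.fixture
def small_genotypes() -> GenotypeTable:
    """Four LD-structured blocks of 5 variants, 25 samples."""
    rng = np.random.default_rng(11)
    blocks = sim.default_blocks(4, 5, rng)
    gt, _ = sim.simulate_genotypes(sim.SimSpec(n_samples=25, blocks=blocks, seed=7))
    return gt


@pytest.fixture
def two_variant_table() -> GenotypeTable:
    """A minimal table used where only variant coordinates matter."""
    variants = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [0, 1],
         "ref": ["A", "A"], "alt": ["G", "G"]},
        index=pd.Index(["hsnp", "esnp"], name="id"),
    )
    hap = np.array([[0, 1], [0, 1]], dtype=np.int8)
    return GenotypeTable(variants, ["s0", "s1"], hap, hap.copy())


def make_haplotype_table(hap_a: list[int], hap_b: list[int]) -> GenotypeTable:
    """Two variants whose phased haplotypes are given explicitly.

    ``hap_a``/``hap_b`` list the allele carried by each of 2N haplotypes at
    the two loci; consecutive pairs form one diploid sample.
    """
    assert len(hap_a) == len(hap_b) and len(hap_a) % 2 == 0
    n = len(hap_a) // 2
    variants = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [100, 200],
         "ref": ["A", "A"], "alt": ["G", "G"]},
        index=pd.Index(["va", "vb"], name="id"),
    )
    hap1 = np.array([hap_a[0::2], hap_b[0::2]], dtype=np.int8)
    hap2 = np.array([hap_a[1::2], hap_b[1::2]], dtype=np.int8)
    return GenotypeTable(variants, [f"s{i}" for i in range(n)], hap1, hap2)
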