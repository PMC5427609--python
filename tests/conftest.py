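import numpy as np
import pandas as pd
import pytest

from breedsig.io import HaplotypePanel, SamplePanel, recode_major_minor, ternary_encode
from breedsig.simulate import SimConfig, simulate_panel


def make_panel(haplotypes, breeds, chrom="chr1", positions=None, ref="A", alt="T"):
    """Hand-built panel from a (2N, S) 0/1 matrix and per-sample breed labels."""
    hap = np.asarray(haplotypes, dtype=np.uint8)
    n_samples = hap.shape[0] // 2
    assert hap.shape[0] == 2 * n_samples and len(breeds) == n_samples
    s = hap.shape[1]
    if positions is None:
        positions = np.arange(1, s + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "ref": ref, "alt": alt}
    )
    samples = SamplePanel(
        np.array([f"s{i:02d}" for i in range(n_samples)], dtype=object),
        np.asarray(breeds, dtype=object),
    )
    return HaplotypePanel(samples=samples, sites=sites, haplotypes=hap)


SMALL_SIM = dict(
    n_sites=2000,
    chrom_length=1_000_000,
    n_genes=40,
    gene_length=10_000,
    signature_genes=5,
    opposite_genes=1,
    sweep_specs=((0, 500_000, 0.9, 100_000),),
    seed=7,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A desk-sized planted panel: 2 breeds x (10, 9), 2k SNPs, 40 genes."""
    return simulate_panel(SimConfig(**SMALL_SIM))


@pytest.fixture(scope="session")
def small_recoded(small_fixture):
    panel, genes, truth = small_fixture
    recoded = recode_major_minor(panel.copy())
    return recoded, ternary_encode(recoded), genes, truth
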