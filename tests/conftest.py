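import numpy as np
import pandas as pd
import pytest

from seedmethylome.genome import ReferenceGenome
from seedmethylome.simulate import SeedMethylomeSimulator, SimulationConfig

#: a miniature study for planted-truth unit tests (a fraction of the default size)
SMALL_SIM_KWARGS = dict(
    seed=11,
    genome_size=150_000,
    n_features={
        "protein_coding_gene": 10,
        "pseudogene": 3,
        "transposable_element": 6,
        "repeat": 6,
    },
    dmr_n_windows=15,
    srna_total=15_000,
)


@pytest.fixture(scope="session")
def small_sim():
    return SeedMethylomeSimulator(SimulationConfig(**SMALL_SIM_KWARGS))


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim.simulate_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_genome(seq: str, name: str = "chr1") -> ReferenceGenome:
    return ReferenceGenome({name: seq})


def random_calls(rng, n=100, contig="chr1", span=1000, max_reads=30) -> pd.DataFrame:
    """Random but structurally valid call table for IO/invariance tests."""
    pos = np.sort(rng.integers(0, span, size=n))
    cov = rng.integers(0, max_reads, size=n)
    n_meth = rng.binomial(cov, rng.random(n))
    return pd.DataFrame(
        {
            "chrom": contig,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n),
            "context": rng.choice(["CG", "CHG", "CHH"], size=n),
            "n_meth": n_meth,
            "n_unmeth": cov - n_meth,
        }
    )
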