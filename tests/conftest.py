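import numpy as np
import pytest

import radpop as rp
from radpop.trees import Tree


@pytest.fixture(scope="session")
def four_pop_tree() -> Tree:
    """Asymmetric quartet (((W,X),Y),Z) with Z a deep outgroup."""
    return Tree.from_newick("(((W:0.02,X:0.02):0.02,Y:0.04):0.02,Z:0.2);")


@pytest.fixture(scope="session")
def five_pop_tree() -> Tree:
    return Tree.from_newick(
        "(((A:0.02,B:0.02):0.02,C:0.04):0.02,(D:0.04,E:0.04):0.02);"
    )


@pytest.fixture(scope="session")
def diverged_tree() -> Tree:
    """Moderately drifted 5-population tree with a distinct outgroup (E)."""
    return Tree.from_newick(
        "(((A:0.05,B:0.05):0.03,C:0.08):0.03,(D:0.06,E:0.2):0.05);"
    )


@pytest.fixture(scope="session")
def diverged_matrix(diverged_tree) -> rp.GenotypeMatrix:
    config = rp.SimulationConfig(
        tree=diverged_tree,
        n_sites=5000,
        n_per_pop={p: 8 for p in "ABCDE"},
        seed=19,
    )
    return rp.sample_genotypes(rp.simulate_frequencies(config))


@pytest.fixture(scope="session")
def small_matrix(five_pop_tree) -> rp.GenotypeMatrix:
    """5 populations x 8 diploids, 5,000 polymorphic SNPs, no missingness."""
    config = rp.SimulationConfig(
        tree=five_pop_tree,
        n_sites=5000,
        n_per_pop={p: 8 for p in "ABCDE"},
        seed=11,
    )
    return rp.sample_genotypes(rp.simulate_frequencies(config))


def make_matrix(dosage, depth=None, pops=None, samples=None):
    """Build a GenotypeMatrix from a raw dosage array (tests' shorthand)."""
    import pandas as pd

    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if depth is None:
        depth = np.full(dosage.shape, 20, dtype=np.int32)
    else:
        depth = np.asarray(depth, dtype=np.int32)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        popmap = {s: "pop1" for s in samples}
    else:
        popmap = dict(zip(samples, pops))
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": 1 + 1000 * np.arange(n_sites),
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    return rp.GenotypeMatrix(sites, list(samples), dosage, depth, popmap)
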