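"""Shared fixtures: small synthetic panels built at test time."""

import numpy as np
import pandas as pd
import pytest

import crossqtl as cq


@pytest.fixture(scope="session")
def small_map():
    return cq.make_marker_map({"chrA": 400_000, "chrB": 400_000}, 10_000)


@pytest.fixture(scope="session")
def small_geno(small_map):
    return cq.simulate_genotypes(small_map, 80, seed=42)


@pytest.fixture(scope="session")
def collapsed(small_geno):
    return cq.process_genotypes(small_geno)


@pytest.fixture(scope="session")
def mapping_panel():
    """110 strains, ~300 unique markers: the mapper's working scale."""
    mm = cq.make_marker_map({f"chr{c}": 760_000 for c in "ABCD"}, 10_000)
    geno = cq.simulate_genotypes(mm, 110, seed=7)
    uset = cq.process_genotypes(geno)
    cov = cq.structure_eigenvectors(uset.calls, k=7).vectors
    return geno, uset, cov


@pytest.fixture(scope="session")
def replicate_design():
    """Balanced design: 20 strains x 3 replicates."""
    strains = [f"s{i:02d}" for i in range(20)]
    rows = [(f"{s}_r{r}", s, "batch0", r) for s in strains for r in range(3)]
    return pd.DataFrame(rows, columns=["sample", "strain", "batch", "replicate"])


def simulate_h2_samples(h2_true, design, rng, sigma_e=1.0):
    """Samples with a known broad-sense heritability (balanced design)."""
    sigma_g = np.sqrt(h2_true / (1 - h2_true)) * sigma_e
    strains = design["strain"].unique()
    strain_val = dict(zip(strains, rng.normal(0, sigma_g, len(strains))))
    return np.array([strain_val[s] for s in design["strain"]]) + rng.normal(
        0, sigma_e, len(design))
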