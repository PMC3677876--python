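import numpy as np
import pandas as pd
import pytest

import ovinescan as ov


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def two_breed_dataset():
    """Two drifted breeds, study-like sample sizes, 2,000 markers."""
    spec = ov.SimulationSpec(
        chrom_layout=ov.default_chrom_layout(2000, n_autosomes=10),
        populations=[("Suffolk", 18, 0.1621), ("Rambouillet", 16, 0.1621)],
        seed=101,
    )
    return ov.simulate(spec)


@pytest.fixture(scope="session")
def five_breed_dataset():
    """Five breeds at the study's sizes, mild drift, 1,500 markers."""
    spec = ov.SimulationSpec(
        chrom_layout=ov.default_chrom_layout(1500, n_autosomes=10),
        populations=[
            ("Columbia", 19, 0.114),
            ("Polypay", 19, 0.114),
            ("Rambouillet", 16, 0.114),
            ("Suffolk", 18, 0.114),
            ("Targhee", 22, 0.114),
        ],
        seed=202,
    )
    return ov.simulate(spec)


def make_dataset(genotypes, breeds=None, chroms=None, positions=None, sexes=None):
    """Hand-build a GenotypeDataset from a small genotype matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    breeds = breeds if breeds is not None else ["B1"] * n
    chroms = chroms if chroms is not None else ["1"] * m
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    sexes = sexes if sexes is not None else [1] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "breed": breeds,
            "sex": sexes,
        }
    )
    markers = pd.DataFrame(
        {
            "name": [f"m{j}" for j in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return ov.GenotypeDataset(samples=samples, markers=markers, genotypes=g)
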