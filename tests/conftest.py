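import numpy as np
import pandas as pd
import pytest

from autozygome.genotype_io import GenotypeDataset


def make_dataset(
    calls,
    chromosomes=None,
    positions=None,
    populations=None,
    birth_years=None,
    spacing_bp=100_000,
):
    """Build a GenotypeDataset from a raw call matrix with sensible defaults:
    one chromosome, evenly spaced markers, single population."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if chromosomes is None:
        chromosomes = np.ones(m, dtype=int)
    if positions is None:
        positions = np.zeros(m, dtype=int)
        for ch in np.unique(chromosomes):
            idx = np.flatnonzero(chromosomes == ch)
            positions[idx] = (np.arange(len(idx)) + 1) * spacing_bp
    markers = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "a1": "A",
            "a2": "B",
        }
    )
    if populations is None:
        populations = ["P"] * n
    samples = pd.DataFrame(
        {
            "animal_id": [f"an{i}" for i in range(n)],
            "population": populations,
            "sex": "cow",
            "birth_year": 2000 if birth_years is None else birth_years,
            "herd_id": "h1",
        }
    )
    return GenotypeDataset(samples, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
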