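import numpy as np
import pytest

from recpeel.core import GenotypeMatrix, MarkerMap, Pedigree
from recpeel.simulate import SimConfig, simulate


def make_pedigree(records):
    """Build a Pedigree from (id, sire, dam, sex, line) tuples; '0' = unknown."""
    ids = [r[0] for r in records]
    index = {i: k for k, i in enumerate(ids)}
    sire = np.array([index[r[1]] if r[1] != "0" else -1 for r in records])
    dam = np.array([index[r[2]] if r[2] != "0" else -1 for r in records])
    sex = np.array([r[3] if len(r) > 3 else "U" for r in records])
    line = np.array([r[4] if len(r) > 4 else "1" for r in records], dtype=object)
    return Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, line=line)


def make_genotypes(pedigree, rows):
    """GenotypeMatrix aligned to a pedigree from {id: list-of-codes}."""
    L = len(next(iter(rows.values())))
    calls = np.full((len(pedigree), L), 9, dtype=np.uint8)
    for ident, row in rows.items():
        calls[pedigree.index_of(ident)] = row
    panel = np.array(
        ["high" if (calls[i] != 9).any() else "ungenotyped" for i in range(len(pedigree))],
        dtype=object,
    )
    return GenotypeMatrix(ids=list(pedigree.ids), calls=calls, panel=panel)


def make_marker_map(n_loci, chromosome="1", spacing=100_000):
    return MarkerMap(
        ids=[f"m{j}" for j in range(n_loci)],
        chromosome=np.full(n_loci, chromosome, dtype=object),
        position=np.arange(1, n_loci + 1) * spacing,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Moderate simulated dataset shared across tests (error-free calls)."""
    return simulate(
        SimConfig(
            n_founders=120,
            n_per_generation=120,
            n_sires=8,
            n_dams=60,
            n_loci=120,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
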