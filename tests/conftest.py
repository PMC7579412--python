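import numpy as np
import pytest

from ddgbench.core import MutationRecord
from ddgbench.synthetic import (
    SyntheticSpec,
    gen_mutation_table,
    gen_packed_core,
    gen_parent_sequences,
    gen_parent_structures,
    gen_two_chain_helices,
)


@pytest.fixture(scope="session")
def packed_core():
    return gen_packed_core()


@pytest.fixture(scope="session")
def helices_far():
    return gen_two_chain_helices(50.0)


@pytest.fixture(scope="session")
def helices_close():
    return gen_two_chain_helices(4.0)


@pytest.fixture(scope="session")
def parent_sequences():
    return gen_parent_sequences(seed=11)


@pytest.fixture(scope="session")
def parent_structures(parent_sequences):
    return gen_parent_structures(parent_sequences)


@pytest.fixture(scope="session")
def synthetic_records(parent_sequences):
    spec = SyntheticSpec(n_records=300, seed=11)
    return gen_mutation_table(spec, parent_sequences)


def make_record(wt="L", mut="Q", pos="10", pdb="1ABC", chain="A", ddg=1.0, ph=7.0):
    return MutationRecord(
        pdb_id=pdb, chain=chain, position=pos, wt_aa=wt, mut_aa=mut,
        ddg_exp=ddg, ph=ph,
    )


def grid_sasa(structure, radii_of, probe=1.4, n_points=3000, seed=0):
    """Independent SASA oracle: random sphere sampling per atom.

    For each atom, points are drawn uniformly on its solvent-expanded
    sphere; the free fraction times the expanded-sphere area is its SASA.
    Deliberately shares no code with the production path.
    """
    rng = np.random.default_rng(seed)
    coords = structure.coords
    radii = np.array([radii_of(a) for a in structure.atoms]) + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + radii[i] * v
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            free &= d2 > radii[j] ** 2
        areas[i] = free.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas
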