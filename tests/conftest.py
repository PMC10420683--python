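import numpy as np
import pytest

from topoindex import fixture_compounds, table1
from topoindex.elements import ELEMENTS
from topoindex.structures import Atom, Bond, MolecularGraph


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {g.name: g for g in fixture_compounds()}


@pytest.fixture(scope="session")
def published_table():
    return table1()


def random_molecule(rng: np.random.Generator, max_atoms: int = 12) -> MolecularGraph:
    """Random single-bonded tree molecule with C backbone and heteroatom leaves.

    Hydrogen counts are filled to the smallest allowed valence, so every
    generated graph satisfies the package's valence invariant.
    """
    n = int(rng.integers(2, max_atoms + 1))
    parents = [int(rng.integers(0, i)) for i in range(1, n)]
    # cap carbon degree at 4 by re-drawing overloaded parents
    degree = [0] * n
    bonds = []
    for child, parent in enumerate(parents, start=1):
        while degree[parent] >= 4:
            parent = int(rng.integers(0, child))
        bonds.append(Bond(parent, child, 1))
        degree[parent] += 1
        degree[child] += 1
    symbols = ["C"] * n
    for i in range(1, n):
        if degree[i] == 1 and rng.random() < 0.3:
            symbols[i] = str(rng.choice(["N", "O", "F", "Cl"]))
    atoms = []
    for i, sym in enumerate(symbols):
        data = ELEMENTS[sym]
        valence = min(v for v in data.allowed_valences if v >= degree[i])
        atoms.append(Atom(i, sym, data.atomic_number, data.valence_electrons,
                          valence - degree[i]))
    return MolecularGraph(atoms, bonds, name=f"random-{n}")


def brute_force_distances(g: MolecularGraph, weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by exhaustive Floyd-Warshall relaxation.

    Independent of the implementation's Dijkstra path; pure-python triple
    loop over the dense weight matrix (inf where no edge).
    """
    n = g.n_atoms
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for b in g.bonds:
        d[b.i, b.j] = d[b.j, b.i] = min(d[b.i, b.j], weights[b.i, b.j])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d
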