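import numpy as np
import pytest

from rigidall.network import BarEdge, ConstraintNetwork
from rigidall.structure import AtomRecord, StructureModel


def make_network(n, edges):
    """Shorthand: edges as (i, j, bars) triples."""
    kind = {2: "hydrophobic", 5: "covalent_rotatable", 6: "covalent_locked"}
    return ConstraintNetwork(
        n, [BarEdge(i, j, b, kind[b]) for i, j, b in edges]
    )


def chain_network(n, bars=5):
    return make_network(n, [(i, i + 1, bars) for i in range(n - 1)])


def ring_network(n, bars=5):
    return make_network(n, [(i, (i + 1) % n, bars) for i in range(n)])


def random_framework(rng, max_bodies=8):
    """Random generic framework as ((n, edge triples), network)."""
    n = int(rng.integers(2, max_bodies + 1))
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_edges = int(rng.integers(1, len(all_pairs) + 1))
    chosen = rng.choice(len(all_pairs), size=n_edges, replace=False)
    edges = [(all_pairs[p][0], all_pairs[p][1],
              int(rng.choice([2, 5, 6]))) for p in chosen]
    return n, edges, make_network(n, edges)


def rank_oracle_dof(n, edges, rng, n_trials=3):
    """Brute-force internal DOF from the rank of the body-bar rigidity
    matrix at random generic placements (best rank over trials)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    best = 0
    for _ in range(n_trials):
        centers = rng.uniform(-10, 10, (n, 3))
        rows = []
        for i, j, bars in edges:
            for _b in range(bars):
                a = centers[i] + rng.uniform(-1, 1, 3)
                b = centers[j] + rng.uniform(-1, 1, 3)
                d = a - b
                row = np.zeros(6 * n)
                row[6 * i:6 * i + 3] = d
                row[6 * i + 3:6 * i + 6] = np.cross(a, d)
                row[6 * j:6 * j + 3] = -d
                row[6 * j + 3:6 * j + 6] = -np.cross(b, d)
                rows.append(row)
        rank = np.linalg.matrix_rank(np.array(rows)) if rows else 0
        best = max(best, rank)
    if edges:
        eu = [e[0] for e in edges]
        ev = [e[1] for e in edges]
        graph = sp.coo_matrix((np.ones(len(eu)), (eu, ev)), shape=(n, n))
        n_comp, _ = connected_components(graph, directed=False)
    else:
        n_comp = n
    return 6 * n - 6 * n_comp - best


def simple_atom(serial, name, element, xyz, res_seq=1, res_name="ALA",
                chain="A", hetero=False):
    return AtomRecord(serial=serial, name=name, element=element,
                      res_name=res_name, chain=chain, res_seq=res_seq,
                      icode="", xyz=tuple(float(x) for x in xyz),
                      is_hetero=hetero)


def tripeptide(res_names=("ALA", "ALA", "ALA")):
    """Minimal extended tripeptide backbone (N, CA, C, O per residue)."""
    from rigidall.synthetic import gen_dihedral_ensemble

    ens, _ = gen_dihedral_ensemble(1, len(res_names) + 2, seed=0)
    frame = ens.frames[0]
    atoms = []
    serial = 0
    for a in frame.atoms:
        if a.res_seq > len(res_names):
            continue
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=a.name, element=a.element,
            res_name=res_names[a.res_seq - 1], chain="A",
            res_seq=a.res_seq, icode="", xyz=a.xyz,
        ))
    return StructureModel(atoms, label="tripeptide")


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
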