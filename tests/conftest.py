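import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from azulike import datasets
from azulike.interface_analysis import AtomRecord, ComplexModel

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def candidates():
    return datasets.candidate_peptides()


@pytest.fixture(scope="session")
def references():
    return datasets.reference_peptides()


@pytest.fixture(scope="session")
def published_hpp():
    return datasets.published_hpp()


@pytest.fixture(scope="session")
def interface_table():
    return datasets.published_interface_table()


def random_complex(rng: np.random.Generator, max_atoms: int = 500) -> ComplexModel:
    """A random two-chain point cloud for oracle-equivalence checks."""
    n_rec = int(rng.integers(5, max_atoms // 2))
    n_lig = int(rng.integers(5, max_atoms // 2))
    elements = np.array(list("CNOS"))
    atoms = []
    for chain, n in (("A", n_rec), ("B", n_lig)):
        coords = rng.uniform(0, 30, size=(n, 3))
        for i in range(n):
            atoms.append(
                AtomRecord(
                    chain=chain,
                    resseq=i // 3 + 1,  # a few atoms per pseudo-residue
                    icode="",
                    resname="GLY",
                    name=f"X{i}",
                    element=str(rng.choice(elements)),
                    coord=tuple(float(v) for v in coords[i]),
                )
            )
    return ComplexModel(atoms=atoms, receptor_chain="A", ligand_chain="B")


def brute_force_interface(model: ComplexModel, cutoff: float):
    """Independent all-pairs O(n^2) contact scan (the interface oracle)."""
    rec = model.heavy_atoms(model.receptor_chain)
    lig = model.heavy_atoms(model.ligand_chain)
    pairs = set()
    if rec and lig:
        rx = np.array([a.coord for a in rec])
        lx = np.array([a.coord for a in lig])
        dist = np.sqrt(((rx[:, None, :] - lx[None, :, :]) ** 2).sum(axis=2))
        for i, j in zip(*np.nonzero(dist <= cutoff)):
            pairs.add((rec[i].atom_id, lig[j].atom_id))
    receptor = frozenset(p[0][:3] for p in pairs)
    ligand = frozenset(p[1][:3] for p in pairs)
    return receptor, ligand, frozenset(pairs)
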