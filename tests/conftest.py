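import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem


def embed3d(smiles: str, seed: int = 7) -> Chem.Mol:
    """Small molecule with one force-field-relaxed 3D conformation."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    else:
        AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    return Chem.RemoveHs(mol)


@pytest.fixture(scope="session")
def reaction_library():
    from lyscov.electrophiles import load_reaction_library
    return load_reaction_library()


@pytest.fixture(scope="session")
def toluene3d():
    return embed3d("Cc1ccccc1")


@pytest.fixture(scope="session")
def phenol3d():
    return embed3d("Oc1ccccc1")


@pytest.fixture(scope="session")
def sa_adduct(toluene3d, reaction_library):
    """Salicylaldehyde (imine) adduct of toluene, with its connection spec."""
    from lyscov.electrophiles import enumerate_analogs, make_adduct
    analogs = enumerate_analogs(
        toluene3d, [r for r in reaction_library if r.name == "salicylaldehyde"])
    analog = analogs[0]
    adduct, conn = make_adduct(analog)
    return analog, adduct, conn


@pytest.fixture(scope="session")
def ground_truth():
    """One deterministic cleft fixture with planted covalent answer."""
    from lyscov.fixtures import FixtureSpec, make_ground_truth
    return make_ground_truth(FixtureSpec(seed=100))


@pytest.fixture(scope="session")
def ground_truth_clean():
    """Same fixture without coordinate noise (exact planted geometry)."""
    from lyscov.fixtures import FixtureSpec, make_ground_truth
    return make_ground_truth(FixtureSpec(seed=100, noise=0.0))


@pytest.fixture(scope="session")
def benchmark_ground_truths():
    """All 20 paired benchmark fixtures (built once per session)."""
    from lyscov.fixtures import benchmark20, make_ground_truth
    return [make_ground_truth(spec) for spec in benchmark20()]
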