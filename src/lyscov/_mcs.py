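"""Maximum-common-substructure helpers shared by conformer generation and
the RMSD metrics.

MCS is computed with bond-order-insensitive comparison so that, e.g., a
reacted adduct whose aromatic ring picked up an exocyclic double bond still
maps onto its template.  Matching is over heavy atoms.
"""
from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import rdFMCS

MIN_MCS_ATOMS = 3


class MCSError(ValueError):
    pass


def mcs_query(mol_a: Chem.Mol, mol_b: Chem.Mol) -> Chem.Mol:
    """MCS query molecule between two molecules (CompareAny bond order)."""
    res = rdFMCS.FindMCS(
        [mol_a, mol_b],
        bondCompare=rdFMCS.BondCompare.CompareAny,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        ringMatchesRingOnly=False,
        timeout=10,
    )
    if res.numAtoms < MIN_MCS_ATOMS:
        raise MCSError(f"insufficient overlap: MCS has {res.numAtoms} atoms (<{MIN_MCS_ATOMS})")
    q = Chem.MolFromSmarts(res.smartsString)
    if q is None:
        raise MCSError("could not parse MCS SMARTS")
    return q


def all_matches(mol: Chem.Mol, query: Chem.Mol, max_matches: int = 2000):
    """All (symmetry-inclusive) embeddings of the query in the molecule."""
    return mol.GetSubstructMatches(query, uniquify=False, maxMatches=max_matches)


def canonical_ranks(mol: Chem.Mol):
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def best_match_pair(mol_a: Chem.Mol, mol_b: Chem.Mol):
    """One deterministic MCS atom mapping [(ia, ib), ...].

    Among equal-size MCS embeddings, ties are broken by the lowest sum of
    canonical atom ranks (first in a, then in b), giving an input-order
    independent result.
    """
    q = mcs_query(mol_a, mol_b)
    ra = canonical_ranks(mol_a)
    rb = canonical_ranks(mol_b)
    ma = min(all_matches(mol_a, q), key=lambda m: (sum(ra[i] for i in m), [ra[i] for i in m]))
    mb = min(all_matches(mol_b, q), key=lambda m: (sum(rb[i] for i in m), [rb[i] for i in m]))
    return list(zip(ma, mb))
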