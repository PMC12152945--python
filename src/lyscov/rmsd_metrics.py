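"""Selection-rule RMSD metrics: MCS ligand RMSD and symmetry-aware ring RMSD.

Both metrics are *in place*: the two conformations are compared in the same
(crystal) frame without re-superposition, because the design rules care about
absolute placement in the pocket, not shape similarity.  Both take molecular
symmetry into account by minimizing over equivalent atom mappings.  Heavy
atoms only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import _mcs
from .geometry import rmsd_inplace

MCSError = _mcs.MCSError


@dataclass
class RingMatch:
    """Best symmetry-aware match of a model ring onto a template-ligand ring."""
    rmsd: float
    template_ring: tuple[int, ...]   # template atom indices, cyclic order
    mapping: tuple[int, ...]         # mapping[i] = template atom matched to model ring position i
    model_ring: np.ndarray
    ligand_ring: np.ndarray


def heavy_coords(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


def _heavy_only(mol, coords):
    """Restrict a molecule + coordinate array to heavy atoms."""
    if all(a.GetAtomicNum() > 1 for a in mol.GetAtoms()):
        return mol, np.asarray(coords, dtype=float)
    idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    sub = Chem.RWMol(mol)
    for i in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() <= 1), reverse=True):
        sub.RemoveAtom(i)
    return sub.GetMol(), np.asarray(coords, dtype=float)[idx]


def mcs_rmsd(mol_a: Chem.Mol, coords_a: np.ndarray,
             mol_b: Chem.Mol, coords_b: np.ndarray) -> float:
    """In-place RMSD over the MCS of two molecules, minimized over all
    symmetry-equivalent MCS embeddings.

    Raises MCSError when the MCS is smaller than 3 atoms.
    """
    mol_a, coords_a = _heavy_only(mol_a, coords_a)
    mol_b, coords_b = _heavy_only(mol_b, coords_b)
    q = _mcs.mcs_query(mol_a, mol_b)
    matches_a = _mcs.all_matches(mol_a, q)
    matches_b = _mcs.all_matches(mol_b, q)
    if not matches_a or not matches_b:
        raise MCSError("MCS query does not embed in both molecules")
    # distinct images in a (embeddings with the same image differ by a query
    # automorphism, which is already covered by iterating all matches in b)
    images = {}
    for m in matches_a:
        images.setdefault(frozenset(m), m)
    best = np.inf
    for ma in images.values():
        xa = coords_a[list(ma)]
        for mb in matches_b:
            val = rmsd_inplace(xa, coords_b[list(mb)])
            if val < best:
                best = val
    return float(best)


def _cycle_mappings(n: int):
    """The 2n dihedral-group index mappings of an n-cycle."""
    for s in range(n):
        yield [(s + i) % n for i in range(n)]
        yield [(s - i) % n for i in range(n)]


def ring_mappings(model_elements, template_elements):
    """Adjacency- and element-preserving mappings between two rings given as
    cyclically ordered element lists.  Returns position-index mappings."""
    n = len(model_elements)
    out = []
    for perm in _cycle_mappings(n):
        if all(model_elements[i] == template_elements[perm[i]] for i in range(n)):
            out.append(perm)
    return out


def template_rings(template: Chem.Mol, ring_size: int):
    """Rings of the requested size in the template, as cyclically ordered
    atom-index tuples (heavy atoms; RDKit ring perception)."""
    ri = template.GetRingInfo()
    return [r for r in ri.AtomRings() if len(r) == ring_size]


def ring_rmsd(model_ring_coords: np.ndarray, model_ring_elements: list[str],
              template: Chem.Mol, template_coords: np.ndarray,
              ring_size: int | None = None) -> RingMatch:
    """Minimum in-place RMSD between a model ring and every similar ring of the
    template ligand, over all adjacency-preserving index permutations.

    ``model_ring_coords`` must be in cyclic (bonded) order.  A template ring is
    "similar" when it has the same size and the same multiset of elements;
    aromaticity is not required to match.  Raises ValueError when the template
    has no similar ring.
    """
    model_ring_coords = np.asarray(model_ring_coords, dtype=float)
    n = len(model_ring_coords)
    if ring_size is None:
        ring_size = n
    rings = template_rings(template, ring_size)
    if not rings:
        raise ValueError(f"no ring of size {ring_size} in template")
    model_elements = [e.upper() for e in model_ring_elements]
    best: RingMatch | None = None
    for ring in rings:
        t_elems = [template.GetAtomWithIdx(i).GetSymbol().upper() for i in ring]
        if sorted(t_elems) != sorted(model_elements):
            continue
        t_xyz = np.asarray(template_coords, dtype=float)[list(ring)]
        for perm in ring_mappings(model_elements, t_elems):
            val = rmsd_inplace(model_ring_coords, t_xyz[perm])
            if best is None or val < best.rmsd:
                best = RingMatch(
                    rmsd=float(val),
                    template_ring=tuple(ring),
                    mapping=tuple(ring[p] for p in perm),
                    model_ring=model_ring_coords,
                    ligand_ring=t_xyz[perm],
                )
    if best is None:
        raise ValueError("no similar ring (element composition mismatch)")
    return best
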