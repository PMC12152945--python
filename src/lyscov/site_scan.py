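"""Candidate-site mining: lysine-ligand pairs eligible for covalent design.

Finds every (lysine, ligand) pair with a ligand atom within a cutoff of the
lysine NZ, flags pairs that are already covalent (LINK record to that NZ),
drops small ligands (ions/solvent), clusters redundant entries by receptor
sequence identity and ligand fingerprint similarity, and applies the
benchmark-set construction filters (terminal warhead, single LINK, regular
bond length).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from rdkit import Chem
from rdkit.Chem import DataStructs

from .structures import LINK_REGULAR_RANGE, ProteinLigandComplex

NZ_CUTOFF = 8.0
MIN_LIGAND_ATOMS = 10
SEQ_IDENTITY = 0.90
FP_CUTOFF = 0.6

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class LysineLigandPair:
    """One candidate design site from structure scanning."""
    receptor: str
    lysine: tuple[str, int]              # (chain, resnum)
    ligand_id: str                       # 3-letter code + instance
    min_nz_distance: float
    aromatic_eligible: bool = False      # aromatic ligand atom within cutoff
    already_covalent: bool = False       # LINK to this NZ
    ligand_heavy_atoms: int = 0
    sequence: str = ""                   # receptor sequence (for clustering)
    ligand_mol: Chem.Mol | None = None
    resolution: float = 99.0


def _aromatic_indices(mol: Chem.Mol | None) -> set[int]:
    if mol is None:
        return set()
    return {a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()}


def scan_structure(cplx: ProteinLigandComplex, cutoff: float = NZ_CUTOFF,
                   receptor: str = "", ligand_mol: Chem.Mol | None = None,
                   phenyl_only: bool = False) -> list[LysineLigandPair]:
    """One pair per (lysine, ligand) with any ligand atom within ``cutoff`` of
    the lysine NZ.  Ligands under 10 heavy atoms are dropped.  Aromaticity is
    perceived from the ligand sidecar chemistry (``ligand_mol``), never from
    atom naming; ``phenyl_only`` restricts eligibility to six-membered
    aromatic carbocycles.
    """
    aromatic = _aromatic_indices(ligand_mol)
    if phenyl_only and ligand_mol is not None:
        aromatic = {i for ring in ligand_mol.GetRingInfo().AtomRings()
                    if len(ring) == 6
                    and all(ligand_mol.GetAtomWithIdx(j).GetIsAromatic()
                            and ligand_mol.GetAtomWithIdx(j).GetSymbol() == "C"
                            for j in ring)
                    for i in ring}
    pairs: list[LysineLigandPair] = []
    for ligand in cplx.ligands:
        lig_xyz = ligand.coords()
        heavy = sum(1 for a in ligand.atoms if a.element != "H")
        if heavy < MIN_LIGAND_ATOMS:
            continue
        for chain in cplx.chains:
            for res in chain.residues:
                if res.name != "LYS" or not res.has_atom("NZ"):
                    continue
                nz = res.atom("NZ").pos
                d = np.linalg.norm(lig_xyz - nz, axis=1)
                if d.min() > cutoff:
                    continue
                covalent = any(
                    {(link.a.chain_id, link.a.seqid, link.a.atom_name),
                     (link.b.chain_id, link.b.seqid, link.b.atom_name)} &
                    {(chain.id, res.seqid, "NZ")}
                    and (link.a.res_name == ligand.name or link.b.res_name == ligand.name)
                    for link in cplx.link_records)
                arom_ok = bool(aromatic) and bool(
                    np.any(d[sorted(i for i in aromatic if i < len(d))] <= cutoff))
                pairs.append(LysineLigandPair(
                    receptor=receptor,
                    lysine=(chain.id, res.seqid),
                    ligand_id=f"{ligand.name}:{ligand.chain_id}{ligand.seqid}",
                    min_nz_distance=float(d.min()),
                    aromatic_eligible=arom_ok,
                    already_covalent=covalent,
                    ligand_heavy_atoms=heavy,
                    sequence=_chain_sequence(chain),
                    ligand_mol=ligand_mol,
                ))
    return pairs


def _chain_sequence(chain) -> str:
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in chain.residues)


def design_candidates(pairs: list[LysineLigandPair]) -> list[LysineLigandPair]:
    """Pairs eligible as design inputs: not already covalently bound."""
    return [p for p in pairs if not p.already_covalent]


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity over the aligned length."""
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aln = aligner.align(a, b)[0]
    ta, tb = aln[0], aln[1]
    matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    length = max(len(ta), 1)
    return matches / length


def fingerprint_similarity(mol_a: Chem.Mol, mol_b: Chem.Mol) -> float:
    """Topological (RDKit) fingerprint Tanimoto similarity."""
    fa = Chem.RDKFingerprint(mol_a)
    fb = Chem.RDKFingerprint(mol_b)
    return DataStructs.FingerprintSimilarity(fa, fb)


def cluster_pairs(pairs: list[LysineLigandPair],
                  seq_identity: float = SEQ_IDENTITY,
                  fp_cutoff: float = FP_CUTOFF) -> list[LysineLigandPair]:
    """Greedy single-linkage clustering: first on receptor sequence identity,
    then on ligand fingerprint similarity within each sequence cluster.  One
    representative per cluster, chosen deterministically (best resolution,
    then lexical ids)."""
    if not pairs:
        return []
    n = len(pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(pairs[i].sequence, pairs[j].sequence) >= seq_identity:
                sim = 1.0
                if pairs[i].ligand_mol is not None and pairs[j].ligand_mol is not None:
                    sim = fingerprint_similarity(pairs[i].ligand_mol, pairs[j].ligand_mol)
                if sim >= fp_cutoff:
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    reps = []
    for members in clusters.values():
        members.sort(key=lambda i: (pairs[i].resolution, pairs[i].receptor,
                                    pairs[i].ligand_id, pairs[i].lysine))
        reps.append(pairs[members[0]])
    reps.sort(key=lambda p: (p.receptor, p.ligand_id, p.lysine))
    return reps


@dataclass
class CovalentRecord:
    """A covalent-complex record as mined from a structure database."""
    record_id: str
    ligand_mol: Chem.Mol
    link_atom_idx: int                   # ligand atom bonded to the protein
    n_links: int = 1
    bond_length: float = 1.4


def _is_terminal_warhead(mol: Chem.Mol, link_idx: int) -> bool:
    """The linking atom must carry at most one single-bonded heavy neighbor
    within the ligand (double-bonded O/N count as part of the warhead unit)."""
    atom = mol.GetAtomWithIdx(link_idx)
    single_heavy = 0
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() <= 1:
            continue
        if bond.GetBondType() == Chem.BondType.DOUBLE and other.GetSymbol() in ("O", "N"):
            continue
        single_heavy += 1
    return single_heavy <= 1


def filter_covpdb_style(records: list[CovalentRecord]) -> list[CovalentRecord]:
    """Benchmark-set construction filters: terminal unsubstituted warhead,
    exactly one LINK record, covalent bond length within the regular window."""
    lo, hi = LINK_REGULAR_RANGE
    out = []
    for rec in records:
        if rec.n_links != 1:
            continue
        if not (lo <= rec.bond_length <= hi):
            continue
        if not _is_terminal_warhead(rec.ligand_mol, rec.link_atom_idx):
            continue
        out.append(rec)
    return out
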