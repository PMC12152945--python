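"""Conformer libraries for covalent adducts.

For each adduct we build up to ``n_constrained`` conformers whose maximum
common substructure (MCS) with the template ligand is restrained to the
crystallographic template coordinates, plus up to ``n_free`` unconstrained
conformers.  Every conformer is force-field minimized (UFF), energy-filtered
against the minimized template energy (+100 units), aligned onto the template
over the MCS, and deduplicated at 0.5 A in-place RMSD in generation order
(constrained first, then free).

The virtual-site nitrogen marking the lysine attachment point is excluded
from the dedup RMSD; it is a real nitrogen of the reacted adduct and is kept
in the force-field energy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign

from . import _mcs
from .geometry import rmsd_inplace
from .rmsd_metrics import heavy_coords

ENERGY_WINDOW = 100.0   # conformers above template energy + window are discarded
DEDUP_RMSD = 0.5        # A; minimum in-place RMSD between retained conformers

MCSError = _mcs.MCSError


class ConformerError(RuntimeError):
    pass


@dataclass
class ConformerSet:
    adduct: Chem.Mol
    template: Chem.Mol
    conformers: list[np.ndarray] = field(default_factory=list)   # heavy-atom coords
    provenance: list[str] = field(default_factory=list)          # "constrained" | "free"
    energies: list[float] = field(default_factory=list)
    mcs_map: list[tuple[int, int]] = field(default_factory=list)  # (adduct idx, template idx)
    template_energy: float = 0.0

    def __len__(self) -> int:
        return len(self.conformers)


def mcs_match(adduct: Chem.Mol, template: Chem.Mol) -> list[tuple[int, int]]:
    """Deterministic MCS atom mapping between adduct and template
    (bond-order-insensitive).  Raises MCSError below 3 atoms."""
    return _mcs.best_match_pair(adduct, template)


def _uff_energy(molh: Chem.Mol, conf_id: int) -> float:
    ff = AllChem.UFFGetMoleculeForceField(molh, confId=conf_id)
    return ff.CalcEnergy()


def minimized_template_energy(template: Chem.Mol) -> float:
    """UFF energy of the template ligand after minimization (the reference for
    the conformer energy filter)."""
    molh = Chem.AddHs(Chem.Mol(template), addCoords=True)
    AllChem.UFFOptimizeMolecule(molh, maxIters=500)
    return _uff_energy(molh, 0)


def greedy_dedup(coords: list[np.ndarray], min_rmsd: float = DEDUP_RMSD,
                 mask: np.ndarray | None = None) -> list[int]:
    """Greedy prefix filter: keep a conformer iff its in-place RMSD (over
    ``mask`` atoms) to every previously kept conformer exceeds ``min_rmsd``.
    Returns kept indices in input order."""
    kept: list[int] = []
    for i, xyz in enumerate(coords):
        a = xyz if mask is None else xyz[mask]
        ok = True
        for j in kept:
            b = coords[j] if mask is None else coords[j][mask]
            if rmsd_inplace(a, b) <= min_rmsd:
                ok = False
                break
        if ok:
            kept.append(i)
    return kept


def generate_conformers(adduct: Chem.Mol, template: Chem.Mol,
                        n_free: int = 100, n_constrained: int = 100,
                        seed: int = 1) -> ConformerSet:
    """Build the filtered, template-aligned conformer set for an adduct.

    ``template`` must carry one 3D conformation (the crystallographic pose).
    Raises ConformerError when no conformer survives the filters.
    """
    if template.GetNumConformers() == 0:
        raise ConformerError("template has no 3D conformation")
    pairs = mcs_match(adduct, template)
    tmpl_xyz = heavy_coords(template)
    tmpl_energy = minimized_template_energy(template)

    # the MCS embedding into the template is ambiguous under template
    # symmetry; align each conformer under every symmetry image (deduped
    # later) so no covalent-geometry-compatible placement is lost
    q = _mcs.mcs_query(adduct, template)
    ma0 = [ai for ai, _ in pairs]
    sym_maps = []
    for mb in _mcs.all_matches(template, q, max_matches=200)[:8]:
        sym_maps.append(list(zip(ma0, mb)))
    if not sym_maps:
        sym_maps = [pairs]

    n_heavy = adduct.GetNumAtoms()
    nz_idx = adduct.GetIntProp("nz_idx") if adduct.HasProp("nz_idx") else None
    molh = Chem.AddHs(Chem.Mol(adduct))

    candidates: list[tuple[str, np.ndarray, float]] = []

    def embed(n: int, constrained: bool, seed_offset: int):
        if n <= 0:
            return
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + seed_offset
        params.numThreads = 1
        params.clearConfs = True
        work = Chem.Mol(molh)
        if constrained:
            cmap = {ai: Chem.rdGeometry.Point3D(*tmpl_xyz[ti]) for ai, ti in pairs}
            cids = AllChem.EmbedMultipleConfs(work, numConfs=n, coordMap=cmap,
                                              randomSeed=seed + seed_offset,
                                              numThreads=1, clearConfs=True)
        else:
            cids = AllChem.EmbedMultipleConfs(work, numConfs=n, params=params)
        for cid in cids:
            try:
                ff = AllChem.UFFGetMoleculeForceField(work, confId=cid)
                ff.Minimize(maxIts=500)
                energy = ff.CalcEnergy()
            except Exception:
                continue
            for amap in sym_maps:
                rdMolAlign.AlignMol(work, template, prbCid=cid,
                                    atomMap=[(int(ai), int(ti)) for ai, ti in amap])
                conf = work.GetConformer(cid)
                xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(n_heavy)])
                candidates.append(("constrained" if constrained else "free", xyz, energy))

    embed(n_constrained, constrained=True, seed_offset=0)
    embed(n_free, constrained=False, seed_offset=7919)

    mask = None
    if nz_idx is not None:
        mask = np.array([i for i in range(n_heavy) if i != nz_idx])
    retained = apply_filters(candidates, tmpl_energy, mask)
    if not retained:
        raise ConformerError("no valid conformers")
    cs = ConformerSet(adduct=adduct, template=template, mcs_map=pairs,
                      template_energy=tmpl_energy)
    for p, x, e in retained:
        cs.provenance.append(p)
        cs.conformers.append(x)
        cs.energies.append(e)
    return cs


def apply_filters(candidates: list[tuple[str, np.ndarray, float]],
                  template_energy: float,
                  mask: np.ndarray | None = None
                  ) -> list[tuple[str, np.ndarray, float]]:
    """Energy window then greedy 0.5 A dedup, in generation order.

    ``candidates`` are (provenance, heavy-atom coords, energy) triples; the
    virtual-site atom is excluded from the dedup RMSD via ``mask``.
    """
    surviving = [c for c in candidates if c[2] <= template_energy + ENERGY_WINDOW]
    kept = greedy_dedup([x for _, x, _ in surviving], DEDUP_RMSD, mask)
    return [surviving[i] for i in kept]


def write_conformers_sdf(cs: ConformerSet, path: str) -> None:
    """Multi-conformer SDF with per-conformer energy and provenance tags."""
    writer = Chem.SDWriter(path)
    mol = Chem.Mol(cs.adduct)
    mol.RemoveAllConformers()
    for i, xyz in enumerate(cs.conformers):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for j, p in enumerate(xyz):
            conf.SetAtomPosition(j, Chem.rdGeometry.Point3D(*p))
        m = Chem.Mol(mol)
        m.AddConformer(conf, assignId=True)
        m.SetProp("provenance", cs.provenance[i])
        m.SetDoubleProp("uff_energy", cs.energies[i])
        writer.write(m)
    writer.close()
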