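"""Synthetic benchmark fixtures: geometric peptide pockets with a planted,
ground-truth covalent lysine-ligand adduct.

Construction works backwards from the answer: a modified-lysine rotamer is
drawn from the rotamer library, its warhead ring defines the crystallographic
pose of the planted aromatic ligand, and wall strands are arranged around the
ring to form the requested pocket shape.  The emitted complex carries the
*stripped* noncovalent ligand and an apo lysine rotamer (the protocol input);
the true analog and its covalent pose are returned as the answer key.

Pockets are geometric poly-Ala/Gly arrangements, not folded proteins: every
quantity the protocols measure (distances, clashes, RMSD, ranking) depends
only on local geometry.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .conformers import generate_conformers
from .electrophiles import (CovalentAnalog, enumerate_analogs,
                            load_reaction_library, make_adduct)
from .geometry import kabsch
from .lysine_rotamers import (DEFAULT_CHI_LIBRARY, ModifiedResidueTemplate,
                              build_coordinates, build_template)
from .residues import add_cb, build_sidechain, build_strand
from .structures import (Atom, Chain, ProteinLigandComplex, Residue,
                         StructureError)

WALL_OFFSET = 5.0          # A between the ring plane and each cleft wall sheet
WALL_CLEARANCE = 3.4       # minimum wall distance to ligand/lysine atoms
MAX_WALL_PUSH = 3.6
COLLAR_RADIUS = 5.4        # A from ring centroid to rim blocker centroids


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 1
    pocket_shape: str = "cleft"           # open | cleft | walled
    planted_ligand: str = "Cc1ccccc1"     # SMILES of the noncovalent template
    planted_warhead: str = "salicylaldehyde"
    noise: float = 0.15                   # coordinate jitter sigma, A
    lysine_chis: tuple[float, ...] | None = None


@dataclass
class GroundTruth:
    """A paired (protocol input, protocol answer) fixture."""
    spec: FixtureSpec
    complex: ProteinLigandComplex         # noncovalent input (stripped ligand, apo lysine)
    template_mol: Chem.Mol                # ligand chemistry with the planted 3D pose
    analog: CovalentAnalog                # the true electrophilic analog
    adduct: Chem.Mol
    connection: object
    true_pose: np.ndarray                 # adduct heavy-atom coords, ideal covalent geometry
    planted_chis: tuple[float, ...]
    planted_proton_chis: tuple[float, ...]
    apo_chis: tuple[float, ...]
    planted_position: int                 # template-ligand atom index bearing the warhead
    planted_ring: tuple[int, ...]         # template-ligand ring atom indices
    mod_template: ModifiedResidueTemplate


def _strand_chain(chain_id: str, n_res: int, seq_start: int = 1,
                  lys_at: int | None = None) -> Chain:
    """Ideal extended strand as a Chain of ALA (with a LYS at ``lys_at``)."""
    bbs = build_strand(n_res)
    chain = Chain(chain_id)
    for i, bb in enumerate(bbs):
        name = "LYS" if i == lys_at else "ALA"
        res = Residue(name, seq_start + i, chain_id)
        for aname in ("N", "CA", "C", "O"):
            res.atoms.append(Atom(aname, aname[0], bb[aname].copy()))
        res.atoms.append(Atom("CB", "C", add_cb(bb)))
        chain.residues.append(res)
    return chain


def _chain_coords(chain: Chain) -> np.ndarray:
    return chain.coords()


def _embed_ligand(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FixtureError(f"bad ligand SMILES: {smiles}")
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=seed) != 0:
        raise FixtureError("ligand embedding failed")
    if AllChem.MMFFHasAllMoleculeParams(molh):
        AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    else:
        AllChem.UFFOptimizeMolecule(molh, maxIters=500)
    return Chem.RemoveHs(molh)


def _ring_cyclic_order(mol: Chem.Mol, ring: tuple[int, ...]) -> list[int]:
    return list(ring)  # RDKit AtomRings are already in bonded cyclic order


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.min(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2))))


def _place_strand(chain_id: str, n_res: int, direction: np.ndarray,
                  up: np.ndarray, center: np.ndarray) -> Chain:
    """Strand along ``direction`` with its atom centroid at ``center``."""
    chain = _strand_chain(chain_id, n_res)
    xyz = _chain_coords(chain)
    a1 = direction / np.linalg.norm(direction)
    a3 = up - np.dot(up, a1) * a1
    a3 /= np.linalg.norm(a3)
    a2 = np.cross(a3, a1)
    R = np.column_stack([a1, a2, a3])
    centroid = xyz.mean(axis=0)
    for res in chain.residues:
        for atom in res.atoms:
            atom.pos = R @ (atom.pos - centroid) + center
    return chain


def make_ground_truth(spec: FixtureSpec) -> GroundTruth:
    """Build the paired fixture; deterministic per spec/seed."""
    rng = np.random.default_rng(spec.seed)
    reactions = [r for r in load_reaction_library() if r.name == spec.planted_warhead]
    if not reactions:
        raise FixtureError(f"warhead not applicable: {spec.planted_warhead!r}")
    mod_template = build_template(spec.planted_warhead)
    lig_mol = _embed_ligand(spec.planted_ligand, int(rng.integers(1, 2 ** 30)))
    analogs = enumerate_analogs(lig_mol, reactions)
    if not analogs:
        raise FixtureError("warhead not applicable: no analog of the planted ligand")
    # prefer analogs that keep the ligand's substituents (so that native polar
    # contacts survive warhead installation), and require a mappable ring
    keep = [a for a in analogs if not a.removed] or analogs
    keep = [(a, _ring_order(lig_mol, a)) for a in keep]
    keep = [(a, o) for a, o in keep if o is not None]
    if not keep:
        raise FixtureError("warhead not applicable: no mappable ring site")
    analog, ring_order = keep[int(rng.integers(len(keep)))]
    position = analog.site_ordered[0]
    adduct, connection = make_adduct(analog)
    conf_set = generate_conformers(adduct, lig_mol, seed=1)
    # the planted warhead-to-ring torsion must be one the adduct's conformer
    # library can realize (force fields keep conjugated linkers near-planar,
    # which an arbitrary grid value would violate)
    aryl_torsions = _accessible_aryl_torsions(adduct, analog, ring_order, conf_set)

    chain_a = _strand_chain("A", 7, lys_at=3)
    lys = chain_a.residue(4)
    backbone = {n: lys.atom(n).pos for n in ("N", "CA", "C")}
    chain_a_xyz = _chain_coords(chain_a)
    # clash reference for the side chain: everything but the lysine itself
    other_xyz = np.concatenate([r.coords() for r in chain_a.residues if r.seqid != 4])

    chi_states = [[s[0] for s in states] for states in DEFAULT_CHI_LIBRARY]
    last_error = "no feasible rotamer"
    for attempt in range(200):
        if spec.lysine_chis is not None and attempt == 0:
            chis = tuple(spec.lysine_chis)
        else:
            chis = (float(rng.choice(chi_states[0][:2])),
                    float(rng.choice(chi_states[1])),
                    float(rng.choice(chi_states[2])),
                    float(rng.choice(chi_states[3])))
        pchis = list(float(g[rng.integers(len(g))]) for g in mod_template.proton_chis)
        # the aryl torsion (last proton chi) comes from the conformer library
        pchis[-1] = float(aryl_torsions[rng.integers(len(aryl_torsions))])
        pchis = tuple(pchis)
        mod_coords = build_coordinates(mod_template, backbone, chis, pchis)
        # the modified side chain must clear its own strand
        sc_names = [n for n in mod_coords if n not in ("CB",)]
        sc_xyz = np.array([mod_coords[n] for n in sc_names])
        if _min_dist(sc_xyz, other_xyz) < 2.9:
            last_error = "modified side chain clashes with its strand"
            continue

        lig_xyz = _plant_ligand(lig_mol, ring_order, mod_coords)
        if _min_dist(lig_xyz, other_xyz) < 2.9:
            last_error = "planted ligand clashes with the lysine strand"
            continue

        apo = _pick_apo_chis(backbone, chis, chi_states, lig_xyz, other_xyz, rng)
        if apo is None:
            last_error = "no apo rotamer with NZ 4-8 A from the ligand"
            continue

        ring_xyz = np.array([mod_coords[n] for n in mod_template.ring_atoms])
        try:
            walls = _build_walls(spec, ring_xyz, mod_coords, lig_xyz,
                                 np.vstack([chain_a_xyz, sc_xyz]))
        except FixtureError as exc:
            last_error = str(exc)
            continue
        break
    else:
        raise FixtureError(f"infeasible spec: {last_error}")

    # apo lysine side chain into the emitted complex
    sc = build_sidechain(backbone, list(apo))
    for name, pos in sc.items():
        lys.atoms.append(Atom(name, "N" if name.startswith("N") else "C", pos.copy()))

    ligand_res = _ligand_residue(lig_mol, lig_xyz)

    wall_xyz = [c.coords() for c in walls]
    avoid = np.vstack([chain_a_xyz, sc_xyz, lig_xyz] + wall_xyz)
    anchor = _build_anchor(lig_mol, lig_xyz, np.vstack([chain_a_xyz, sc_xyz] + wall_xyz))
    if anchor is not None:
        walls = walls + [anchor]
        avoid = np.vstack([avoid, anchor.coords()])
    wh_anchor = _build_warhead_anchor(mod_coords, spec.planted_warhead, avoid)
    if wh_anchor is not None:
        walls = walls + [wh_anchor]
        avoid = np.vstack([avoid, wh_anchor.coords()])
    ring_xyz = np.array([mod_coords[n] for n in mod_template.ring_atoms])
    rc, nv, a1, a2 = _ring_frame(ring_xyz, mod_coords)
    collar = _build_collar(rc, nv, a1, a2, mod_coords, lig_xyz, avoid)
    if collar is not None:
        walls = walls + [collar]
        avoid = np.vstack([avoid, collar.coords()])
    if spec.pocket_shape == "walled":
        walls = walls + _build_caps(spec, ring_xyz, mod_coords, lig_xyz, avoid)

    cplx = ProteinLigandComplex(
        chains=[chain_a] + walls,
        ligands=[ligand_res],
        link_records=[],
        target_lysine=("A", 4),
    )

    true_pose = _true_adduct_pose(adduct, analog, lig_xyz, mod_coords, mod_template)

    template_mol = Chem.Mol(lig_mol)
    conf = template_mol.GetConformer()
    for i, p in enumerate(lig_xyz):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))

    if spec.noise > 0:
        _apply_noise(cplx, rng, spec.noise)

    cplx.validate()
    return GroundTruth(
        spec=spec, complex=cplx, template_mol=template_mol, analog=analog,
        adduct=adduct, connection=connection, true_pose=true_pose,
        planted_chis=chis, planted_proton_chis=pchis, apo_chis=apo,
        planted_position=position, planted_ring=tuple(ring_order),
        mod_template=mod_template,
    )


def _accessible_aryl_torsions(adduct: Chem.Mol, analog: CovalentAnalog,
                              ring_order: list[int], conf_set) -> list[float]:
    """Warhead-to-ring torsion values realized by the adduct conformer
    library, measured as dih(N-zeta, link, C1, C2) per conformer."""
    ce = analog.ce_idx

    def shift(i: int) -> int:
        return i - 1 if i > ce else i

    inv_parent = {t: shift(a) for a, t in analog.parent_map.items() if a != ce}
    nz = adduct.GetIntProp("nz_idx")
    link = adduct.GetIntProp("link_idx")
    c1 = inv_parent[ring_order[0]]
    c2 = inv_parent[ring_order[1]]
    from .geometry import dihedral_angle
    vals = sorted({round(dihedral_angle(x[nz], x[link], x[c1], x[c2]), 1)
                   for x in conf_set.conformers})
    return [float(v) for v in vals]


def _ring_order(lig_mol: Chem.Mol, analog: CovalentAnalog):
    """Cyclic order of the derivatized ligand ring starting at the warhead
    position (second site atom next, for two-point warheads)."""
    site = analog.site_ordered
    rings = [r for r in lig_mol.GetRingInfo().AtomRings()
             if len(r) == 6 and site[0] in r]
    if not rings:
        return None
    ring = _ring_cyclic_order(lig_mol, rings[0])
    k = ring.index(site[0])
    order_fwd = [ring[(k + i) % 6] for i in range(6)]
    order_rev = [ring[(k - i) % 6] for i in range(6)]
    if len(site) > 1 and site[1] in ring:
        order = order_fwd if order_fwd[1] == site[1] else order_rev
        if order[1] != site[1]:
            return None
    else:
        order = order_fwd
    return order


def _plant_ligand(lig_mol: Chem.Mol, order: list[int],
                  mod_coords: dict[str, np.ndarray]):
    """Pose the template ligand so that its derivatized ring coincides with
    the modified-residue ring (warhead site onto C1 etc.)."""
    conf = lig_mol.GetConformer()
    lig_xyz = np.array([list(conf.GetAtomPosition(i))
                        for i in range(lig_mol.GetNumAtoms())])
    target = np.array([mod_coords[n] for n in ("C1", "C2", "C3", "C4", "C5", "C6")])
    R, t = kabsch(lig_xyz[order], target)
    return lig_xyz @ R.T + t


def _pick_apo_chis(backbone, planted, chi_states, lig_xyz, chain_a_xyz, rng):
    """An apo lysine rotamer: NZ 4-8 A from the ligand, no clashes."""
    candidates = []
    for d2 in [planted[1]] + [d for d in chi_states[1] if d != planted[1]]:
        for d4 in chi_states[3]:
            for d3 in chi_states[2]:
                if (d2, d3, d4) != tuple(planted[1:]):
                    candidates.append((planted[0], d2, d3, d4))
    candidates.append((planted[0], planted[1], planted[2], planted[3] + 120.0))
    for cand in candidates:
        sc = build_sidechain(backbone, list(cand))
        xyz = np.array(list(sc.values()))
        nz = sc["NZ"]
        d_lig = float(np.min(np.linalg.norm(lig_xyz - nz, axis=1)))
        if not (4.0 <= d_lig <= 8.0):
            continue
        if _min_dist(xyz[1:], chain_a_xyz) < 2.9:   # skip CB (bonded geometry)
            continue
        if _min_dist(xyz, lig_xyz) < 3.2:
            continue
        return tuple(float(c) for c in cand)
    return None


def _ligand_residue(lig_mol: Chem.Mol, lig_xyz: np.ndarray) -> Residue:
    res = Residue("LIG", 1, "X")
    counts: dict[str, int] = {}
    for i, atom in enumerate(lig_mol.GetAtoms()):
        sym = atom.GetSymbol().upper()
        counts[sym] = counts.get(sym, 0) + 1
        res.atoms.append(Atom(f"{sym}{counts[sym]}", sym, lig_xyz[i].copy()))
    return res


def _ring_frame(ring_xyz: np.ndarray, mod_coords: dict[str, np.ndarray]):
    """Local frame of the planted ring: centroid, normal, outward in-plane
    direction (from the lysine attachment toward the ring) and its
    perpendicular."""
    rc = ring_xyz.mean(axis=0)
    nv = np.cross(ring_xyz[1] - ring_xyz[0], ring_xyz[2] - ring_xyz[0])
    nv /= np.linalg.norm(nv)
    outward = rc - mod_coords["CE"]
    outward -= np.dot(outward, nv) * nv
    a1 = outward / np.linalg.norm(outward)
    a2 = np.cross(nv, a1)
    return rc, nv, a1, a2


def _build_walls(spec: FixtureSpec, ring_xyz: np.ndarray,
                 mod_coords: dict[str, np.ndarray], lig_xyz: np.ndarray,
                 protected: np.ndarray) -> list[Chain]:
    """Wall strands around the planted ring, per pocket shape.

    Cleft/walled: two 2-strand sheets parallel to the ring plane on both
    faces plus a rim collar.  Open: a single floor strand and the collar.
    A wall that cannot clear the protein after pushing outward is dropped.
    Side caps for walled pockets are added separately, after the anchors.
    """
    rc, nv, a1, a2 = _ring_frame(ring_xyz, mod_coords)

    protected_all = np.vstack([protected, lig_xyz])
    # (center, push direction, max push)
    placements: list[tuple[np.ndarray, np.ndarray, float]] = []
    if spec.pocket_shape in ("cleft", "walled"):
        for s in (1.0, -1.0):
            for l in (1.0, -1.0):
                placements.append((rc + s * WALL_OFFSET * nv + l * 1.8 * a2
                                   + 0.8 * a1, s * nv, 3.2))
    elif spec.pocket_shape == "open":
        placements.append((rc - WALL_OFFSET * nv, -nv, MAX_WALL_PUSH))
    else:
        raise FixtureError(f"unknown pocket shape {spec.pocket_shape!r}")

    chains: list[Chain] = []
    chain_ids = itertools.cycle("BCDEFGH")
    n_placed_plane = 0
    for k, (center, push, max_push) in enumerate(placements):
        cid = next(chain_ids)
        placed = None
        for extra in np.arange(0.0, max_push + 0.01, 0.4):
            chain = _place_strand(cid, 3, a1, push, center + extra * push)
            if _min_dist(_chain_coords(chain), protected_all) >= WALL_CLEARANCE:
                placed = chain
                break
        if placed is None:
            continue
        protected_all = np.vstack([protected_all, _chain_coords(placed)])
        chains.append(placed)
        if spec.pocket_shape in ("cleft", "walled"):
            n_placed_plane += 1
    if spec.pocket_shape in ("cleft", "walled") and n_placed_plane < 1:
        raise FixtureError("could not form the requested pocket shape")
    return chains


def _build_caps(spec: FixtureSpec, ring_xyz: np.ndarray,
                mod_coords: dict[str, np.ndarray], lig_xyz: np.ndarray,
                avoid: np.ndarray) -> list[Chain]:
    """Side caps closing a walled pocket; error when the ligand itself blocks
    every cap position (oversized ligand)."""
    rc, nv, a1, a2 = _ring_frame(ring_xyz, mod_coords)
    chains: list[Chain] = []
    for cid, sgn in (("G", 1.0), ("H", -1.0)):
        placed = None
        for extra in np.arange(0.0, 8.01, 0.4):
            chain = _place_strand(cid, 3, a1, sgn * a2,
                                  rc + (5.6 + extra) * sgn * a2)
            if _min_dist(_chain_coords(chain), avoid) >= WALL_CLEARANCE:
                placed = chain
                break
        if placed is None:
            if _min_dist(_chain_coords(chain), lig_xyz) < WALL_CLEARANCE:
                raise FixtureError("infeasible spec: ligand overlaps wall")
            continue
        avoid = np.vstack([avoid, _chain_coords(placed)])
        chains.append(placed)
    return chains


def _place_anchor(chain_id: str, target: np.ndarray, direction: np.ndarray,
                  partner_atom: str, avoid: np.ndarray) -> Chain | None:
    """A single glycine whose ``partner_atom`` ('O' for an acceptor carbonyl,
    'N' for a donor amide) sits at ``target`` with its bond axis along
    ``-direction`` (hydrogen-bond-competent geometry)."""
    from .geometry import rotation_matrix
    d = direction / np.linalg.norm(direction)
    chain = _strand_chain(chain_id, 1)
    res = chain.residues[0]
    res.atoms = [a for a in res.atoms if a.name != "CB"]   # glycine
    res.name = "GLY"
    parent = {"O": "C", "N": "CA"}[partner_atom]
    p_pos = res.atom(partner_atom).pos
    v = p_pos - res.atom(parent).pos
    v /= np.linalg.norm(v)
    axis = np.cross(v, -d)
    ang = np.degrees(np.arccos(np.clip(np.dot(v, -d), -1, 1)))
    R0 = rotation_matrix(axis, ang) if np.linalg.norm(axis) > 1e-8 else np.eye(3)
    for min_clear in (3.2, 3.0):
        for stretch in (0.0, 0.2, -0.2):
            for roll in (0.0, 60.0, 120.0, 180.0, 240.0, 300.0):
                R = rotation_matrix(-d, roll) @ R0
                t = target + stretch * d - R @ p_pos
                xyz = np.array([R @ a.pos + t for a in res.atoms])
                others = np.array([x for x, a in zip(xyz, res.atoms)
                                   if a.name != partner_atom])
                if _min_dist(others, avoid) >= min_clear:
                    for a, x in zip(res.atoms, xyz):
                        a.pos = x
                    return chain
    return None


def _build_anchor(lig_mol: Chem.Mol, lig_xyz: np.ndarray,
                  protected: np.ndarray) -> Chain | None:
    """Acceptor carbonyl for a polar ligand atom (native contact)."""
    avoid = np.vstack([protected, lig_xyz])
    for atom in lig_mol.GetAtoms():
        if atom.GetSymbol() not in ("O", "N"):
            continue
        nbs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if not nbs:
            continue
        o_lig = lig_xyz[atom.GetIdx()]
        d = o_lig - lig_xyz[nbs[0]]
        d /= np.linalg.norm(d)
        placed = _place_anchor("Z", o_lig + 2.9 * d, d, "O", avoid)
        if placed is not None:
            return placed
    return None


def _build_warhead_anchor(mod_coords: dict[str, np.ndarray], warhead: str,
                          avoid: np.ndarray) -> Chain | None:
    """Hydrogen-bond partner for the installed warhead: an acceptor carbonyl
    for the salicylaldehyde hydroxyl, a donor amide for a sulfonyl oxygen.
    Selects the planted ring placement in both protocols."""
    if warhead == "salicylaldehyde":
        d = mod_coords["O2"] - mod_coords["C2"]
        d /= np.linalg.norm(d)
        return _place_anchor("W", mod_coords["O2"] + 2.9 * d, d, "O", avoid)
    for oxygen in ("O1S", "O2S"):
        d = mod_coords[oxygen] - mod_coords["S"]
        d /= np.linalg.norm(d)
        placed = _place_anchor("W", mod_coords[oxygen] + 2.9 * d, d, "N", avoid)
        if placed is not None:
            return placed
    return None


def _build_collar(rc, nv, a1, a2, mod_coords, lig_xyz, protected_all) -> Chain | None:
    """Single-residue rim blockers around the ring, leaving openings for the
    ligand tail and the lysine linker.  Gives the cavity its shape so that
    sliding the ligand in-plane costs energy."""
    # in-plane directions already occupied by ligand tail or linker
    blocked_angles = []
    for xyz in list(lig_xyz) + [mod_coords["CE"], mod_coords["NZ"]]:
        v = xyz - rc
        v_ip = v - np.dot(v, nv) * nv
        if np.linalg.norm(v_ip) < 2.2:
            continue
        blocked_angles.append(np.arctan2(np.dot(v_ip, a2), np.dot(v_ip, a1)))
    chain = Chain("Y")
    seq = 0
    for theta in np.deg2rad(np.arange(0.0, 360.0, 45.0)):
        if any(abs(np.angle(np.exp(1j * (theta - b)))) < np.deg2rad(45.0)
               for b in blocked_angles):
            continue
        d_i = np.cos(theta) * a1 + np.sin(theta) * a2
        placed = None
        for extra in (0.0, 0.6, 1.2, 1.8):
            probe = _place_strand("Y", 1, np.cross(nv, d_i), d_i,
                                  rc + (COLLAR_RADIUS + extra) * d_i)
            if _min_dist(_chain_coords(probe), protected_all) >= WALL_CLEARANCE:
                placed = probe
                break
        if placed is None:
            continue
        seq += 1
        res = placed.residues[0]
        res.seqid = seq
        res.chain_id = "Y"
        chain.residues.append(res)
        protected_all = np.vstack([protected_all, res.coords()])
    return chain if chain.residues else None


def _true_adduct_pose(adduct: Chem.Mol, analog: CovalentAnalog,
                      lig_xyz: np.ndarray, mod_coords: dict[str, np.ndarray],
                      mod_template: ModifiedResidueTemplate) -> np.ndarray:
    """Ideal covalent pose of the adduct, assembled directly on the planted
    geometry: core atoms take the planted-ligand coordinates, warhead atoms
    the modified-residue warhead coordinates, and the N-zeta virtual site sits
    exactly on the lysine NZ."""
    ce = analog.ce_idx

    def shift(i: int) -> int:
        return i - 1 if i > ce else i

    pose = np.zeros((adduct.GetNumAtoms(), 3))
    assigned = np.zeros(adduct.GetNumAtoms(), dtype=bool)

    def put(idx: int, xyz: np.ndarray):
        pose[idx] = xyz
        assigned[idx] = True

    for analog_idx, tmpl_idx in analog.parent_map.items():
        if analog_idx != ce:
            put(shift(analog_idx), lig_xyz[tmpl_idx])
    put(shift(analog.link_idx), mod_coords[mod_template.link_atom])
    put(shift(analog.nz_idx), mod_coords["NZ"])
    oxygens = [shift(w) for w in analog.warhead_idxs if w != analog.link_idx
               and analog.molecule.GetAtomWithIdx(w).GetSymbol() == "O"]
    if analog.reaction == "salicylaldehyde":
        for o in oxygens:
            put(o, mod_coords["O2"])
    else:  # sulfonamide oxygens are symmetry-equivalent; assignment is free
        for o, name in zip(oxygens, ("O1S", "O2S")):
            put(o, mod_coords[name])
    if not assigned.all():
        raise FixtureError("true-pose assembly left atoms unplaced")
    return pose


def _apply_noise(cplx: ProteinLigandComplex, rng, sigma: float) -> None:
    """Coordinate noise emulating model/crystallographic uncertainty: mostly
    rigid per unit (chain or ligand) - a translation of scale ``sigma`` and a
    small rotation - plus independent atomic jitter at 0.35 * sigma.  Local
    internal geometry stays near-ideal, as in a refined structure, so the
    error does not get amplified through side-chain rebuilding."""
    from .geometry import rotation_matrix

    def jitter_unit(atoms):
        xyz = np.array([a.pos for a in atoms])
        centroid = xyz.mean(axis=0)
        axis = rng.normal(size=3)
        R = rotation_matrix(axis, rng.normal(0.0, 1.0))
        t = rng.normal(0.0, sigma, 3)
        for a in atoms:
            a.pos = R @ (a.pos - centroid) + centroid + t \
                + rng.normal(0.0, 0.35 * sigma, 3)

    for chain in cplx.chains:
        jitter_unit([a for r in chain.residues for a in r.atoms])
    for res in cplx.ligands:
        jitter_unit(res.atoms)


def make_pocket(spec: FixtureSpec) -> ProteinLigandComplex:
    """The noncovalent fixture complex alone (protocol input)."""
    return make_ground_truth(spec).complex


BENCHMARK_LIGANDS = [
    "Oc1ccccc1", "Cc1ccc(O)cc1", "COc1ccccc1", "CCc1ccc(O)cc1", "Cc1cccc(O)c1",
]
DECOY_RING_LIGAND = "Oc1ccc(Cc2ccccc2)cc1"   # second aryl ring stresses ring matching


def benchmark20(noise: float = 0.15, base_seed: int = 100) -> list[FixtureSpec]:
    """The 20-fixture benchmark set: both warheads, mixed pocket shapes,
    two decoy-ring ligands."""
    specs = []
    shapes = ["cleft", "cleft", "cleft", "walled", "open"]
    for i in range(20):
        warhead = "salicylaldehyde" if i % 2 == 0 else "aryl-sulfonyl-fluoride"
        ligand = DECOY_RING_LIGAND if i in (9, 18) else BENCHMARK_LIGANDS[i % 5]
        specs.append(FixtureSpec(
            seed=base_seed + i,
            pocket_shape=shapes[i % 5],
            planted_ligand=ligand,
            planted_warhead=warhead,
            noise=noise,
        ))
    return specs
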