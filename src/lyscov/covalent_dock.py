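"""Ligand-side protocol: covalent docking of electrophilic adducts.

Each adduct conformer is placed in the trimmed, prepacked pocket and refined
by Monte-Carlo moves over rigid-body degrees of freedom, conformer swaps and
target-lysine chi angles, under harmonic covalent constraints that pull the
covalent-bond atoms onto their ideal (virtual-site) positions.  Models are
ranked by interface score; a candidate is called high-confidence when a
top-10 model satisfies constraint score < 2 and MCS RMSD < 1.5 A to the
crystallographic template ligand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize

from . import _mcs
from .energy import AtomGroup, pair_energy, polar_directions
from .geometry import (dihedral_angle, random_rotation, rmsd_inplace,
                       rotation_matrix)
from .residues import LYS_SIDECHAIN, build_sidechain
from .rmsd_metrics import heavy_coords
from .structures import ConnectionSpec, ProteinLigandComplex, StructureError

logger = logging.getLogger(__name__)

SIDECHAIN_NAMES = [n for n, *_ in LYS_SIDECHAIN]


def harmonic(d: float, x0: float = 0.0, sd: float = 0.3) -> float:
    return ((d - x0) / sd) ** 2


@dataclass
class CovalentConstraint:
    """Harmonic distance restraints between covalent-bond atoms and their
    virtual placeholders; per-pair score ((d - x0)/sd)^2."""
    pairs: list  # opaque pair handles; resolved by the caller to positions
    x0: float = 0.0
    sd: float = 0.3


def constraint_score(pair_positions, constraint: CovalentConstraint | None = None) -> float:
    """Sum of harmonic penalties over (position_a, position_b) pairs."""
    x0 = constraint.x0 if constraint else 0.0
    sd = constraint.sd if constraint else 0.3
    total = 0.0
    for pa, pb in pair_positions:
        d = float(np.linalg.norm(np.asarray(pa, dtype=float) - np.asarray(pb, dtype=float)))
        total += harmonic(d, x0, sd)
    return total


@dataclass
class SelectionCriteria:
    """Accept/reject thresholds for both protocols."""
    top_n: int = 10
    max_constraint: float = 2.0
    max_rmsd: float = 1.5
    top_fraction: float = 0.10   # protein-side
    max_ring_rmsd: float = 1.0   # protein-side

    def __post_init__(self):
        for name in ("top_n", "max_constraint", "max_rmsd", "top_fraction", "max_ring_rmsd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"criteria field {name} must be positive")


@dataclass
class PoseModel:
    coordinates: np.ndarray          # ligand heavy atoms then lysine side chain
    total_score: float
    interface_score: float
    constraint_score: float
    mcs_rmsd_to_template: float
    conformer_index: int
    rank: int = -1


@dataclass
class MCConfig:
    """Monte-Carlo schedule for the docking refinement."""
    cycles: int = 300
    kt: float = 1.0
    p_rigid: float = 0.4
    p_swap: float = 0.3
    p_chi: float = 0.3
    max_translation: float = 0.5   # A
    max_rotation: float = 5.0      # deg
    max_chi_step: float = 20.0     # deg
    constraint_weight: float = 1.0
    minimize_maxfev: int = 200


def _approx_bond_graph(xyz: np.ndarray, cutoff: float = 1.8) -> list[tuple[int, int]]:
    from scipy.spatial import cKDTree
    tree = cKDTree(xyz)
    return [(i, j) for i, j in tree.query_pairs(cutoff)]


def _bfs_distances(n: int, bonds, sources: list[int], max_d: int = 4) -> np.ndarray:
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    dist = np.full(n, 99, dtype=int)
    frontier = list(sources)
    for s in sources:
        dist[s] = 0
    d = 0
    while frontier and d < max_d:
        d += 1
        nxt = []
        for i in frontier:
            for j in adj.get(i, []):
                if dist[j] > d:
                    dist[j] = d
                    nxt.append(j)
        frontier = nxt
    return dist


class DockingSystem:
    """Precomputed state for docking one adduct into one pocket."""

    def __init__(self, pocket: ProteinLigandComplex, adduct: Chem.Mol,
                 conformers, connection: ConnectionSpec,
                 config: MCConfig | None = None):
        self.config = config or MCConfig()
        self.adduct = adduct
        self.conformer_set = conformers
        self.connection = connection
        self.nz_idx = adduct.GetIntProp("nz_idx")
        self.link_idx = adduct.GetIntProp("link_idx")

        lys = pocket.lysine()
        self.lys_backbone = {n: lys.atom(n).pos.copy() for n in ("N", "CA", "C")}
        self.init_chis = self._measure_chis(lys)

        # static pocket: everything except the target-lysine side chain
        stat_xyz, stat_elems = [], []
        ca_index = None
        for chain in pocket.chains:
            for res in chain.residues:
                is_target = (chain.id, res.seqid) == pocket.target_lysine
                for atom in res.atoms:
                    if is_target and atom.name in SIDECHAIN_NAMES:
                        continue
                    if is_target and atom.name == "CA":
                        ca_index = len(stat_xyz)
                    stat_xyz.append(atom.pos)
                    stat_elems.append(atom.element)
        stat_xyz = np.array(stat_xyz)
        bonds = _approx_bond_graph(stat_xyz)
        self.static = AtomGroup(stat_xyz, stat_elems,
                                polar_directions(stat_xyz, stat_elems, bonds))
        d_ca = _bfs_distances(len(stat_xyz), bonds, [ca_index]) if ca_index is not None \
            else np.full(len(stat_xyz), 99)

        # lysine side-chain group and its exclusions vs the static pocket:
        # topological separation (k+1) + d(CA, static atom) <= 3 is excluded
        sc_elems = ["C", "C", "C", "C", "N"]
        self.lys_group = AtomGroup(np.zeros((5, 3)), sc_elems)
        self.lys_static_exclude = np.zeros((5, len(stat_xyz)), dtype=bool)
        for k in range(5):
            self.lys_static_exclude[k] = (k + 1) + d_ca <= 3

        # ligand steric atoms: all heavy atoms except the virtual-site N
        n_heavy = adduct.GetNumAtoms()
        self.lig_steric = np.array([i for i in range(n_heavy) if i != self.nz_idx])
        elems = [adduct.GetAtomWithIdx(int(i)).GetSymbol() for i in self.lig_steric]
        self.lig_group = AtomGroup(np.zeros((len(self.lig_steric), 3)), elems)
        self.lig_bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                          for b in adduct.GetBonds()]
        # bonded heavy parent per polar ligand atom (H-bond directionality)
        self.lig_polar_pairs = []   # (steric row, parent full-mol index)
        for row, i in enumerate(self.lig_steric):
            atom = adduct.GetAtomWithIdx(int(i))
            if atom.GetSymbol().upper() in ("N", "O"):
                nbs = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
                if nbs:
                    self.lig_polar_pairs.append((row, min(nbs)))

        # exclusions between ligand and lysine side chain through the new bond
        dmat = Chem.GetDistanceMatrix(adduct)
        lig_d_link = dmat[self.lig_steric, self.link_idx]
        lys_d_nz = np.array([4, 3, 2, 1, 0])  # CB CG CD CE NZ
        self.lig_lys_exclude = (lig_d_link[:, None] + 1 + lys_d_nz[None, :]) <= 3

        # covalent geometry targets
        self.bond_length = connection.internal_coords[0]
        self.ideal_angle = 120.5  # CE-NZ-link angle for the lysine-side virtual site
        self.constraint = CovalentConstraint(pairs=["nz_virtual", "link_virtual"])

        # template correspondence for per-pose MCS RMSD
        template = conformers.template
        self.template_xyz = heavy_coords(template)
        q = _mcs.mcs_query(adduct, template)
        matches_a = _mcs.all_matches(adduct, q)
        matches_b = _mcs.all_matches(template, q)
        images = {}
        for m in matches_a:
            images.setdefault(frozenset(m), m)
        self.correspondences = [(np.array(ma), np.array(mb))
                                for ma in images.values() for mb in matches_b]

    def _measure_chis(self, lys) -> np.ndarray:
        pos = {n: lys.atom(n).pos for n in ("N", "CA", "CB", "CG", "CD", "CE", "NZ")
               if lys.has_atom(n)}
        chain = ["N", "CA", "CB", "CG", "CD", "CE", "NZ"]
        chis = []
        for k in range(4):
            names = chain[k:k + 4]
            if all(n in pos for n in names):
                chis.append(dihedral_angle(*(pos[n] for n in names)))
            else:
                chis.append(180.0)
        return np.array(chis)

    # --- pose evaluation -------------------------------------------------

    def sidechain_coords(self, chis) -> np.ndarray:
        sc = build_sidechain(self.lys_backbone, list(chis))
        return np.array([sc[n] for n in SIDECHAIN_NAMES])

    def constraint_pairs(self, lig_xyz: np.ndarray, sc_xyz: np.ndarray):
        """The two reciprocal covalent constraint pairs.

        1. lysine NZ vs the ligand-side virtual site (the adduct's N-zeta);
        2. ligand link atom vs the lysine-side virtual site: the ideal-bond
           circle around NZ (bond length, CE-NZ-link angle ideal; torsion
           free), evaluated at its nearest point in closed form.
        """
        nz = sc_xyz[4]
        ce = sc_xyz[3]
        lig_nz = lig_xyz[self.nz_idx]
        link = lig_xyz[self.link_idx]
        pairs = [(nz, lig_nz)]
        # nearest point on the ideal-geometry circle
        u = nz - ce
        u /= np.linalg.norm(u)
        w = link - nz
        theta = np.deg2rad(180.0 - self.ideal_angle)  # angle from the CE->NZ axis
        w_par = float(np.dot(w, u))
        w_perp = w - w_par * u
        p = np.linalg.norm(w_perp)
        target_par = self.bond_length * np.cos(theta)
        target_perp = self.bond_length * np.sin(theta)
        gap = float(np.hypot(w_par - target_par, p - target_perp))
        # express the cone gap as a pair of points at that separation
        pairs.append((np.zeros(3), np.array([gap, 0.0, 0.0])))
        return pairs

    def cst_score(self, lig_xyz: np.ndarray, sc_xyz: np.ndarray) -> float:
        return constraint_score(self.constraint_pairs(lig_xyz, sc_xyz), self.constraint)

    def energies(self, lig_xyz: np.ndarray, chis) -> tuple[float, float, float]:
        """(total, interface, constraint) for a pose."""
        sc_xyz = self.sidechain_coords(chis)
        lig_steric_xyz = lig_xyz[self.lig_steric]
        lig_dirs = np.zeros_like(lig_steric_xyz)
        for row, parent in self.lig_polar_pairs:
            v = lig_steric_xyz[row] - lig_xyz[parent]
            lig_dirs[row] = v / np.linalg.norm(v)
        lig = self.lig_group.moved(lig_steric_xyz, lig_dirs)
        nz_dir = sc_xyz[4] - sc_xyz[3]
        nz_dir /= np.linalg.norm(nz_dir)
        sc_dirs = np.zeros((5, 3))
        sc_dirs[4] = nz_dir
        lys = self.lys_group.moved(sc_xyz, sc_dirs)

        e_lig_static = pair_energy(lig, self.static)
        e_lig_lys = pair_energy(lig, lys, exclude=self.lig_lys_exclude)
        e_lys_static = pair_energy(lys, self.static, exclude=self.lys_static_exclude)
        cst = self.cst_score(lig_xyz, sc_xyz)
        interface = e_lig_static + e_lig_lys + self.config.constraint_weight * cst
        total = interface + e_lys_static
        return total, interface, cst


def pose_energy(system: DockingSystem, lig_xyz: np.ndarray, chis=None) -> float:
    """Total pose energy (steric + attraction + H-bond + weighted constraint).

    Deterministic closed form; clashes give large finite values.
    """
    if chis is None:
        chis = system.init_chis
    return system.energies(lig_xyz, chis)[0]


def prepack(pocket: ProteinLigandComplex, tol: float = 1e-5) -> ProteinLigandComplex:
    """Relax the target-lysine side chain to a local energy minimum
    (torsion-space coordinate descent; backbone fixed).  Energy never
    increases; idempotent within tolerance."""
    pocket = pocket.copy()
    if pocket.target_lysine is None:
        return pocket
    system = _sidechain_system(pocket)
    chis = system["init_chis"].copy()
    e = system["energy"](chis)
    improved = True
    while improved:
        improved = False
        for k in range(4):
            for step in (30.0, 10.0, 3.0, 1.0):
                for sgn in (1.0, -1.0):
                    trial = chis.copy()
                    trial[k] += sgn * step
                    et = system["energy"](trial)
                    if et < e - tol:
                        chis, e = trial, et
                        improved = True
    _apply_chis(pocket, chis)
    return pocket


def _sidechain_system(pocket: ProteinLigandComplex):
    """Minimal closure for lysine side-chain vs pocket energy (no ligand)."""
    lys = pocket.lysine()
    backbone = {n: lys.atom(n).pos.copy() for n in ("N", "CA", "C")}
    stat_xyz, stat_elems = [], []
    ca_index = None
    for chain in pocket.chains:
        for res in chain.residues:
            is_target = (chain.id, res.seqid) == pocket.target_lysine
            for atom in res.atoms:
                if is_target and atom.name in SIDECHAIN_NAMES:
                    continue
                if is_target and atom.name == "CA":
                    ca_index = len(stat_xyz)
                stat_xyz.append(atom.pos)
                stat_elems.append(atom.element)
    stat_xyz = np.array(stat_xyz)
    bonds = _approx_bond_graph(stat_xyz)
    static = AtomGroup(stat_xyz, stat_elems,
                       polar_directions(stat_xyz, stat_elems, bonds))
    d_ca = _bfs_distances(len(stat_xyz), bonds, [ca_index]) if ca_index is not None \
        else np.full(len(stat_xyz), 99)
    exclude = np.zeros((5, len(stat_xyz)), dtype=bool)
    for k in range(5):
        exclude[k] = (k + 1) + d_ca <= 3
    group = AtomGroup(np.zeros((5, 3)), ["C", "C", "C", "C", "N"])

    chain_names = ["N", "CA", "CB", "CG", "CD", "CE", "NZ"]
    pos = {n: lys.atom(n).pos for n in chain_names if lys.has_atom(n)}
    init = []
    for k in range(4):
        names = chain_names[k:k + 4]
        init.append(dihedral_angle(*(pos[n] for n in names)) if all(n in pos for n in names) else 180.0)

    def energy(chis):
        sc = build_sidechain(backbone, list(chis))
        xyz = np.array([sc[n] for n in SIDECHAIN_NAMES])
        return pair_energy(group.moved(xyz), static, exclude=exclude)

    return {"init_chis": np.array(init), "energy": energy}


def _apply_chis(pocket: ProteinLigandComplex, chis) -> None:
    lys = pocket.lysine()
    backbone = {n: lys.atom(n).pos.copy() for n in ("N", "CA", "C")}
    sc = build_sidechain(backbone, list(chis))
    for name, xyz in sc.items():
        if lys.has_atom(name):
            lys.atom(name).pos = xyz
        else:
            from .structures import Atom
            lys.atoms.append(Atom(name, "N" if name == "NZ" else "C", xyz))


def dock(pocket: ProteinLigandComplex, adduct: Chem.Mol, conformer_set,
         connection: ConnectionSpec, n_models: int = 100, seed: int = 1,
         config: MCConfig | None = None) -> list[PoseModel]:
    """Generate ``n_models`` covalently constrained docking models.

    Each model: random conformer pick, initial placement near the lysine NZ,
    Metropolis Monte-Carlo refinement (rigid body / conformer swap / lysine
    chis), then gradient-free minimization.  Deterministic for a fixed seed.
    """
    if len(conformer_set) == 0:
        raise ValueError("empty conformer set")
    system = DockingSystem(pocket, adduct, conformer_set, connection, config)
    cfg = system.config
    bases = [np.asarray(x, dtype=float) for x in conformer_set.conformers]
    nz_pocket = system.sidechain_coords(system.init_chis)[4]

    models = []
    for m in range(n_models):
        rng = np.random.default_rng([seed, m])
        state = _mc_model(system, bases, nz_pocket, rng, cfg)
        lig_xyz, chis, conf_idx = state
        total, interface, cst = system.energies(lig_xyz, chis)
        rmsd = _pose_mcs_rmsd(system, lig_xyz)
        models.append(PoseModel(
            coordinates=np.vstack([lig_xyz, system.sidechain_coords(chis)]),
            total_score=total, interface_score=interface, constraint_score=cst,
            mcs_rmsd_to_template=rmsd, conformer_index=conf_idx))
    return models


def _transform(base: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    c0 = base.mean(axis=0)
    return (base - c0) @ R.T + c0 + t


_CHI_STATES = (-60.0, 60.0, 180.0)


def _best_start_chis(system: DockingSystem, lig_xyz: np.ndarray) -> np.ndarray:
    """Pick the lysine rotamer (library states) minimizing the covalent
    constraint for the given ligand placement: on-the-fly sampling of the
    target nucleophile's rotamers."""
    best, best_chis = np.inf, system.init_chis
    for chis in np.array(np.meshgrid(*[_CHI_STATES] * 4)).T.reshape(-1, 4):
        sc = system.sidechain_coords(chis)
        val = system.cst_score(lig_xyz, sc)
        if val < best:
            best, best_chis = val, chis
    return np.array(best_chis, dtype=float)


def _mc_model(system: DockingSystem, bases, nz_pocket, rng, cfg: MCConfig):
    conf_idx = int(rng.integers(len(bases)))
    R = np.eye(3)
    # half the trajectories start template-aligned, half superpose the
    # adduct virtual site onto the lysine NZ
    if rng.random() < 0.5:
        t = np.zeros(3)
    else:
        t = nz_pocket - bases[conf_idx][system.nz_idx]
    t = t + rng.normal(scale=0.1, size=3)
    chis = _best_start_chis(system, _transform(bases[conf_idx], R, t))

    def coords():
        return _transform(bases[conf_idx], R, t)

    e_cur = system.energies(coords(), chis)[0]
    best = (e_cur, conf_idx, R.copy(), t.copy(), chis.copy())
    for _ in range(cfg.cycles):
        move = rng.random()
        new_conf, new_R, new_t, new_chis = conf_idx, R, t, chis
        if move < cfg.p_rigid:
            new_R = random_rotation(rng, cfg.max_rotation) @ R
            new_t = t + rng.uniform(-cfg.max_translation, cfg.max_translation, 3)
        elif move < cfg.p_rigid + cfg.p_swap and len(bases) > 1:
            new_conf = int(rng.integers(len(bases)))
        else:
            new_chis = chis.copy()
            k = int(rng.integers(4))
            if rng.random() < 0.5:
                new_chis[k] += rng.uniform(-cfg.max_chi_step, cfg.max_chi_step)
            else:
                # jump to another rotamer well
                new_chis[k] = _CHI_STATES[int(rng.integers(3))] \
                    + rng.uniform(-5.0, 5.0)
        xyz = _transform(bases[new_conf], new_R, new_t)
        e_new = system.energies(xyz, new_chis)[0]
        if e_new <= e_cur or rng.random() < np.exp(-(e_new - e_cur) / cfg.kt):
            conf_idx, R, t, chis, e_cur = new_conf, new_R, new_t, new_chis, e_new
            if e_cur < best[0]:
                best = (e_cur, conf_idx, R.copy(), t.copy(), chis.copy())

    _, conf_idx, R, t, chis = best
    base = bases[conf_idx]

    def objective(x):
        Rx = rotation_matrix(np.array([1.0, 0, 0]), x[3]) @ \
             rotation_matrix(np.array([0, 1.0, 0]), x[4]) @ \
             rotation_matrix(np.array([0, 0, 1.0]), x[5]) @ R
        xyz = _transform(base, Rx, t + x[:3])
        return system.energies(xyz, chis + x[6:])[0]

    x0 = np.zeros(10)
    res = minimize(objective, x0, method="Powell",
                   options={"maxfev": cfg.minimize_maxfev, "xtol": 1e-2, "ftol": 1e-4})
    x = res.x
    R = rotation_matrix(np.array([1.0, 0, 0]), x[3]) @ \
        rotation_matrix(np.array([0, 1.0, 0]), x[4]) @ \
        rotation_matrix(np.array([0, 0, 1.0]), x[5]) @ R
    t = t + x[:3]
    chis = chis + x[6:]
    return _transform(base, R, t), chis, conf_idx


def _pose_mcs_rmsd(system: DockingSystem, lig_xyz: np.ndarray) -> float:
    best = np.inf
    for ma, mb in system.correspondences:
        val = rmsd_inplace(lig_xyz[ma], system.template_xyz[mb])
        if val < best:
            best = val
    return float(best)


def rank_and_select(models: list[PoseModel], criteria: SelectionCriteria | None = None):
    """Sort models by interface score and apply the high-confidence rule:
    some top-``top_n`` model with constraint < max_constraint and MCS RMSD
    < max_rmsd.  Returns (ranked models, high_confidence, passing indices)."""
    if not models:
        raise ValueError("empty model list")
    criteria = criteria or SelectionCriteria()
    ranked = sorted(models, key=lambda p: p.interface_score)
    for i, p in enumerate(ranked):
        p.rank = i + 1
    passing = [i for i, p in enumerate(ranked)
               if p.constraint_score < criteria.max_constraint
               and p.mcs_rmsd_to_template < criteria.max_rmsd]
    high_confidence = any(i < criteria.top_n for i in passing)
    return ranked, high_confidence, passing
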