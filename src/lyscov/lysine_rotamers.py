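"""Protein-side protocol: electrophile-modified lysine rotamer scanning.

The target lysine is rebuilt as a covalently modified residue (electrophile
installed on an aryl ring), its conformational space is enumerated as the
Cartesian product of a backbone-independent lysine rotamer library with
warhead-torsion grids, each conformation is scored against the 10 A pocket
neighborhood, and top-scoring conformations whose ring overlaps a template
ligand ring (symmetry-aware ring RMSD < 1 A) yield proposed warhead
installation vectors.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .covalent_dock import (SelectionCriteria, _approx_bond_graph,
                            _bfs_distances)
from .energy import AtomGroup, pair_energy, polar_directions
from .geometry import bond_angle, dihedral_angle, distance, place_atom
from .residues import LYS_SIDECHAIN
from .rmsd_metrics import RingMatch, heavy_coords, ring_rmsd
from .structures import ProteinLigandComplex, StructureError

logger = logging.getLogger(__name__)

NEIGHBORHOOD_RADIUS = 10.0

# backbone-independent lysine rotamer library: 3 states per chi with
# gauche-/trans/gauche+ means and marginal probabilities; a rotamer's
# probability is the product of its per-chi marginals
DEFAULT_CHI_LIBRARY: list[list[tuple[float, float]]] = [
    [(-60.0, 0.52), (180.0, 0.35), (60.0, 0.13)],
    [(180.0, 0.60), (-60.0, 0.22), (60.0, 0.18)],
    [(180.0, 0.65), (-60.0, 0.18), (60.0, 0.17)],
    [(180.0, 0.60), (-60.0, 0.20), (60.0, 0.20)],
]


def _grid(step: float, span: float = 360.0) -> list[float]:
    n = int(round(span / step))
    return [-180.0 + i * step for i in range(n)] if span == 360.0 \
        else [i * step for i in range(n)]


# warhead geometry past NZ; entries (name, (a, b, c), d, ang, dih spec)
# dih spec: ("pchi", i) sampled torsion, ("pchi_offset", i, deg), ("fixed", deg)
_SA_WARHEAD = [
    ("C4A", ("CD", "CE", "NZ"), 1.28, 121.0, ("pchi", 0)),
    ("C1", ("CE", "NZ", "C4A"), 1.47, 122.0, ("fixed", 180.0)),  # E-imine
    ("C2", ("NZ", "C4A", "C1"), 1.40, 120.0, ("pchi", 1)),
    ("C3", ("C4A", "C1", "C2"), 1.40, 120.0, ("fixed", 180.0)),
    ("C4", ("C1", "C2", "C3"), 1.40, 120.0, ("fixed", 0.0)),
    ("C5", ("C2", "C3", "C4"), 1.40, 120.0, ("fixed", 0.0)),
    ("C6", ("C3", "C4", "C5"), 1.40, 120.0, ("fixed", 0.0)),
    ("O2", ("C4A", "C1", "C2"), 1.36, 120.0, ("fixed", 0.0)),
]
_SF_WARHEAD = [
    ("S", ("CD", "CE", "NZ"), 1.63, 120.0, ("pchi", 0)),
    ("O1S", ("CE", "NZ", "S"), 1.43, 107.0, ("pchi_offset", 1, 120.0)),
    ("O2S", ("CE", "NZ", "S"), 1.43, 107.0, ("pchi_offset", 1, -120.0)),
    ("C1", ("CE", "NZ", "S"), 1.77, 103.0, ("pchi", 1)),
    ("C2", ("NZ", "S", "C1"), 1.40, 120.0, ("pchi", 2)),
    ("C3", ("S", "C1", "C2"), 1.40, 120.0, ("fixed", 180.0)),
    ("C4", ("C1", "C2", "C3"), 1.40, 120.0, ("fixed", 0.0)),
    ("C5", ("C2", "C3", "C4"), 1.40, 120.0, ("fixed", 0.0)),
    ("C6", ("C3", "C4", "C5"), 1.40, 120.0, ("fixed", 0.0)),
]

# proton-chi sampling grids (degrees): the CE-NZ and N-S torsions at 60 (30
# for the two-torsion imine linker), the 2-fold symmetric S-aryl torsion over
# [0, 180)
_WARHEADS = {
    "salicylaldehyde": (_SA_WARHEAD, [_grid(30.0), _grid(30.0)], "C4A"),
    "aryl-sulfonyl-fluoride": (_SF_WARHEAD, [_grid(60.0), _grid(60.0), _grid(30.0, 180.0)], "S"),
}

RING_ATOMS = ["C1", "C2", "C3", "C4", "C5", "C6"]


@dataclass
class ModifiedResidueTemplate:
    """Internal-coordinate template of an electrophile-modified lysine."""
    warhead: str
    zmat: list                      # side chain + warhead internal coordinates
    proton_chis: list[list[float]]  # sampling grid per extra torsion
    ring_atoms: list[str] = field(default_factory=lambda: list(RING_ATOMS))
    link_atom: str = ""
    warhead_position_atom: str = "C1"

    @property
    def n_chis(self) -> int:
        return 4

    def atom_names(self) -> list[str]:
        return [row[0] for row in self.zmat]

    def elements(self) -> list[str]:
        out = []
        for name in self.atom_names():
            out.append(name[0] if name[0] in ("C", "N", "O", "S") else "C")
        return out


@dataclass
class RotamerAssignment:
    chis: tuple[float, ...]
    proton_chis: tuple[float, ...]
    probability: float


@dataclass
class RotamerConformation:
    chi_values: tuple[float, ...]       # chis + proton chis
    probability: float
    coordinates: np.ndarray             # side-chain + warhead atoms, pocket frame
    neighborhood_score: float
    ring_xyz: np.ndarray | None = None  # warhead ring, cyclic order, C1 first
    ring_rmsd: float = np.nan
    ring_match: RingMatch | None = None
    rank: int = -1


def build_template(warhead: str, ring_spec: str | None = None) -> ModifiedResidueTemplate:
    """Idealized internal-coordinate template for a modified lysine.

    The aldehyde warhead is built as the E-configured imine (Schiff base),
    the sulfonyl fluoride as the sulfonamide.  Raises ValueError for an
    unknown warhead name.
    """
    if warhead not in _WARHEADS:
        raise ValueError(f"unknown warhead: {warhead!r}")
    wh_zmat, grids, link = _WARHEADS[warhead]
    return ModifiedResidueTemplate(
        warhead=warhead,
        zmat=list(LYS_SIDECHAIN) + list(wh_zmat),
        proton_chis=[list(g) for g in grids],
        link_atom=link,
    )


def build_coordinates(template: ModifiedResidueTemplate,
                      backbone: dict[str, np.ndarray],
                      chis, proton_chis) -> dict[str, np.ndarray]:
    """Cartesian coordinates of the modified side chain from backbone N/CA/C
    and torsion values (exact NeRF chain construction)."""
    coords = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    out: dict[str, np.ndarray] = {}
    for name, (a, b, c), d, ang, dih_spec in template.zmat:
        kind = dih_spec[0]
        if kind == "chi":
            dih = chis[dih_spec[1]]
        elif kind == "pchi":
            dih = proton_chis[dih_spec[1]]
        elif kind == "pchi_offset":
            dih = proton_chis[dih_spec[1]] + dih_spec[2]
        else:
            dih = dih_spec[1]
        pos = place_atom(coords[a], coords[b], coords[c], d, ang, dih)
        coords[name] = pos
        out[name] = pos
    return out


def measure_internal(template: ModifiedResidueTemplate,
                     backbone: dict[str, np.ndarray],
                     coords: dict[str, np.ndarray]) -> list[tuple[float, float, float]]:
    """Measure (distance, angle, dihedral) for every template atom from
    Cartesian coordinates (the inverse of build_coordinates)."""
    all_pos = {**{k: np.asarray(v, float) for k, v in backbone.items()},
               **{k: np.asarray(v, float) for k, v in coords.items()}}
    rows = []
    for name, (a, b, c), *_ in template.zmat:
        rows.append((distance(all_pos[name], all_pos[c]),
                     bond_angle(all_pos[b], all_pos[c], all_pos[name]),
                     dihedral_angle(all_pos[a], all_pos[b], all_pos[c], all_pos[name])))
    return rows


def enumerate_rotamers(template: ModifiedResidueTemplate,
                       chi_library: list[list[tuple[float, float]]] | None = None,
                       proton_grids: list[list[float]] | None = None
                       ) -> list[RotamerAssignment]:
    """Cartesian product of library chi combinations and proton-chi grid
    points.  Zero-probability entries are excluded.  Deterministic order:
    descending rotamer probability, then grid order."""
    library = chi_library if chi_library is not None else DEFAULT_CHI_LIBRARY
    grids = proton_grids if proton_grids is not None else template.proton_chis
    if not library or any(len(states) == 0 for states in library):
        raise ValueError("empty rotamer library")
    combos = []
    for combo in itertools.product(*library):
        prob = float(np.prod([p for _, p in combo]))
        if prob <= 0.0:
            continue
        combos.append((tuple(angle for angle, _ in combo), prob))
    combos.sort(key=lambda cp: (-cp[1], cp[0]))
    out = []
    grid_product = list(itertools.product(*grids)) if grids else [()]
    for chis, prob in combos:
        for pchis in grid_product:
            out.append(RotamerAssignment(chis, tuple(pchis), prob))
    return out


class RotamerScorer:
    """Scores modified-lysine rotamers against a fixed (ligand-free) pocket."""

    def __init__(self, pocket: ProteinLigandComplex,
                 template: ModifiedResidueTemplate):
        if pocket.target_lysine is None:
            raise StructureError("pocket has no target lysine")
        self.template = template
        lys = pocket.lysine()
        self.backbone = {n: lys.atom(n).pos.copy() for n in ("N", "CA", "C")}
        names = template.atom_names()
        self.elements = template.elements()

        stat_xyz, stat_elems = [], []
        self.res_index: list[int] = []   # residue ordinal per static atom
        ca_index = None
        n_res = 0
        sidechain_names = set(n for n, *_ in LYS_SIDECHAIN)
        for chain in pocket.chains:
            for res in chain.residues:
                is_target = (chain.id, res.seqid) == pocket.target_lysine
                for atom in res.atoms:
                    if is_target and atom.name in sidechain_names:
                        continue  # replaced by the modified side chain
                    if is_target and atom.name == "CA":
                        ca_index = len(stat_xyz)
                    stat_xyz.append(atom.pos)
                    stat_elems.append(atom.element)
                    self.res_index.append(n_res)
                n_res += 1
        stat_xyz = np.array(stat_xyz)
        bonds = _approx_bond_graph(stat_xyz)
        self.static = AtomGroup(stat_xyz, stat_elems,
                                polar_directions(stat_xyz, stat_elems, bonds))
        d_ca = _bfs_distances(len(stat_xyz), bonds, [ca_index]) if ca_index is not None \
            else np.full(len(stat_xyz), 99)
        # exclude pairs topologically closer than 4 bonds through CA
        n_side = len(names)
        self.exclude = np.zeros((n_side, len(stat_xyz)), dtype=bool)
        for k in range(n_side):
            self.exclude[k] = (min(k, 4) + 1) + d_ca <= 3
        self.group = AtomGroup(np.zeros((n_side, 3)), self.elements)
        self.names = names
        self.ring_idx = [names.index(n) for n in template.ring_atoms]
        # bonded parent per side-chain atom (the NeRF attachment reference),
        # used for the hydrogen-bond angular factor
        self.parent = [names.index(row[1][2]) if row[1][2] in names else -1
                       for row in template.zmat]

    def _dirs(self, xyz: np.ndarray) -> np.ndarray:
        dirs = np.zeros_like(xyz)
        for i, p in enumerate(self.parent):
            if self.group.polar[i]:
                base = xyz[p] if p >= 0 else self.backbone["CA"]
                v = xyz[i] - base
                dirs[i] = v / np.linalg.norm(v)
        return dirs

    def score(self, chis, proton_chis) -> tuple[np.ndarray, float]:
        coords = build_coordinates(self.template, self.backbone, chis, proton_chis)
        xyz = np.array([coords[n] for n in self.names])
        d = np.min(np.linalg.norm(
            self.static.xyz[None, :, :] - xyz[:, None, :], axis=2), axis=0)
        near = d <= NEIGHBORHOOD_RADIUS
        if not np.any(near):
            return xyz, 0.0
        sub = AtomGroup(self.static.xyz[near],
                        [self.static.elements[i] for i in np.nonzero(near)[0]],
                        self.static.polar_dir[near] if self.static.polar_dir is not None else None)
        e = pair_energy(self.group.moved(xyz, self._dirs(xyz)), sub,
                        exclude=self.exclude[:, near])
        return xyz, float(e)


def build_coordinates_batch(template: ModifiedResidueTemplate,
                            backbone: dict[str, np.ndarray],
                            chis, pchi_array: np.ndarray) -> np.ndarray:
    """Batched NeRF build: one chi combination, K proton-chi assignments.

    ``pchi_array`` has shape (K, n_proton_chis); returns (K, n_atoms, 3).
    Row-for-row identical to build_coordinates.
    """
    from .geometry import place_atom_batch
    K = len(pchi_array)
    coords: dict[str, np.ndarray] = {
        k: np.broadcast_to(np.asarray(v, float), (K, 3)).copy()
        for k, v in backbone.items()}
    names = template.atom_names()
    out = np.empty((K, len(names), 3))
    for row_i, (name, (a, b, c), d, ang, dih_spec) in enumerate(template.zmat):
        kind = dih_spec[0]
        if kind == "chi":
            dih = np.full(K, chis[dih_spec[1]])
        elif kind == "pchi":
            dih = pchi_array[:, dih_spec[1]]
        elif kind == "pchi_offset":
            dih = pchi_array[:, dih_spec[1]] + dih_spec[2]
        else:
            dih = np.full(K, dih_spec[1])
        pos = place_atom_batch(coords[a], coords[b], coords[c], d, ang, dih)
        coords[name] = pos
        out[:, row_i] = pos
    return out


def scan_rotamers_fast(pocket: ProteinLigandComplex,
                       template: ModifiedResidueTemplate,
                       rotamers: list[RotamerAssignment] | None = None
                       ) -> list[RotamerConformation]:
    """Vectorized equivalent of scan_rotamers (same scores and ordering)."""
    from .energy import pair_energy_batch
    scorer = RotamerScorer(pocket, template)
    rotamers = rotamers if rotamers is not None else enumerate_rotamers(template)
    parent = scorer.parent
    polar = scorer.group.polar
    out: list[RotamerConformation] = []
    by_chis: dict[tuple, list[RotamerAssignment]] = {}
    for rot in rotamers:
        by_chis.setdefault(rot.chis, []).append(rot)
    for chis, group in by_chis.items():
        pgrid = np.array([r.proton_chis for r in group], dtype=float)
        if pgrid.size == 0:
            pgrid = np.zeros((len(group), 0))
        X = build_coordinates_batch(template, scorer.backbone, chis, pgrid)
        dirs = np.zeros_like(X)
        for i, p in enumerate(parent):
            if polar[i]:
                base = X[:, p] if p >= 0 else np.broadcast_to(
                    scorer.backbone["CA"], (len(X), 3))
                v = X[:, i] - base
                dirs[:, i] = v / np.linalg.norm(v, axis=1, keepdims=True)
        energies = pair_energy_batch(X, scorer.group.radii, polar, dirs,
                                     scorer.static, exclude=scorer.exclude)
        for k, rot in enumerate(group):
            out.append(RotamerConformation(
                chi_values=rot.chis + rot.proton_chis,
                probability=rot.probability,
                coordinates=X[k],
                ring_xyz=X[k][scorer.ring_idx],
                neighborhood_score=float(energies[k]),
            ))
    out.sort(key=lambda r: (r.neighborhood_score, -r.probability))
    for i, r in enumerate(out):
        r.rank = i + 1
    return out


def preminimize_pocket(cplx: ProteinLigandComplex) -> tuple[ProteinLigandComplex, "object"]:
    """Relax side chains around the ligand (torsion-space descent, tolerance
    1e-5), then remove the ligand.  Returns (ligand-free pocket, retained
    template-ligand residue for later RMSD reference)."""
    from .covalent_dock import prepack
    if not cplx.ligands:
        raise StructureError("complex has no ligand")
    relaxed = prepack(cplx, tol=1e-5)
    template_ref = relaxed.ligands[0].copy()
    pocket = relaxed.copy()
    pocket.ligands = []
    return pocket, template_ref


def place_and_score(pocket: ProteinLigandComplex, residue_site: tuple[str, int],
                    rotamer: RotamerAssignment,
                    template: ModifiedResidueTemplate,
                    scorer: RotamerScorer | None = None) -> RotamerConformation:
    """Build one rotamer of the modified lysine in the pocket and score its
    10 A neighborhood.  ``residue_site`` must be the pocket's target lysine."""
    if residue_site != pocket.target_lysine:
        raise StructureError("site is not the target lysine")
    if len(rotamer.chis) != template.n_chis:
        raise ValueError("rotamer chi count does not match template")
    scorer = scorer or RotamerScorer(pocket, template)
    xyz, e = scorer.score(rotamer.chis, rotamer.proton_chis)
    return RotamerConformation(
        chi_values=rotamer.chis + rotamer.proton_chis,
        probability=rotamer.probability,
        coordinates=xyz,
        ring_xyz=xyz[scorer.ring_idx],
        neighborhood_score=e,
    )


def scan_rotamers(pocket: ProteinLigandComplex,
                  template: ModifiedResidueTemplate,
                  rotamers: list[RotamerAssignment] | None = None
                  ) -> list[RotamerConformation]:
    """Score every rotamer; returns conformations ranked by neighborhood
    score ascending (ties broken by probability descending)."""
    scorer = RotamerScorer(pocket, template)
    rotamers = rotamers if rotamers is not None else enumerate_rotamers(template)
    out = []
    for rot in rotamers:
        xyz, e = scorer.score(rot.chis, rot.proton_chis)
        out.append(RotamerConformation(
            chi_values=rot.chis + rot.proton_chis,
            probability=rot.probability,
            coordinates=xyz,
            ring_xyz=xyz[scorer.ring_idx],
            neighborhood_score=e,
        ))
    out.sort(key=lambda r: (r.neighborhood_score, -r.probability))
    for i, r in enumerate(out):
        r.rank = i + 1
    return out


@dataclass
class VectorSuggestion:
    """A proposed warhead installation vector on the template ligand."""
    template_ring: tuple[int, ...]
    position: int            # template atom index to derivatize
    ring_rmsd: float
    rotamer: RotamerConformation


def select_vectors(scored: list[RotamerConformation],
                   template_mol: Chem.Mol,
                   template_coords: np.ndarray | None = None,
                   criteria: SelectionCriteria | None = None
                   ) -> list[VectorSuggestion]:
    """Apply the protein-side selection rule: among the top ``top_fraction``
    rotamers by neighborhood score, emit one suggestion per (template ring,
    ring position) whose symmetry-aware ring RMSD is below ``max_ring_rmsd``.

    The installation position is the template atom matched to the
    warhead-bearing ring atom of the modified residue.
    """
    if len(scored) < 10:
        raise ValueError("need at least 10 scored rotamers")
    criteria = criteria or SelectionCriteria()
    if not template_mol.GetRingInfo().AtomRings() and template_coords is None:
        raise ValueError("template has no rings")
    if template_coords is None:
        template_coords = heavy_coords(template_mol)
    if not template_mol.GetRingInfo().AtomRings():
        raise ValueError("template has no rings")

    ranked = sorted(scored, key=lambda r: (r.neighborhood_score, -r.probability))
    n_top = max(1, int(np.floor(criteria.top_fraction * len(ranked))))
    best: dict[tuple[tuple[int, ...], int], VectorSuggestion] = {}
    for rot in ranked[:n_top]:
        if rot.ring_xyz is None:
            continue
        try:
            # the warhead-bearing ring atom (C1) is cyclic position 0
            match = ring_rmsd(rot.ring_xyz, ["C"] * len(rot.ring_xyz),
                              template_mol, template_coords)
        except ValueError:
            continue
        rot.ring_rmsd = match.rmsd
        rot.ring_match = match
        if match.rmsd < criteria.max_ring_rmsd:
            position = match.mapping[0]
            key = (match.template_ring, position)
            if key not in best or match.rmsd < best[key].ring_rmsd:
                best[key] = VectorSuggestion(match.template_ring, position,
                                             match.rmsd, rot)
    return sorted(best.values(), key=lambda v: v.ring_rmsd)
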