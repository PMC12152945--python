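"""Protein-ligand complex model and PDB input/output.

A complex holds polymer chains, non-polymer ligands, covalent LINK records and
an optional target lysine.  Parsing goes through gemmi; writing emits standard
ATOM/HETATM/LINK/CONECT records.  Coordinates are Cartesian angstroms and
residue numbering follows PDB author numbering.  Alternate locations: only
altloc '' or 'A' atoms are kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# standard amino-acid names (used to tell polymer from ligand residues)
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ACE", "NME", "NMA",
}

# covalent bond lengths outside this window are flagged irregular
LINK_REGULAR_RANGE = (1.0, 1.8)


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,)

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy())


@dataclass
class Residue:
    name: str
    seqid: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"atom {name} not found in {self.chain_id}:{self.seqid} {self.name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def copy(self) -> "Residue":
        return Residue(self.name, self.seqid, self.chain_id,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int) -> Residue:
        for r in self.residues:
            if r.seqid == seqid:
                return r
        raise StructureError(f"residue {self.id}:{seqid} not found")

    def coords(self) -> np.ndarray:
        return np.concatenate([r.coords() for r in self.residues])

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class AtomLocator:
    chain_id: str
    seqid: int
    res_name: str
    atom_name: str


@dataclass
class LinkRecord:
    a: AtomLocator
    b: AtomLocator
    distance: float

    @property
    def irregular(self) -> bool:
        lo, hi = LINK_REGULAR_RANGE
        return not (lo <= self.distance <= hi)


@dataclass
class ConnectionSpec:
    """Covalent connection of a ligand atom to lysine NZ.

    The virtual site is the ideal position of the partner atom, stored as
    internal coordinates (distance, angle, dihedral) relative to three ligand
    reference atoms so it can be rebuilt in any pose.
    """
    ligand_link_atom: str
    ref_atoms: tuple[str, str, str]      # (link atom, neighbor, next neighbor)
    internal_coords: tuple[float, float, float]  # (d, angle deg, dihedral deg)
    partner: AtomLocator | None = None

    def reconstruct(self, link_pos, nb1_pos, nb2_pos) -> np.ndarray:
        from .geometry import place_atom
        d, ang, dih = self.internal_coords
        return place_atom(nb2_pos, nb1_pos, link_pos, d, ang, dih)


@dataclass
class ProteinLigandComplex:
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    link_records: list[LinkRecord] = field(default_factory=list)
    target_lysine: tuple[str, int] | None = None  # (chain id, seqid)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(f"chain {chain_id} not found")

    @property
    def ligand(self) -> Residue:
        if not self.ligands:
            raise StructureError("complex has no ligand")
        return self.ligands[0]

    def lysine(self) -> Residue:
        if self.target_lysine is None:
            raise StructureError("no target lysine set")
        cid, seqid = self.target_lysine
        return self.chain(cid).residue(seqid)

    def protein_coords(self) -> np.ndarray:
        return np.concatenate([c.coords() for c in self.chains])

    def all_atoms(self) -> list[tuple[Residue, Atom]]:
        out = []
        for c in self.chains:
            for r in c.residues:
                out.extend((r, a) for a in r.atoms)
        for r in self.ligands:
            out.extend((r, a) for a in r.atoms)
        return out

    def copy(self) -> "ProteinLigandComplex":
        return ProteinLigandComplex(
            [c.copy() for c in self.chains],
            [r.copy() for r in self.ligands],
            list(self.link_records),
            self.target_lysine,
        )

    def validate(self) -> None:
        for res, atom in self.all_atoms():
            if not np.all(np.isfinite(atom.pos)):
                raise StructureError(f"non-finite coordinates at {res.chain_id}:{res.seqid}:{atom.name}")
        for link in self.link_records:
            for loc in (link.a, link.b):
                self._resolve(loc)
        if self.target_lysine is not None:
            lys = self.lysine()
            if lys.name != "LYS":
                raise StructureError("not a lysine")
            if not lys.has_atom("NZ"):
                raise StructureError("not a lysine: missing NZ atom")

    def _resolve(self, loc: AtomLocator) -> Atom:
        for c in self.chains:
            if c.id != loc.chain_id:
                continue
            for r in c.residues:
                if r.seqid == loc.seqid:
                    return r.atom(loc.atom_name)
        for r in self.ligands:
            if r.chain_id == loc.chain_id and r.seqid == loc.seqid:
                return r.atom(loc.atom_name)
        raise StructureError(f"link atom {loc} not found")


def _parse_res_id(res_id: str) -> tuple[str | None, int | None, str | None]:
    """Parse 'A:221' (chain:number) or a 3-letter residue code like 'LIG'."""
    if ":" in res_id:
        cid, num = res_id.split(":")
        return cid, int(num), None
    return None, None, res_id


def read_complex(pdb_text: str, ligand_id: str, lysine_id: str) -> ProteinLigandComplex:
    """Parse PDB text into a complex with the named ligand and target lysine.

    ``ligand_id`` is a 3-letter residue name or 'chain:resnum'; ``lysine_id``
    is 'chain:resnum'.  LINK records are retained.  Raises StructureError if a
    residue is missing or the named lysine is not a lysine with an NZ atom.
    """
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    if len(st) == 0:
        raise StructureError("no model in PDB")
    model = st[0]

    chains: list[Chain] = []
    ligands: list[Residue] = []
    lig_chain, lig_num, lig_name = _parse_res_id(ligand_id)

    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gres.name, gres.seqid.num, gchain.name)
            for ga in gres:
                if ga.altloc not in ("", "\x00", "A"):
                    logger.warning("dropping altloc %r atom %s in %s:%d",
                                   ga.altloc, ga.name, gchain.name, gres.seqid.num)
                    continue
                res.atoms.append(Atom(ga.name, ga.element.name.upper(),
                                      np.array([ga.pos.x, ga.pos.y, ga.pos.z])))
            if not res.atoms:
                continue
            is_lig = (res.name == lig_name if lig_name else
                      (gchain.name == lig_chain and res.seqid == lig_num))
            if is_lig:
                ligands.append(res)
            elif res.name in AMINO_ACIDS:
                chain.residues.append(res)
            # non-polymer residues that are not the requested ligand are dropped
        if chain.residues:
            chains.append(chain)

    if not ligands:
        raise StructureError(f"residue not found: ligand {ligand_id!r}")

    links: list[LinkRecord] = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Covale and con.type != gemmi.ConnectionType.Unknown:
            continue
        loc_a = AtomLocator(con.partner1.chain_name, con.partner1.res_id.seqid.num,
                            con.partner1.res_id.name, con.partner1.atom_name)
        loc_b = AtomLocator(con.partner2.chain_name, con.partner2.res_id.seqid.num,
                            con.partner2.res_id.name, con.partner2.atom_name)
        links.append(LinkRecord(loc_a, loc_b, con.reported_distance))

    lys_chain, lys_num, _ = _parse_res_id(lysine_id)
    if lys_chain is None:
        raise StructureError("lysine_id must be 'chain:resnum'")

    cplx = ProteinLigandComplex(chains, ligands, links, (lys_chain, lys_num))
    try:
        lys = cplx.lysine()
    except StructureError:
        raise StructureError(f"residue not found: lysine {lysine_id!r}")
    if lys.name != "LYS" or not lys.has_atom("NZ"):
        raise StructureError("not a lysine")

    # fill in measured distances for LINK records missing them
    for link in cplx.link_records:
        if link.distance is None or link.distance == 0.0:
            try:
                pa = cplx._resolve(link.a).pos
                pb = cplx._resolve(link.b).pos
                link.distance = float(np.linalg.norm(pa - pb))
            except StructureError:
                pass
        if link.distance and link.irregular:
            logger.warning("irregular covalent bond length %.2f A in LINK %s-%s",
                           link.distance, link.a.atom_name, link.b.atom_name)
    cplx.validate()
    return cplx


def trim_to_pocket(cplx: ProteinLigandComplex, cutoff: float = 10.0,
                   drop_ligand: bool = False) -> ProteinLigandComplex:
    """Keep only chains with at least one atom within ``cutoff`` of the ligand.

    Optionally removes the template ligand itself (``drop_ligand``), as done
    before docking a covalent analog into the emptied pocket.
    """
    lig_xyz = cplx.ligand.coords()
    kept: list[Chain] = []
    for chain in cplx.chains:
        xyz = chain.coords()
        d2 = np.min(np.sum((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=2))
        if d2 <= cutoff ** 2:
            kept.append(chain.copy())
    if not kept:
        raise StructureError("empty pocket: no chain within cutoff of the ligand")
    target = cplx.target_lysine
    if target is not None and not any(c.id == target[0] for c in kept):
        target = None
    ligands = [] if drop_ligand else [r.copy() for r in cplx.ligands]
    kept_ids = {c.id for c in kept}
    links = [l for l in cplx.link_records
             if (l.a.chain_id in kept_ids or any(r.chain_id == l.a.chain_id for r in ligands))
             and (l.b.chain_id in kept_ids or any(r.chain_id == l.b.chain_id for r in ligands))]
    return ProteinLigandComplex(kept, ligands, links, target)


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, hetatm: bool) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name = atom.name
    # PDB atom-name justification: element right-aligned in cols 13-14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.pos
    return (f"{record}{serial:5d} {name:<4s}{res.name:>4s} {res.chain_id:1s}"
            f"{res.seqid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {atom.element:>2s}")


def write_model(cplx: ProteinLigandComplex, pose: np.ndarray | None = None) -> str:
    """Write the complex as PDB text; ``pose`` optionally replaces all
    coordinates (same atom order and count as ``all_atoms``).

    LINK records are emitted for covalent connections, and CONECT records for
    ligand-protein covalent bonds.
    """
    entries = cplx.all_atoms()
    if not entries:
        raise StructureError("empty complex")
    if pose is not None:
        pose = np.asarray(pose, dtype=float)
        if pose.shape != (len(entries), 3):
            raise StructureError(
                f"pose atom count mismatch: {pose.shape} vs {len(entries)} atoms")
    lines = []
    for link in cplx.link_records:
        la, lb = link.a, link.b
        dist = link.distance if link.distance else 0.0
        lines.append(
            f"LINK        {la.atom_name:<4s}{la.res_name:>4s} {la.chain_id}{la.seqid:4d}"
            f"                {lb.atom_name:<4s}{lb.res_name:>4s} {lb.chain_id}{lb.seqid:4d}"
            f"     1555   1555 {dist:5.2f}")
    serials: dict[int, int] = {}
    serial = 0
    lig_ids = {id(r) for r in cplx.ligands}
    for i, (res, atom) in enumerate(entries):
        serial += 1
        serials[id(atom)] = serial
        a = atom if pose is None else Atom(atom.name, atom.element, pose[i])
        lines.append(_pdb_atom_line(serial, a, res, hetatm=id(res) in lig_ids))
    # CONECT for covalent ligand links
    for link in cplx.link_records:
        try:
            aa = cplx._resolve(link.a)
            ab = cplx._resolve(link.b)
        except StructureError:
            continue
        sa, sb = serials.get(id(aa)), serials.get(id(ab))
        if sa and sb:
            lines.append(f"CONECT{sa:5d}{sb:5d}")
            lines.append(f"CONECT{sb:5d}{sa:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
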