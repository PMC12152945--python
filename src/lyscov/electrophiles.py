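"""Virtual library of lysine-targeting electrophilic analogs.

Given a template ligand, each reaction from the library installs a warhead at
every eligible aromatic position, producing the analog directly in its
*reacted* (covalent adduct) form, including stub atoms for the lysine N-zeta
and C-epsilon so that the covalent geometry is carried by the molecule itself.

Rules mirrored from the design protocol:
  - existing single, non-ring substituents on a reacting position are removed
    (replaced by the warhead);
  - any product that would require breaking or deleting a template ring bond
    is excluded;
  - products are deduplicated by canonical isomeric SMILES per reaction.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .structures import ConnectionSpec

RDLogger.DisableLog("rdApp.warning")

PLAUSIBLE_BOND_RANGE = (1.2, 1.7)
_EMBED_SEED = 20251  # fixed: analog embedding must be a pure function


class ChemistryError(ValueError):
    pass


@dataclass
class ReactionSpec:
    """A reacted-form warhead installation reaction."""
    name: str
    smarts: str
    site_smarts: str
    link_atom_map: int
    nz_map: int
    ce_map: int
    warhead_atom_maps: list[int] = field(default_factory=list)

    def reaction(self):
        return AllChem.ReactionFromSmarts(self.smarts)


@dataclass
class CovalentAnalog:
    """A derivatized ligand in reacted form, with lysine stub atoms."""
    molecule: Chem.Mol
    parent: Chem.Mol
    reaction: str
    site: tuple[int, ...]            # template atom indices that were derivatized
    link_idx: int                    # analog atom bonded to N-zeta
    nz_idx: int
    ce_idx: int
    warhead_idxs: tuple[int, ...]
    removed: tuple[tuple[int, tuple[int, ...]], ...] = ()  # (site atom, branch atoms) in template indexing
    smiles: str = ""
    site_ordered: tuple[int, ...] = ()   # site in reaction-map order (warhead position first)
    parent_map: dict[int, int] = field(default_factory=dict)  # analog atom -> template atom

    def core(self) -> Chem.Mol:
        """Analog minus warhead and stub atoms (the retained template core)."""
        drop = set(self.warhead_idxs) | {self.nz_idx, self.ce_idx}
        rw = Chem.RWMol(self.molecule)
        for i in sorted(drop, reverse=True):
            rw.RemoveAtom(i)
        m = rw.GetMol()
        Chem.SanitizeMol(m)
        return m


def load_reaction_library(path: str | None = None) -> list[ReactionSpec]:
    """Load reactions from YAML (default: the built-in two-warhead library)."""
    if path is None:
        text = (importlib.resources.files("lyscov") / "data" / "reactions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    return [ReactionSpec(name=k, **v) for k, v in data.items()]


def _branch_atoms(mol: Chem.Mol, start: int, blocked: int) -> set[int]:
    """Atoms reachable from ``start`` without passing through ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nb.GetIdx()
            if j not in seen:
                seen.add(j)
                stack.append(j)
    seen.discard(blocked)
    return seen


def _strip_substituents(template: Chem.Mol, site: tuple[int, ...]):
    """Remove single non-ring heavy substituents at the site atoms.

    Returns (variant molecule, variant_idx -> template_idx list, removed info)
    or None when a site atom carries an un-removable substituent (a ring bond
    or a branch that itself contains ring atoms, whose removal would delete
    template ring bonds).
    """
    to_remove: set[int] = set()
    removed_info: list[tuple[int, tuple[int, ...]]] = []
    for s in site:
        atom = template.GetAtomWithIdx(s)
        subs = []
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() <= 1:
                continue
            bond = template.GetBondBetweenAtoms(s, nb.GetIdx())
            if bond.IsInRing():
                continue
            subs.append(nb.GetIdx())
        if len(subs) > 1:
            return None
        for sub in subs:
            branch = _branch_atoms(template, sub, s)
            if any(template.GetAtomWithIdx(i).IsInRing() for i in branch):
                return None  # removing this branch would delete template ring bonds
            if branch & set(site):
                return None
            to_remove |= branch
            removed_info.append((s, tuple(sorted(branch))))
    rw = Chem.RWMol(template)
    old_to_new = {}
    keep = [i for i in range(template.GetNumAtoms()) if i not in to_remove]
    for i in sorted(to_remove, reverse=True):
        rw.RemoveAtom(i)
    for new, old in enumerate(keep):
        old_to_new[old] = new
    variant = rw.GetMol()
    Chem.SanitizeMol(variant)
    new_to_old = {v: k for k, v in old_to_new.items()}
    return variant, new_to_old, tuple(removed_info)


def _product_analog(prod: Chem.Mol, spec: ReactionSpec, template: Chem.Mol,
                    site_template: tuple[int, ...], new_to_old: dict[int, int],
                    removed) -> CovalentAnalog | None:
    try:
        Chem.SanitizeMol(prod)
    except Exception:
        return None
    by_map: dict[int, int] = {}
    reacted_variant_idx: list[int] = []
    parent_map: dict[int, int] = {}
    for a in prod.GetAtoms():
        if a.HasProp("react_atom_idx"):
            parent_map[a.GetIdx()] = new_to_old[a.GetIntProp("react_atom_idx")]
        if a.HasProp("old_mapno"):
            by_map[a.GetIntProp("old_mapno")] = a.GetIdx()
            if a.HasProp("react_atom_idx"):
                reacted_variant_idx.append(a.GetIntProp("react_atom_idx"))
    needed = {spec.link_atom_map, spec.nz_map, spec.ce_map}
    if not needed <= set(by_map):
        return None
    # the reaction must have fired exactly at the requested site
    fired = tuple(sorted(new_to_old[i] for i in reacted_variant_idx))
    if fired != tuple(sorted(site_template)):
        return None
    # site in reactant-map order: map 1 is the warhead-bearing position
    site_maps = sorted(m for m in by_map if m < 10)
    site_ordered = tuple(parent_map[by_map[m]] for m in site_maps)
    smiles = Chem.MolToSmiles(prod)
    return CovalentAnalog(
        molecule=prod,
        parent=template,
        reaction=spec.name,
        site=tuple(sorted(site_template)),
        link_idx=by_map[spec.link_atom_map],
        nz_idx=by_map[spec.nz_map],
        ce_idx=by_map[spec.ce_map],
        warhead_idxs=tuple(by_map[m] for m in spec.warhead_atom_maps if m in by_map),
        removed=removed,
        smiles=smiles,
        site_ordered=site_ordered,
        parent_map=parent_map,
    )


def enumerate_analogs(template: Chem.Mol,
                      reactions: list[ReactionSpec] | None = None) -> list[CovalentAnalog]:
    """Enumerate unique covalent analogs of the template over the reaction
    library: one analog per unique (reaction, product) after canonical
    deduplication.  Deterministic and independent of input atom order.
    """
    if template is None:
        raise ChemistryError("invalid molecule")
    template = Chem.Mol(template)
    try:
        Chem.SanitizeMol(template)
    except Exception as exc:
        raise ChemistryError(f"invalid molecule: {exc}") from exc
    template = Chem.RemoveHs(template)
    if reactions is None:
        reactions = load_reaction_library()

    out: dict[tuple[str, str], CovalentAnalog] = {}
    for spec in reactions:
        rxn = spec.reaction()
        site_q = Chem.MolFromSmarts(spec.site_smarts)
        sites = set()
        for match in template.GetSubstructMatches(site_q, uniquify=False):
            sites.add(tuple(match))
        for site in sorted(sites):
            stripped = _strip_substituents(template, site)
            if stripped is None:
                continue
            variant, new_to_old, removed = stripped
            for prod_tuple in rxn.RunReactants((variant,)):
                analog = _product_analog(prod_tuple[0], spec, template, site,
                                         new_to_old, removed)
                if analog is None:
                    continue
                key = (spec.name, analog.smiles)
                if key not in out:
                    out[key] = analog
    return sorted(out.values(), key=lambda a: (a.reaction, a.smiles, a.site))


def make_adduct(analog: CovalentAnalog) -> tuple[Chem.Mol, ConnectionSpec]:
    """Convert an analog to its docking form: drop the C-epsilon stub and keep
    the N-zeta as a typed virtual-site marker whose ideal position is recorded
    as internal coordinates in the ConnectionSpec.

    Pure function: a fixed embedding seed makes repeated calls identical.
    """
    mol = Chem.Mol(analog.molecule)
    for needed in (analog.nz_idx, analog.ce_idx):
        if needed >= mol.GetNumAtoms():
            raise ChemistryError("missing stub atoms")
    if mol.GetAtomWithIdx(analog.nz_idx).GetSymbol() != "N":
        raise ChemistryError("missing stub atoms: N-zeta is not nitrogen")

    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=_EMBED_SEED) != 0:
        raise ChemistryError("embedding failed")
    # MMFF reproduces imine and sulfonamide bond lengths better than UFF
    if AllChem.MMFFHasAllMoleculeParams(molh):
        AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    else:
        AllChem.UFFOptimizeMolecule(molh, maxIters=500)
    mol3d = Chem.RemoveHs(molh)
    conf = mol3d.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol3d.GetNumAtoms())])

    link, nz = analog.link_idx, analog.nz_idx
    # reference frame: link atom and two chained heavy neighbors
    nb1 = min(j.GetIdx() for j in mol3d.GetAtomWithIdx(link).GetNeighbors()
              if j.GetIdx() != nz and j.GetAtomicNum() > 1)
    nb2 = min(j.GetIdx() for j in mol3d.GetAtomWithIdx(nb1).GetNeighbors()
              if j.GetIdx() != link and j.GetAtomicNum() > 1)
    from .geometry import bond_angle, dihedral_angle, distance
    d = distance(xyz[nz], xyz[link])
    ang = bond_angle(xyz[nb1], xyz[link], xyz[nz])
    dih = dihedral_angle(xyz[nb2], xyz[nb1], xyz[link], xyz[nz])
    lo, hi = PLAUSIBLE_BOND_RANGE
    if not (lo <= d <= hi):
        raise ChemistryError(f"implausible covalent bond length {d:.2f} A")

    rw = Chem.RWMol(mol3d)
    rw.RemoveAtom(analog.ce_idx)
    adduct = rw.GetMol()
    nz_atom = adduct.GetAtomWithIdx(nz - 1 if nz > analog.ce_idx else nz)
    nz_atom.SetNumExplicitHs(0)
    nz_atom.SetNoImplicit(False)
    Chem.SanitizeMol(adduct)

    def shift(i: int) -> int:
        return i - 1 if i > analog.ce_idx else i

    nz_new = shift(nz)
    adduct.GetAtomWithIdx(nz_new).SetBoolProp("virtual_site", True)
    adduct.SetIntProp("nz_idx", nz_new)
    adduct.SetIntProp("link_idx", shift(link))
    spec = ConnectionSpec(
        ligand_link_atom=str(shift(link)),
        ref_atoms=(str(shift(link)), str(shift(nb1)), str(shift(nb2))),
        internal_coords=(d, ang, dih),
    )
    return adduct, spec
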