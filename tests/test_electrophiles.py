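"""Analog enumeration against an independent RWMol-surgery oracle."""
import numpy as np
import pytest
from rdkit import Chem

from lyscov.electrophiles import (ChemistryError, enumerate_analogs,
                                  load_reaction_library, make_adduct)


def _branch(mol, start, blocked):
    seen = {blocked, start}
    stack = [start]
    while stack:
        i = stack.pop()
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetIdx() not in seen:
                seen.add(nb.GetIdx())
                stack.append(nb.GetIdx())
    seen.discard(blocked)
    return seen


def _eligible(mol, idx):
    """Site atom eligibility + atoms to delete, or None."""
    atom = mol.GetAtomWithIdx(idx)
    if not (atom.GetIsAromatic() and atom.GetSymbol() == "C"):
        return None
    subs = [nb.GetIdx() for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() > 1
            and not mol.GetBondBetweenAtoms(idx, nb.GetIdx()).IsInRing()]
    if len(subs) > 1:
        return None
    if atom.GetTotalNumHs() == 0 and not subs:
        return None   # ring-fusion position: nothing to displace
    delete = set()
    for s in subs:
        br = _branch(mol, s, idx)
        if any(mol.GetAtomWithIdx(i).IsInRing() for i in br):
            return None
        delete |= br
    return delete


def _attach_sulfonamide(mol, site):
    rw = Chem.RWMol(mol)
    s = rw.AddAtom(Chem.Atom(16))
    o1 = rw.AddAtom(Chem.Atom(8))
    o2 = rw.AddAtom(Chem.Atom(8))
    n = rw.AddAtom(Chem.Atom(7))
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(site, s, Chem.BondType.SINGLE)
    rw.AddBond(s, o1, Chem.BondType.DOUBLE)
    rw.AddBond(s, o2, Chem.BondType.DOUBLE)
    rw.AddBond(s, n, Chem.BondType.SINGLE)
    rw.AddBond(n, c, Chem.BondType.SINGLE)
    return rw


def _attach_imine_phenol(mol, site_a, site_b):
    rw = Chem.RWMol(mol)
    c4a = rw.AddAtom(Chem.Atom(6))
    n = rw.AddAtom(Chem.Atom(7))
    ce = rw.AddAtom(Chem.Atom(6))
    o = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(site_a, c4a, Chem.BondType.SINGLE)
    rw.AddBond(c4a, n, Chem.BondType.DOUBLE)
    rw.AddBond(n, ce, Chem.BondType.SINGLE)
    rw.AddBond(site_b, o, Chem.BondType.SINGLE)
    return rw


def oracle_products(smiles: str, reaction: str) -> set[str]:
    """Brute-force site enumeration with canonical dedup, built by direct
    molecular surgery (independent of the SMARTS-reaction implementation)."""
    mol = Chem.MolFromSmiles(smiles)
    out = set()
    n = mol.GetNumAtoms()
    if reaction == "aryl-sulfonyl-fluoride":
        sites = [(i,) for i in range(n)]
    else:
        sites = [(i, j.GetIdx()) for i in range(n)
                 for j in mol.GetAtomWithIdx(i).GetNeighbors()
                 if mol.GetBondBetweenAtoms(i, j.GetIdx()).GetIsAromatic()]
    for site in sites:
        deletes = set()
        ok = True
        for idx in site:
            d = _eligible(mol, idx)
            if d is None or d & set(site):
                ok = False
                break
            deletes |= d
        if not ok:
            continue
        rw = Chem.RWMol(mol)
        mapping = {i: i for i in range(n)}
        for i in sorted(deletes, reverse=True):
            rw.RemoveAtom(i)
            mapping = {old: (new - 1 if new > i else new)
                       for old, new in mapping.items() if old != i}
        try:
            if reaction == "aryl-sulfonyl-fluoride":
                rw2 = _attach_sulfonamide(rw.GetMol(), mapping[site[0]])
            else:
                rw2 = _attach_imine_phenol(rw.GetMol(), mapping[site[0]],
                                           mapping[site[1]])
            prod = rw2.GetMol()
            Chem.SanitizeMol(prod)
            out.add(Chem.MolToSmiles(prod))
        except Exception:
            continue
    return out


AROMATIC_SET = [
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "COc1ccccc1",
    "Cc1ccc(C)cc1", "Cc1cccc(C)c1", "c1ccc2ccccc2c1", "c1ccncc1",
    "Cc1ccncc1", "CCc1ccccc1", "Clc1ccccc1", "Cc1ccc(O)cc1",
]


class TestEnumerationOracle:
    @pytest.mark.parametrize("reaction", ["aryl-sulfonyl-fluoride", "salicylaldehyde"])
    @pytest.mark.parametrize("smiles", AROMATIC_SET)
    def test_matches_surgery_oracle(self, smiles, reaction, reaction_library):
        mol = Chem.MolFromSmiles(smiles)
        analogs = enumerate_analogs(
            mol, [r for r in reaction_library if r.name == reaction])
        got = {a.smiles for a in analogs}
        assert got == oracle_products(smiles, reaction)

    def test_benzene_single_sulfonyl_fluoride_analog(self, reaction_library):
        analogs = enumerate_analogs(
            Chem.MolFromSmiles("c1ccccc1"),
            [r for r in reaction_library if r.name == "aryl-sulfonyl-fluoride"])
        assert len(analogs) == 1

    def test_non_aromatic_template_yields_nothing(self, reaction_library):
        assert enumerate_analogs(Chem.MolFromSmiles("C1CCCCC1"),
                                 reaction_library) == []

    def test_invalid_template_rejected(self, reaction_library):
        with pytest.raises(ChemistryError, match="invalid molecule"):
            enumerate_analogs(None, reaction_library)


class TestAnalogInvariants:
    @pytest.mark.parametrize("smiles", ["Cc1ccccc1", "Oc1ccc(C)cc1", "c1ccc2ccccc2c1"])
    def test_core_isomorphic_to_template_subgraph(self, smiles, reaction_library):
        mol = Chem.MolFromSmiles(smiles)
        for analog in enumerate_analogs(mol, reaction_library):
            core = analog.core()
            assert mol.HasSubstructMatch(core)
            # every template ring bond survives in the analog
            tmpl_rings = mol.GetRingInfo().BondRings()
            ana_rings = analog.molecule.GetRingInfo().BondRings()
            assert sum(len(r) for r in ana_rings) >= sum(len(r) for r in tmpl_rings)

    def test_enumeration_order_independent_of_atom_numbering(self, reaction_library):
        base = Chem.MolFromSmiles("Cc1ccc(O)cc1")
        renum = Chem.RenumberAtoms(base, list(reversed(range(base.GetNumAtoms()))))
        a = {x.smiles for x in enumerate_analogs(base, reaction_library)}
        b = {x.smiles for x in enumerate_analogs(renum, reaction_library)}
        assert a == b

    def test_substituent_removal_recorded(self, reaction_library):
        analogs = enumerate_analogs(
            Chem.MolFromSmiles("Cc1ccccc1"),
            [r for r in reaction_library if r.name == "aryl-sulfonyl-fluoride"])
        removed = [a for a in analogs if a.removed]
        assert len(removed) == 1           # warhead replacing the methyl
        site, branch = removed[0].removed[0]
        assert len(branch) == 1            # the methyl carbon


class TestMakeAdduct:
    def test_imine_virtual_site_distance(self, sa_adduct):
        _, adduct, conn = sa_adduct
        assert 1.25 <= conn.internal_coords[0] <= 1.35

    def test_sulfonamide_virtual_site_distance(self, toluene3d, reaction_library):
        from lyscov.electrophiles import enumerate_analogs
        analogs = enumerate_analogs(
            toluene3d, [r for r in reaction_library if r.name == "aryl-sulfonyl-fluoride"])
        _, conn = make_adduct(analogs[0])
        assert 1.55 <= conn.internal_coords[0] <= 1.70

    def test_pure_function(self, sa_adduct):
        analog, adduct, conn = sa_adduct
        adduct2, conn2 = make_adduct(analog)
        assert Chem.MolToSmiles(adduct2) == Chem.MolToSmiles(adduct)
        assert conn2.internal_coords == conn.internal_coords
        xyz1 = adduct.GetConformer().GetPositions()
        xyz2 = adduct2.GetConformer().GetPositions()
        assert np.array_equal(xyz1, xyz2)

    def test_missing_stub_rejected(self, sa_adduct):
        import dataclasses
        analog, _, _ = sa_adduct
        broken = dataclasses.replace(analog, nz_idx=analog.link_idx)
        with pytest.raises(ChemistryError, match="stub"):
            make_adduct(broken)
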