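"""Ideal residue geometry: backbone strands, lysine side chains.

Bond lengths/angles are standard amino-acid values (angstroms, degrees).
Used by the synthetic pocket generator, the docking side-chain moves and the
modified-lysine templates.
"""
from __future__ import annotations

import numpy as np

from .geometry import place_atom

# backbone ideal geometry
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8

# lysine side chain: (atom, (a, b, c), distance, angle, chi index or fixed dihedral)
# place_atom(a, b, c, d, ang, dih) -> angle b-c-X, torsion a-b-c-X
LYS_SIDECHAIN = [
    ("CB", ("N", "C", "CA"), 1.530, 110.5, ("fixed", 122.6)),
    ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0)),
    ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 1)),
    ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 2)),
    ("NZ", ("CG", "CD", "CE"), 1.470, 111.9, ("chi", 3)),
]


def build_sidechain(backbone: dict[str, np.ndarray], chis: list[float],
                    zmat=LYS_SIDECHAIN) -> dict[str, np.ndarray]:
    """Build side-chain Cartesian coordinates from backbone N/CA/C and chi
    angles using the internal-coordinate table ``zmat``."""
    coords = dict(backbone)
    for name, (a, b, c), d, ang, dih_spec in zmat:
        kind, val = dih_spec
        if kind == "chi":
            dih = chis[val]
        elif kind == "pchi":
            dih = chis[val]
        else:
            dih = val
        coords[name] = place_atom(coords[a], coords[b], coords[c], d, ang, dih)
    return {name: coords[name] for name, *_ in zmat}


def build_strand(n_res: int, phi: float = -120.0, psi: float = 120.0,
                 omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Extended backbone strand of ``n_res`` residues (N, CA, C, O per residue)
    in a local frame, built residue by residue with ideal geometry."""
    residues: list[dict[str, np.ndarray]] = []
    # seed frame for the first residue
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([N_CA, 0.0, 0.0])
    c = place_atom(np.array([-1.0, 1.0, 0.0]), n, ca, CA_C, ANG_N_CA_C, phi)
    for i in range(n_res):
        res = {"N": n, "CA": ca, "C": c}
        if i + 1 < n_res:
            n_next = place_atom(res["N"], res["CA"], res["C"], C_N, ANG_CA_C_N, psi)
            o = place_atom(n_next, res["CA"], res["C"], C_O, ANG_CA_C_O, 180.0)
            res["O"] = o
            ca_next = place_atom(res["CA"], res["C"], n_next, N_CA, ANG_C_N_CA, omega)
            c_next = place_atom(res["C"], n_next, ca_next, CA_C, ANG_N_CA_C, phi)
            residues.append(res)
            n, ca, c = n_next, ca_next, c_next
        else:
            res["O"] = place_atom(res["N"], res["CA"], res["C"], C_O, ANG_CA_C_O, psi + 180.0)
            residues.append(res)
    return residues


def add_cb(res: dict[str, np.ndarray]) -> np.ndarray:
    """Ideal CB position from backbone N/CA/C (alanine and lysine alike)."""
    return place_atom(res["N"], res["C"], res["CA"], 1.530, 110.5, 122.6)


def transform_coords(coords: dict[str, np.ndarray] | list[dict[str, np.ndarray]],
                     R: np.ndarray, t: np.ndarray):
    """Apply a rigid transform x -> R @ x + t to residue coordinate dicts."""
    if isinstance(coords, dict):
        return {k: R @ v + t for k, v in coords.items()}
    return [{k: R @ v + t for k, v in r.items()} for r in coords]
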