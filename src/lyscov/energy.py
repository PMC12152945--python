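"""Simplified all-atom interaction potential used for docking and rotamer
scoring.

This is a documented, deterministic stand-in potential with three terms,
evaluated over heavy-atom pairs between two atom groups:

  steric/dispersion (12-6):  E_lj = eps * ((rm/d)^12 - 2 (rm/d)^6)  for d < 6 A,
      with rm = r_i + r_j (element vdW radii) and d clamped below 0.55*rm so
      clashes give large finite energies (soft-sphere repulsion);

  hydrogen bond:  for N/O pairs at 2.5-3.5 A,
      E_hb = -w_hb * exp(-((d - d0)/sigma)^2) * f_i * f_j,
      where f is an angular factor: the cosine of the angle between the polar
      atom's bond direction (heavy neighbor -> atom) and the line to the
      partner, clamped to [0, 1] (favoring roughly linear geometries);

  plus, in docking, the covalent constraint score with weight w_cst.

Units are arbitrary "energy units" of kcal/mol scale.  A pairwise sum of this
form is exactly reproducible by an explicit double loop, which the test suite
uses as an oracle.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "F": 1.47,
    "P": 1.80, "CL": 1.75, "BR": 1.85, "H": 1.10,
}
DEFAULT_RADIUS = 1.70
LJ_EPS = 0.10
LJ_CUTOFF = 6.0
CLAMP_FRACTION = 0.55
HB_WEIGHT = 1.5
HB_D0 = 2.9
HB_SIGMA = 0.35
HB_RANGE = (2.5, 3.5)
CLASH_ENERGY = 25.0   # a group pair-sum above this is considered clashing

POLAR_ELEMENTS = {"N", "O"}


def radius_of(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def radii_for(elements) -> np.ndarray:
    return np.array([radius_of(e) for e in elements])


def polar_mask(elements) -> np.ndarray:
    return np.array([e.upper() in POLAR_ELEMENTS for e in elements])


class AtomGroup:
    """Coordinates + element data for one side of a pairwise energy.

    ``polar_dir`` (optional, unit vectors) is the direction from each polar
    atom's bonded heavy neighbor to the atom, used by the hydrogen-bond
    angular factor; rows for apolar atoms are ignored.
    """

    def __init__(self, xyz: np.ndarray, elements: list[str],
                 polar_dir: np.ndarray | None = None):
        self.xyz = np.asarray(xyz, dtype=float)
        self.elements = [e.upper() for e in elements]
        self.radii = radii_for(self.elements)
        self.polar = polar_mask(self.elements)
        self.polar_dir = polar_dir

    def moved(self, xyz: np.ndarray, polar_dir: np.ndarray | None = None) -> "AtomGroup":
        g = AtomGroup.__new__(AtomGroup)
        g.xyz = np.asarray(xyz, dtype=float)
        g.elements = self.elements
        g.radii = self.radii
        g.polar = self.polar
        g.polar_dir = polar_dir if polar_dir is not None else self.polar_dir
        return g


def pair_energy(a: AtomGroup, b: AtomGroup,
                exclude: np.ndarray | None = None) -> float:
    """Total interaction energy between two atom groups.

    ``exclude`` is an optional boolean matrix (len(a), len(b)); True pairs are
    skipped (used for atoms adjacent through the covalent link).
    """
    if len(a.xyz) == 0 or len(b.xyz) == 0:
        return 0.0
    d = cdist(a.xyz, b.xyz)
    rm = a.radii[:, None] + b.radii[None, :]
    within = d < LJ_CUTOFF
    if exclude is not None:
        within &= ~exclude
    dc = np.maximum(d, CLAMP_FRACTION * rm)
    x6 = (rm / dc) ** 6
    e_lj = LJ_EPS * (x6 * x6 - 2.0 * x6)
    energy = float(np.sum(e_lj[within]))

    hb_pairs = within & a.polar[:, None] & b.polar[None, :] \
        & (d > HB_RANGE[0]) & (d < HB_RANGE[1])
    if np.any(hb_pairs):
        ii, jj = np.nonzero(hb_pairs)
        g = np.exp(-(((d[ii, jj] - HB_D0) / HB_SIGMA) ** 2))
        fa = np.ones(len(ii))
        fb = np.ones(len(jj))
        if a.polar_dir is not None:
            v = b.xyz[jj] - a.xyz[ii]
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            fa = np.clip(np.sum(a.polar_dir[ii] * v, axis=1), 0.0, 1.0)
        if b.polar_dir is not None:
            v = a.xyz[ii] - b.xyz[jj]
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            fb = np.clip(np.sum(b.polar_dir[jj] * v, axis=1), 0.0, 1.0)
        energy += float(np.sum(-HB_WEIGHT * g * fa * fb))
    return energy


def pair_energy_batch(X: np.ndarray, radii_a: np.ndarray, polar_a: np.ndarray,
                      dirs_a: np.ndarray | None, b: AtomGroup,
                      exclude: np.ndarray | None = None) -> np.ndarray:
    """Vectorized ``pair_energy`` for a batch of poses of group A.

    ``X`` has shape (K, n, 3); ``dirs_a`` (K, n, 3) or None.  Returns (K,)
    energies, identical to calling pair_energy per pose.
    """
    X = np.asarray(X, dtype=float)
    K, n, _ = X.shape
    diff = X[:, :, None, :] - b.xyz[None, None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=3))          # (K, n, m)
    rm = radii_a[:, None] + b.radii[None, :]          # (n, m)
    within = d < LJ_CUTOFF
    if exclude is not None:
        within &= ~exclude[None, :, :]
    dc = np.maximum(d, CLAMP_FRACTION * rm[None])
    x6 = (rm[None] / dc) ** 6
    e_lj = LJ_EPS * (x6 * x6 - 2.0 * x6)
    energy = np.sum(np.where(within, e_lj, 0.0), axis=(1, 2))

    hb = within & polar_a[None, :, None] & b.polar[None, None, :] \
        & (d > HB_RANGE[0]) & (d < HB_RANGE[1])
    if np.any(hb):
        g = np.exp(-(((d - HB_D0) / HB_SIGMA) ** 2))
        fa = np.ones_like(d)
        fb = np.ones_like(d)
        dn = np.where(d > 1e-8, d, 1.0)
        if dirs_a is not None:
            # diff rows point a -> b after negation (diff = a - b)
            fa = np.clip(np.sum(dirs_a[:, :, None, :] * (-diff), axis=3) / dn, 0.0, 1.0)
        if b.polar_dir is not None:
            fb = np.clip(np.sum(b.polar_dir[None, None, :, :] * diff, axis=3) / dn, 0.0, 1.0)
        energy += np.sum(np.where(hb, -HB_WEIGHT * g * fa * fb, 0.0), axis=(1, 2))
    return energy


def polar_directions(xyz: np.ndarray, elements, bonds: list[tuple[int, int]]) -> np.ndarray:
    """Unit vector per atom from the mean of its bonded heavy neighbors to the
    atom (zeros for atoms with no neighbor)."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    dirs = np.zeros((n, 3))
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for i in range(n):
        nbs = neighbors.get(i)
        if not nbs:
            continue
        base = np.mean(xyz[nbs], axis=0)
        v = xyz[i] - base
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            dirs[i] = v / norm
    return dirs
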