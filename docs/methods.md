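# Methods

## Scope and model

`lyscov` proposes electrophile installation vectors that convert a known
reversible binder into a lysine-targeting covalent binder. Two warhead
chemistries ship by default, modeled in their *reacted* adduct forms:

- **salicylaldehyde** (2-hydroxybenzaldehyde): aldehyde + hydroxyl installed
  on two adjacent aryl carbons; the adduct is the Schiff base, a C=N imine to
  the lysine Nζ (the hydroxyl stabilizes the imine). The imine nitrogen is
  modeled neutral, the C=N configured E.
- **aryl sulfonyl fluoride**: SO₂F installed on one aryl carbon; the adduct
  is the sulfonamide (S–N bond, fluoride departed, neutral N).

The reaction library is a YAML of reacted-form SMARTS transformations with
mapped atoms marking the warhead, the lysine Nζ/Cε stubs, and the link atom;
users can extend it without touching code.

### Analog enumeration rules

A reacting aryl position must carry a hydrogen or a single non-ring
substituent; the substituent (whole branch) is removed before warhead
installation. Sites whose substituent branch contains ring atoms are
skipped: removing them would delete template ring bonds, and products
requiring ring-bond cleavage are excluded by construction. Products are
deduplicated per reaction by canonical isomeric SMILES, which makes the
enumeration deterministic and independent of input atom numbering.

### Covalent geometry as virtual sites

The adduct keeps the Nζ nitrogen as a typed virtual-site marker; its ideal
position is recorded as internal coordinates (bond length, angle, torsion)
relative to the link atom and two reference neighbors, measured on a
force-field-relaxed embedding of the analog (MMFF when parametrized, UFF
otherwise; fixed embedding seed so adduct construction is a pure function).
Covalent constraints are harmonic penalties, per pair ((d − 0)/0.3)², with
two reciprocal pairs:

1. lysine NZ ↔ the adduct's Nζ virtual site (distance directly);
2. ligand link atom ↔ the lysine-side virtual site. The torsion of that
   site about the CE–NZ axis is not specified by the chemistry, so the pair
   is evaluated at the nearest point of the ideal bond-length/angle circle
   around NZ (closed form). It therefore penalizes bond length and angle
   deviations and leaves the torsion free.

The attachment nitrogen is a real atom of the reacted adduct, so it is kept
in force-field energies; it is excluded from the conformer-dedup RMSD and
from steric docking terms (where it is a placeholder, not a collider).

## Conformer libraries

Up to 100 unconstrained and up to 100 MCS-constrained conformers per adduct
(ETKDG embedding, coordinate restraints to the template's crystallographic
MCS atoms for the constrained half), each UFF-minimized. Filters, applied in
generation order (constrained first): discard conformers whose UFF energy
exceeds the minimized template ligand's energy by more than 100 units, and
keep only conformers farther than 0.5 Å in-place heavy-atom RMSD from every
previously kept conformer. The template reference energy comes from
minimizing the template once under the same force field; the minimizer runs
to 500 iterations (RDKit default convergence).

The MCS (bond-order-insensitive, element-matched) embeds into the template
ambiguously whenever the template has symmetry; each conformer is aligned
under **every** symmetry image (up to 8), and the dedup filter removes the
redundant ones. Without this, adducts of symmetric templates can only be
aligned with the warhead on one of two equivalent ring positions, and the
docking would systematically miss the other.

## Simplified interaction potential

Docking and rotamer scoring use a documented three-term pairwise potential
over heavy atoms (arbitrary energy units of kcal/mol scale):

- 12-6 steric/dispersion with element vdW radii, cutoff 6 Å, distances
  clamped below 0.55·(rᵢ+rⱼ) so clashes are large but finite;
- a distance-and-angle hydrogen-bond term for N/O pairs at 2.5–3.5 Å:
  −1.5 · exp(−((d − 2.9)/0.35)²) scaled by the clamped cosines between each
  polar atom's bond direction and the line to its partner;
- the covalent constraint score with weight 1.

The interface score of a pose is the ligand's cross-interaction energy
(ligand–pocket + ligand–lysine-side-chain + weighted constraint), equal to
total(bound) − total(ligand removed); it is exactly reproducible by an
explicit double loop, which the test suite uses as an oracle. Pairs within
three topological bonds of the covalent link (and of the side-chain
attachment) are excluded from sterics, mirroring standard bonded-exclusion
practice.

This potential deliberately replaces a full biomolecular force field: the
protocols' contributions are the constraint construction, ranking and
selection logic, which are independent of the energy model's detail. The
energy model is versioned and pluggable.

## Ligand-side docking protocol

Pocket preparation: chains with no atom within 10 Å of the ligand are
removed, the template ligand is deleted, and the target-lysine side chain is
relaxed by torsion-space coordinate descent (tolerance 1e-5).

Each of `n_models` (default 100; the shipped benchmark uses 50 per fixture)
models: a random conformer is picked; half the trajectories start
template-aligned, half superpose the adduct's virtual site onto the lysine
NZ; the target lysine starts in its best rotamer-library state for the
initial placement (on-the-fly rotamer sampling of the nucleophile); then 300
Metropolis Monte-Carlo cycles at kT = 1 (40% rigid-body moves ≤ 0.5 Å /
≤ 5°, 30% conformer swaps, 30% lysine chi moves — half ±20° drifts, half
rotamer-well jumps), followed by gradient-free Powell minimization over the
six rigid degrees of freedom and four chi angles. Models are ranked by
interface score; the high-confidence rule asks for a top-10 model with
constraint < 2 and MCS RMSD < 1.5 Å.

## Protein-side rotamer scan

The modified lysine is built from ideal internal coordinates (standard bond
lengths/angles; aromatic ring closed planar; imine C=N 1.28 Å, sulfonamide
S–N 1.63 Å). Four canonical chis use a backbone-independent 3-state library
(gauche−/trans/gauche+ means with plausible marginal probabilities; rotamer
probability is the product of marginals; entries with zero probability are
excluded — a superset-safe variant of stopping at the first zero). The
warhead torsions are sampled on fixed grids: 30° for the two imine-linker
torsions; 60° for the CE–NZ and N–S torsions and 30° over [0°, 180°) for
the two-fold-symmetric S–aryl torsion of the sulfonamide. These grids are a
compromise between coverage and enumeration size (11 664 and 17 496
rotamers respectively).

Each rotamer is rebuilt in the pocket frame by exact NeRF chains (the
internal↔Cartesian round trip is tested to 1e-6 Å) and scored against the
10 Å neighborhood with the same potential (side chains of neighbors with
rotatable chis are relaxed first; the poly-Ala fixtures make this a no-op).
A vectorized batch path produces bit-identical scores to the scalar path
and is ~30× faster.

Ranking is by neighborhood score ascending with ties broken by rotamer
probability descending. For the top 10% of rotamers, the warhead ring is
compared against every similar ring (same size, same element multiset) of
the crystallographic ligand by symmetry-aware in-place ring RMSD; overlaps
below 1 Å emit an installation vector: the template atom matched to the
warhead-bearing ring atom.

### RMSD metrics

Both selection metrics are *in place* (no re-superposition): the protocols
compare conformations in the crystal frame, and superposition would hide
exactly the placement errors the rules are meant to catch. The ligand
metric minimizes over all symmetry-equivalent MCS embeddings; the ring
metric minimizes over all template rings of matching size/composition and
all adjacency-preserving cyclic/reflective index mappings. Heavy atoms
only. A Kabsch superposition helper exists as a utility but is never used
by the selection rules.

## Site mining

`scan_structure` emits one (lysine, ligand) pair per ligand atom within
8 Å of a lysine NZ, flags pairs already covalent (LINK record to that NZ),
and drops ligands under 10 heavy atoms (ions/solvent). Aromatic eligibility
is perceived from sidecar chemistry, never from PDB atom names; a
`phenyl_only` flag restricts to six-membered carbocycles. Redundancy
clustering is greedy single linkage: receptor global-alignment sequence
identity ≥ 0.90, then RDKit topological-fingerprint Tanimoto ≥ 0.6 within
a sequence cluster; representatives are chosen by resolution then lexical
id. Benchmark-style record filters require a single LINK record, a covalent
bond length within 1.0–1.8 Å (outside it the record is "irregular"), and a
terminal warhead: the link atom carries at most one single-bonded heavy
neighbor within the ligand, with double-bonded O/N counted as part of the
warhead unit.

## Synthetic fixtures: what they emulate and what they do not

The generator builds geometric poly-Ala/Gly pockets (10–60 residues)
*backwards from the answer*: a modified-lysine rotamer is drawn from the
library (warhead-to-ring torsion drawn from the adduct's own conformer
library, since force fields keep conjugated linkers near-planar and an
arbitrary grid torsion would be chemically unrealizable), its warhead ring
defines the pose of the planted aromatic ligand, and the pocket is
assembled around that pose: two 2-strand wall sheets flanking the ring
faces (cleft/walled) or a single floor strand (open), a rim collar of
single residues leaving openings for the ligand tail and the lysine linker,
one hydrogen-bond anchor complementing a polar ligand atom (the native
contact) and one complementing the warhead (acceptor carbonyl for the
salicylaldehyde hydroxyl, donor amide for a sulfonyl oxygen), and, for
walled pockets, side caps. The emitted complex carries the *stripped*
noncovalent ligand and an apo lysine rotamer with NZ 4–8 Å from the ligand;
the true analog, its ideal covalent pose and the planted torsions are
returned separately as the answer key.

Coordinate noise (default σ = 0.15 Å) is applied per rigid unit — a random
translation of scale σ and ~1° rotation per chain/ligand plus 0.35σ atomic
jitter — emulating model/crystallographic uncertainty while keeping local
geometry near-ideal, as refinement does. Purely independent atomic noise
would be amplified ~7-fold through side-chain rebuilding (a 9 Å lever arm
from the backbone frame to the warhead ring) and would make the
protein-side task artificially impossible near its 1 Å threshold.

These fixtures exercise every quantity the protocols measure — distances,
clashes, covalent geometry, symmetry-aware RMSD, ranking and selection — on
realistic length scales, but they are not folded proteins: passing the
recovery bars demonstrates the correctness and self-consistency of the
pipeline, not performance on real structures, where energy-model quality
and receptor flexibility dominate.

The shipped benchmark is 20 fixtures (seeds 100–119): warheads alternating,
shapes cycling cleft/cleft/cleft/walled/open, five phenol-type ligands plus
two fixtures with a decoy second aryl ring to stress ring matching.
Recovery is scored in three tiers per protocol (sampled, top-10 models /
top-10% rotamers, top-1), mirroring the selection rules.

## Numerical choices and determinism

- All randomness flows from explicit integer seeds; docking derives one
  Philox stream per model from (seed, model index), so runs are bit-identical
  for a fixed seed and models are independent of `n_models`.
- Conformer embedding uses fixed seeds (constrained and free halves offset);
  RDKit embedding is single-threaded for reproducibility.
- Tie-breaks: MCS embedding by lowest canonical-rank sum; rotamer ranking by
  probability descending; cluster representatives by resolution then id.
- Degenerate inputs: empty conformer sets, empty model lists, ring-less
  templates, unknown warheads and non-lysine targets raise typed errors with
  the messages tested in the suite; batch runs isolate per-analog failures.
- Benchmark problem sizes: 50 docking models per fixture and the full
  rotamer enumeration per scan; these sizes are the package's benchmark
  defaults and are stated in the acceptance script's output (`n` fields).

## Known limitations

- The interaction potential is a stand-in; absolute energies are not
  comparable to physics-based force fields, and solvation, polarization and
  backbone flexibility are absent.
- Warhead chemistry is limited to the two shipped reactions; reactivity/pKa
  prediction and synthesis feasibility are out of scope.
- The rotamer library is backbone-independent; no Dunbrack-style
  backbone-dependent statistics.
- mmCIF, multi-model NMR input and altloc ensembles (beyond keeping altloc
  A) are not supported.
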