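# Default lysine-targeting electrophile reactions, written as reacted-form
# (post-bond-formation) SMARTS transformations.  Mapped product atoms:
#   link_atom_map  - analog atom covalently bonded to the lysine N-zeta
#   nz_map         - the lysine N-zeta stub
#   ce_map         - the lysine C-epsilon stub
#   warhead_atom_maps - atoms introduced by the warhead (excluding stubs)
#
# salicylaldehyde: aldehyde + hydroxyl installed on two adjacent aryl carbons;
# modeled as the Schiff base (imine) adduct with the lysine amine.
# aryl-sulfonyl-fluoride: sulfonyl fluoride installed on an aryl carbon;
# modeled as the sulfonamide adduct (fluoride departed, SuFEx chemistry).
salicylaldehyde:
  smarts: "[cH:1][cH:2]>>[c:1]([CH:10]=[N:11][CH3:12])[c:2][OH:13]"
  site_smarts: "cc"
  link_atom_map: 10
  nz_map: 11
  ce_map: 12
  warhead_atom_maps: [10, 13]
aryl-sulfonyl-fluoride:
  smarts: "[cH:1]>>[c:1][S:10](=[O:13])(=[O:14])[NH1:11][CH3:12]"
  site_smarts: "c"
  link_atom_map: 10
  nz_map: 11
  ce_map: 12
  warhead_atom_maps: [10, 13, 14]
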