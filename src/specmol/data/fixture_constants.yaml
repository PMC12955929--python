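# Constants behind the synthetic fixture labels, version 1.
#
# Regression label = sum over functional groups of (coefficient x number of
# substructure matches of that group) + Gaussian noise.  Coefficients are
# deliberately spread in sign and magnitude so the signal is learnable but
# not trivially monotone in any single group.
version: 1
group_coefficients:
  carboxyl: -1.2
  ester: 0.8
  amide: 0.6
  nitro: -1.5
  nitrile: -0.9
  sulfonyl: -1.1
  phosphate: -1.4
  carbonyl: 0.5
  hydroxyl: 1.0
  ether: 0.4
  amine: 1.3
  thiol: 0.7
  halogen: -0.6
# Activity-cliff pairs: one substituent swap flips the label by this offset.
cliff_offset: 3.0
# Single-heavy-atom substituents; swapping low -> high adds cliff_offset.
cliff_low_substituents: [C, F]
cliff_high_substituents: [O, N, Cl]
# Templates: SMILES plus the 0-based atom index where the substituent bonds.
cliff_templates:
  - {smiles: "c1ccccc1CC", site: 0}
  - {smiles: "c1ccc2ccccc2c1", site: 0}
  - {smiles: "c1ccncc1C", site: 0}
  - {smiles: "CC(=O)Nc1ccccc1", site: 5}
  - {smiles: "c1ccccc1OC", site: 0}
  - {smiles: "C1CCCCC1CC", site: 0}
  - {smiles: "c1ccsc1C", site: 0}
  - {smiles: "c1ccoc1C", site: 0}
  - {smiles: "CCc1ccc(CN)cc1", site: 3}
  - {smiles: "c1ccccc1C(=O)OC", site: 0}
  - {smiles: "Cc1cccc(C)c1", site: 2}
  - {smiles: "c1ccccc1CCC", site: 2}
  - {smiles: "CC(C)c1ccccc1", site: 4}
  - {smiles: "c1ccccc1c1ccccc1", site: 0}
  - {smiles: "C1CCOC1C", site: 0}
  - {smiles: "c1ccccc1CNC", site: 2}
  - {smiles: "CCOc1ccccc1", site: 4}
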