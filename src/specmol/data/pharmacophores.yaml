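# Pharmacophore family pattern table, version 1.
#
# Families are multi-hot: an atom may belong to several families.  All atoms
# of a SMARTS match are flagged with that family.  The hydrophobe definition
# deliberately excludes short aliphatic fragments (an isolated ethane carbon
# is not a hydrophobic center); ring carbons, aromatic carbons, halogens on
# carbon and sp3 carbons embedded in a >=3-carbon chain qualify.
version: 1
families:
  - name: donor
    smarts:
      - "[NX3;!H0;+0;!$([NX3]=[OX1])]"
      - "[NX4;!H0;+1]"
      - "[OX2H]"
      - "[SX2H]"
      - "[nH]"
  - name: acceptor
    smarts:
      - "[OX2;+0;!$([OX2][NX3+])]"
      - "[OX1;+0;!$([OX1]~[NX3])]"
      - "[NX2;+0;!$([NX2]=[OX1])]"
      - "[NX1;+0]"
      - "[nX2;+0]"
      - "[NX3;H2,H1,H0;+0;!$([NX3]=[OX1]);!$([NX3][CX3]=[OX1]);!$([NX3]a)]"
  - name: hydrophobe
    smarts:
      - "[c]"
      - "[C;R]"
      - "[F,Cl,Br,I;$(*[#6])]"
      - "[CX4;$([CX4]([#6])[#6])]"
      - "[SX2;$([SX2]([#6])[#6])]"
  - name: aromatic
    smarts:
      - "[a]"
  - name: positive_ionizable
    smarts:
      - "[NX3;+0;!$([NX3]=[OX1]);!$([NX3][CX3]=[OX1]);!$([NX3]a);!$([NX3][SX4]);!$([NX3][PX4])]"
      - "[NX4;+1]"
  - name: negative_ionizable
    smarts:
      - "[CX3](=[OX1])[OX2H1,OX1-]"
      - "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]"
      - "[PX4](=[OX1])([OX2H1,OX1-])"
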