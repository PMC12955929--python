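# Functional-group vocabulary, version 1.
#
# Order IS priority: when an atom is covered by several matches it is
# annotated with the first listed group that matches it.  Groups are listed
# most-specific-first so that e.g. a carboxylic acid's O-H is labelled
# carboxyl, not hydroxyl.  Each group may list several SMARTS patterns; all
# atoms of a match are annotated.
version: 1
groups:
  - name: carboxyl
    smarts:
      - "[CX3](=[OX1])[OX2H1]"
      - "[CX3](=[OX1])[OX1-]"
  - name: ester
    smarts:
      - "[CX3](=[OX1])[OX2H0][#6]"
  - name: amide
    smarts:
      - "[CX3](=[OX1])[NX3]"
  - name: nitro
    smarts:
      - "[NX3+](=[OX1])[OX1-]"
      - "[NX3](=[OX1])=[OX1]"
  - name: nitrile
    smarts:
      - "[CX2]#[NX1]"
  - name: sulfonyl
    smarts:
      - "[SX4](=[OX1])(=[OX1])"
  - name: phosphate
    smarts:
      - "[PX4](=[OX1])"
  - name: carbonyl
    smarts:
      - "[CX3]=[OX1]"
  - name: hydroxyl
    smarts:
      - "[OX2H]"
  - name: ether
    smarts:
      - "[OX2H0]([#6])[#6]"
  - name: amine
    smarts:
      - "[NX3;!$([NX3]=[OX1]);!$([NX3][CX3]=[OX1]);!$([NX3+])]"
  - name: thiol
    smarts:
      - "[SX2H]"
  - name: halogen
    smarts:
      - "[F,Cl,Br,I]"
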