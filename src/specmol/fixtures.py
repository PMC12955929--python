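"""Deterministic synthetic molecules and labels for every test stage.

Everything here is generated in-process from shipped constants: a curated
drug-like SMILES set covering the full functional-group and pharmacophore
vocabularies, structure-derived regression/classification labels (so a model
can provably learn them), matched molecule pairs differing by one heavy-atom
substituent with a large fixed label jump (activity cliffs), and seeded
random graphs for the spectral test harness.

All randomness flows through NumPy's PCG64 generator with explicit seeds,
which is stable across platforms and NumPy releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from rdkit import Chem

from .molgraph import DatasetTable, Molecule, build_graph
from .multiview import _fg_vocabulary  # priority vocabulary, cached

logger = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "CliffPair", "fixture_smiles_set",
           "functional_group_counts", "structure_score", "synthetic_labels",
           "make_fixture_table", "cliff_pair_generator", "cliff_pairs_table",
           "random_graph"]

# Curated drug-like set; every functional group and pharmacophore family in
# the shipped vocabularies is represented (asserted by test).
_FIXTURE_SMILES = (
    "CC(=O)Oc1ccccc1C(=O)O",        # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",   # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",           # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",   # caffeine
    "Oc1ccccc1",                    # phenol
    "c1ccccc1",                     # benzene
    "CCO",                          # ethanol
    "CC(=O)O",                      # acetic acid
    "CN",                           # methylamine
    "CC(C)=O",                      # acetone
    "CCOCC",                        # diethyl ether
    "CCS",                          # ethanethiol
    "CC#N",                         # acetonitrile
    "O=[N+]([O-])c1ccccc1",         # nitrobenzene
    "NS(=O)(=O)c1ccccc1",           # benzenesulfonamide
    "CCOP(=O)(O)O",                 # ethyl phosphate
    "Clc1ccccc1",
    "Fc1ccccc1",
    "Brc1ccccc1",
    "Ic1ccccc1",
    "NCCc1ccccc1",                  # phenethylamine
    "OCCN",                         # ethanolamine
    "CC(N)C(=O)O",                  # alanine
    "NC(=O)c1ccccc1",               # benzamide
    "COc1ccccc1",                   # anisole
    "Cc1ccccc1",                    # toluene
    "CCCCCC",                       # hexane
    "C1CCCCC1",                     # cyclohexane
    "c1ccc2ccccc2c1",               # naphthalene
    "c1ccncc1",                     # pyridine
    "c1cc[nH]c1",                   # pyrrole
    "c1ccsc1",                      # thiophene
    "c1ccoc1",                      # furan
    "OCC1OC(O)C(O)C(O)C1O",         # glucose
    "CC(C)(C)c1ccc(O)cc1",          # 4-tert-butylphenol
    "CCN(CC)CC",                    # triethylamine
    "CN(C)c1ccccc1",                # N,N-dimethylaniline
    "O=C1CCCCC1",                   # cyclohexanone
    "OC(=O)c1ccccc1O",              # salicylic acid
    "CCOC(C)=O",                    # ethyl acetate
    "CNC(C)=O",                     # N-methylacetamide
    "N#Cc1ccccc1",                  # benzonitrile
    "O=[N+]([O-])c1ccc(O)cc1",      # 4-nitrophenol
    "CS(=O)(=O)O",                  # methanesulfonic acid
    "OP(=O)(O)O",                   # phosphoric acid
    "NC(CS)C(=O)O",                 # cysteine
    "OC(=O)CCC(=O)O",               # succinic acid
    "CCOC(=O)c1ccccc1",             # ethyl benzoate
    "NC(N)=N",                      # guanidine
    "CN1CCCC1c1cccnc1",             # nicotine (2D)
    "Oc1ccc(Cl)cc1",                # 4-chlorophenol
    "CC(O)c1ccccc1",                # 1-phenylethanol
    "OCc1ccccc1",                   # benzyl alcohol
    "CNC(=O)Oc1ccccc1",             # phenyl N-methylcarbamate
    "OC(=O)c1ccncc1",               # isonicotinic acid
    "CSc1ccccc1",                   # thioanisole
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; same spec -> identical output."""

    seed: int = 0
    n_molecules: int = 50
    cliff_pairs: int = 10
    imbalance_ratio: tuple[int, int] = (1, 9)   # positive : negative
    noise_sd: float = 0.1


@dataclass(frozen=True)
class CliffPair:
    """A matched molecule pair: one heavy-atom substituent swap, fixed
    label offset, identical graph topology."""

    mol_low: Molecule
    mol_high: Molecule
    label_low: float
    label_high: float
    sub_atom_low: int          # canonical index of the swapped atom
    sub_atom_high: int
    atom_map: tuple[tuple[int, int], ...]   # (canon idx in low, in high)


def fixture_smiles_set() -> list[Molecule]:
    """The shipped fixture molecules (canonicalized, deterministic order)."""
    return [Molecule.from_smiles(s, mol_id=f"fix{i:03d}")
            for i, s in enumerate(_FIXTURE_SMILES)]


@lru_cache(maxsize=None)
def _constants() -> dict:
    with resources.files("specmol.data").joinpath(
            "fixture_constants.yaml").open() as fh:
        return yaml.safe_load(fh)


def functional_group_counts(mol: Chem.Mol) -> dict[str, int]:
    """Distinct substructure-match count per functional group."""
    return {name: len(set(mol.GetSubstructMatches(pats[0])) |
                      {m for p in pats[1:] for m in mol.GetSubstructMatches(p)})
            for name, pats in _fg_vocabulary()}


def structure_score(molecule: Molecule) -> float:
    """Noiseless regression label: weighted functional-group content."""
    coeffs = _constants()["group_coefficients"]
    mol = Chem.MolFromSmiles(molecule.smiles)
    counts = functional_group_counts(mol)
    return float(sum(coeffs[g] * counts[g] for g in coeffs))


def synthetic_labels(molecules: list[Molecule],
                     spec: FixtureSpec) -> DatasetTable:
    """Structure-derived labels: a regression task plus a classification task.

    The regression label is the functional-group score plus seeded Gaussian
    noise; the classification label thresholds the *noiseless* score at the
    quantile that realizes ``spec.imbalance_ratio`` as closely as the
    discrete sample allows.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    scores = np.array([structure_score(m) for m in molecules])
    noise = rng.normal(0.0, spec.noise_sd, size=len(molecules)) \
        if spec.noise_sd > 0 else np.zeros(len(molecules))
    regression = scores + noise

    pos, neg = spec.imbalance_ratio
    n = len(molecules)
    n_pos = int(round(n * pos / (pos + neg)))
    n_pos = min(max(n_pos, 1), n - 1)
    order = np.argsort(-scores, kind="stable")
    labels_cls = np.zeros(n)
    labels_cls[order[:n_pos]] = 1.0
    achieved = labels_cls.sum()
    if achieved != round(n * pos / (pos + neg)):
        logger.warning("imbalance ratio %s unreachable on %d molecules; "
                       "using %d positives", spec.imbalance_ratio, n,
                       int(achieved))
    labels = np.column_stack([regression, labels_cls])
    return DatasetTable(molecules=list(molecules), labels=labels,
                        task_names=["activity", "active"],
                        task_types=["regression", "classification"])


def make_fixture_table(seed: int = 0, n_molecules: int | None = None,
                       noise_sd: float = 0.1,
                       imbalance_ratio: tuple[int, int] = (1, 9)) -> DatasetTable:
    """Seeded subsample of the fixture set with synthetic labels."""
    mols = fixture_smiles_set()
    if n_molecules is not None and n_molecules < len(mols):
        rng = np.random.Generator(np.random.PCG64(seed))
        idx = np.sort(rng.choice(len(mols), size=n_molecules, replace=False))
        mols = [mols[i] for i in idx]
    spec = FixtureSpec(seed=seed, n_molecules=len(mols), noise_sd=noise_sd,
                       imbalance_ratio=imbalance_ratio)
    return synthetic_labels(mols, spec)


def _canonical_order_map(mol: Chem.Mol) -> dict[int, int]:
    """Map original atom index -> index in the canonical-SMILES atom order
    (the order :func:`specmol.molgraph.build_graph` uses)."""
    Chem.MolToSmiles(mol)
    order = list(mol.GetPropsAsDict(includePrivate=True, includeComputed=True)
                 ["_smilesAtomOutputOrder"])
    return {orig: k for k, orig in enumerate(order)}


def _attach(template_smiles: str, site: int, symbol: str,
            mol_id: str) -> tuple[Molecule, dict[int, int], int]:
    """Bond a single heavy atom `symbol` to `site` of the template.

    Returns the molecule, the original->canonical atom index map, and the
    original index of the added atom.
    """
    t = Chem.MolFromSmiles(template_smiles)
    rw = Chem.RWMol(t)
    new_idx = rw.AddAtom(Chem.Atom(symbol))
    rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    cmap = _canonical_order_map(mol)
    return (Molecule(smiles=Chem.MolToSmiles(mol), mol_id=mol_id),
            cmap, new_idx)


def cliff_pair_generator(n_pairs: int, seed: int = 0) -> list[CliffPair]:
    """Matched pairs from common templates: swapping one low-activity
    substituent (C, F) for a high-activity one (O, N, Cl) adds the fixed
    cliff offset to the label; topology is identical within a pair."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    cfg = _constants()
    offset = float(cfg["cliff_offset"])
    combos = [(ti, lo, hi)
              for ti in range(len(cfg["cliff_templates"]))
              for lo in cfg["cliff_low_substituents"]
              for hi in cfg["cliff_high_substituents"]]
    rng = np.random.Generator(np.random.PCG64(seed))
    if n_pairs <= len(combos):
        chosen = [combos[i] for i in
                  rng.choice(len(combos), size=n_pairs, replace=False)]
    else:
        chosen = [combos[i] for i in
                  rng.choice(len(combos), size=n_pairs, replace=True)]
    pairs = []
    for p, (ti, lo, hi) in enumerate(chosen):
        tpl = cfg["cliff_templates"][ti]
        base = structure_score(Molecule.from_smiles(tpl["smiles"]))
        m_lo, map_lo, orig = _attach(tpl["smiles"], tpl["site"], lo,
                                     f"cliff{p:03d}a")
        m_hi, map_hi, _ = _attach(tpl["smiles"], tpl["site"], hi,
                                  f"cliff{p:03d}b")
        atom_map = tuple(sorted((map_lo[a], map_hi[a]) for a in map_lo))
        pairs.append(CliffPair(
            mol_low=m_lo, mol_high=m_hi,
            label_low=base, label_high=base + offset,
            sub_atom_low=map_lo[orig], sub_atom_high=map_hi[orig],
            atom_map=atom_map))
    return pairs


def cliff_pairs_table(n_pairs: int, seed: int = 0,
                      noise_sd: float = 0.0) -> DatasetTable:
    """Flatten cliff pairs into a single-task regression DatasetTable."""
    pairs = cliff_pair_generator(n_pairs, seed=seed)
    rng = np.random.Generator(np.random.PCG64(seed + 1))
    mols, labels = [], []
    for pr in pairs:
        mols.extend([pr.mol_low, pr.mol_high])
        labels.extend([pr.label_low, pr.label_high])
    labels = np.asarray(labels, dtype=np.float64)
    if noise_sd > 0:
        labels = labels + rng.normal(0.0, noise_sd, size=labels.shape)
    return DatasetTable(molecules=mols, labels=labels[:, None],
                        task_names=["activity"], task_types=["regression"])


def random_graph(n: int, edge_prob: float, seed: int = 0) -> list[tuple[int, int]]:
    """Seeded undirected Erdos-Renyi G(n, p) edge list."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.append((i, j))
    return edges
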