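"""Molecule parsing, canonical featurized graphs, and tabular I/O.

Molecules are heavy-atom 2D graphs built from SMILES via RDKit.  Atom order
is the canonical-SMILES output order, so the same molecule always yields a
byte-identical graph regardless of the input spelling — a requirement for
the order-sensitive GRU readout downstream.

Featurization (fixed, dimensions exposed as module constants):

* atom: element one-hot over {C,N,O,S,F,Cl,Br,I,P,other}; degree one-hot
  (0-5); formal charge clipped to [-2, 2]; hybridization one-hot
  (sp, sp2, sp3, other); aromatic flag; total-H one-hot (0-4); in-ring flag.
* bond: order one-hot (single/double/triple/aromatic); conjugation flag;
  in-ring flag.

Missing labels are NaN and are excluded from every loss sum downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; we log drops ourselves

logger = logging.getLogger(__name__)

__all__ = ["Molecule", "MolecularGraph", "DatasetTable", "InvalidMoleculeError",
           "EmptyDatasetError", "build_graph", "read_molecule_table",
           "read_sdf", "write_predictions", "write_table",
           "ELEMENTS", "N_ATOM_FEATURES", "N_BOND_FEATURES"]

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + "other" slot
_HYBRID = {Chem.HybridizationType.SP: 0, Chem.HybridizationType.SP2: 1,
           Chem.HybridizationType.SP3: 2}
_BOND_ORDER = {Chem.BondType.SINGLE: 0, Chem.BondType.DOUBLE: 1,
               Chem.BondType.TRIPLE: 2, Chem.BondType.AROMATIC: 3}

N_ATOM_FEATURES = (len(ELEMENTS) + 1) + 6 + 1 + 4 + 1 + 5 + 1   # 28
N_BOND_FEATURES = 4 + 1 + 1                                      # 6


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class EmptyDatasetError(ValueError):
    """Raised when a molecule table contains zero parseable rows."""


@dataclass(frozen=True)
class Molecule:
    """A molecule identified by its canonical SMILES."""

    smiles: str   # canonical form
    mol_id: str

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str | None = None) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        return cls(smiles=canonical, mol_id=mol_id if mol_id is not None else canonical)


@dataclass
class MolecularGraph:
    """Heavy-atom graph with featurized nodes and bonds, canonical order."""

    n_atoms: int
    atom_features: np.ndarray        # [n_atoms, N_ATOM_FEATURES]
    bond_list: np.ndarray            # [n_bonds, 2], i < j, each bond once
    bond_features: np.ndarray        # [n_bonds, N_BOND_FEATURES]
    atom_symbols: list[str]
    rdkit_mol: Chem.Mol = field(repr=False)

    @property
    def n_bonds(self) -> int:
        return self.bond_list.shape[0]


def _atom_row(atom: Chem.Atom) -> np.ndarray:
    row = np.zeros(N_ATOM_FEATURES)
    off = 0
    sym = atom.GetSymbol()
    row[off + (ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS))] = 1.0
    off += len(ELEMENTS) + 1
    row[off + min(atom.GetDegree(), 5)] = 1.0
    off += 6
    row[off] = float(np.clip(atom.GetFormalCharge(), -2, 2))
    off += 1
    row[off + _HYBRID.get(atom.GetHybridization(), 3)] = 1.0
    off += 4
    row[off] = float(atom.GetIsAromatic())
    off += 1
    row[off + min(atom.GetTotalNumHs(), 4)] = 1.0
    off += 5
    row[off] = float(atom.IsInRing())
    return row


def _bond_row(bond: Chem.Bond) -> np.ndarray:
    row = np.zeros(N_BOND_FEATURES)
    order = _BOND_ORDER.get(bond.GetBondType())
    if order is not None:
        row[order] = 1.0
    row[4] = float(bond.GetIsConjugated())
    row[5] = float(bond.IsInRing())
    return row


def build_graph(molecule: Molecule) -> MolecularGraph:
    """Build the canonical featurized graph for one molecule.

    Parsing the stored canonical SMILES fixes the atom order: RDKit writes
    canonical SMILES in a deterministic atom order, so round-tripping through
    it makes the graph independent of the input spelling.
    """
    mol = Chem.MolFromSmiles(molecule.smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {molecule.smiles!r}")
    n = mol.GetNumAtoms()
    atom_features = np.stack([_atom_row(a) for a in mol.GetAtoms()]) \
        if n else np.zeros((0, N_ATOM_FEATURES))
    bonds, bond_rows = [], []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j)))
        bond_rows.append(_bond_row(b))
    order = np.lexsort(([b[1] for b in bonds], [b[0] for b in bonds])) \
        if bonds else np.array([], dtype=np.int64)
    bond_list = (np.asarray(bonds, dtype=np.int64)[order]
                 if bonds else np.zeros((0, 2), dtype=np.int64))
    bond_features = (np.stack(bond_rows)[order]
                     if bonds else np.zeros((0, N_BOND_FEATURES)))
    return MolecularGraph(n_atoms=n, atom_features=atom_features,
                          bond_list=bond_list, bond_features=bond_features,
                          atom_symbols=[a.GetSymbol() for a in mol.GetAtoms()],
                          rdkit_mol=mol)


@dataclass
class DatasetTable:
    """Molecules with a (possibly sparse) multi-task label matrix."""

    molecules: list[Molecule]
    labels: np.ndarray               # [n_molecules, T], NaN = missing
    task_names: list[str]
    task_types: list[str]            # "classification" | "regression"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.labels.ndim == 1:
            self.labels = self.labels[:, None]
        n, t = self.labels.shape
        if n != len(self.molecules):
            raise ValueError("label row count != molecule count")
        if t != len(self.task_names) or t != len(self.task_types):
            raise ValueError("task name/type count != label column count")
        ids = [m.mol_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("mol_id values must be unique within a dataset")
        for j, kind in enumerate(self.task_types):
            if kind == "classification":
                obs = self.labels[:, j][~np.isnan(self.labels[:, j])]
                if obs.size and not np.all(np.isin(obs, (0.0, 1.0))):
                    raise ValueError(
                        f"classification task {self.task_names[j]!r} has "
                        "labels outside {0,1}")

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def __len__(self) -> int:
        return len(self.molecules)


def _infer_task_type(col: np.ndarray) -> str:
    obs = col[~np.isnan(col)]
    return "classification" if obs.size and np.all(np.isin(obs, (0.0, 1.0))) \
        else "regression"


def read_molecule_table(path, smiles_column: str = "smiles",
                        label_columns: list[str] | None = None,
                        id_column: str | None = None, sep: str = ",",
                        task_types: list[str] | None = None) -> DatasetTable:
    """Read a delimited molecule table; unparseable SMILES rows are dropped.

    ``label_columns`` defaults to every column other than the SMILES and id
    columns.  Task types are inferred per column ({0,1}-valued ->
    classification) unless given explicitly.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if smiles_column not in df.columns:
        raise ValueError(f"column {smiles_column!r} not in {list(df.columns)}")
    if label_columns is None:
        label_columns = [c for c in df.columns
                         if c not in (smiles_column, id_column)]
    missing = [c for c in label_columns if c not in df.columns]
    if missing:
        raise ValueError(f"label columns not found: {missing}")

    molecules, rows, n_dropped = [], [], 0
    for i, rec in df.iterrows():
        mol_id = str(rec[id_column]) if id_column else f"mol{i}"
        try:
            molecules.append(Molecule.from_smiles(str(rec[smiles_column]), mol_id))
        except InvalidMoleculeError:
            n_dropped += 1
            continue
        rows.append([pd.to_numeric(rec[c], errors="coerce")
                     for c in label_columns])
    if n_dropped:
        logger.warning("dropped %d unparseable SMILES rows from %s",
                       n_dropped, path)
    if not molecules:
        raise EmptyDatasetError(f"no parseable molecules in {path}")
    labels = np.asarray(rows, dtype=np.float64).reshape(len(molecules),
                                                        len(label_columns))
    if task_types is None:
        task_types = [_infer_task_type(labels[:, j])
                      for j in range(labels.shape[1])]
    return DatasetTable(molecules=molecules, labels=labels,
                        task_names=list(label_columns), task_types=task_types)


def read_sdf(path, label_props: list[str] | None = None) -> DatasetTable:
    """Read an SDF file, extracting SMILES and named numeric properties."""
    supplier = Chem.SDMolSupplier(str(path))
    molecules, rows, n_dropped = [], [], 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_dropped += 1
            continue
        smiles = Chem.MolToSmiles(mol)
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and \
            mol.GetProp("_Name") else f"mol{i}"
        molecules.append(Molecule(smiles=smiles, mol_id=mol_id))
        if label_props:
            rows.append([float(mol.GetProp(p)) if mol.HasProp(p) else np.nan
                         for p in label_props])
    if n_dropped:
        logger.warning("dropped %d unreadable SDF records from %s",
                       n_dropped, path)
    if not molecules:
        raise EmptyDatasetError(f"no readable molecules in {path}")
    label_props = label_props or []
    labels = (np.asarray(rows, dtype=np.float64) if label_props
              else np.zeros((len(molecules), 0)))
    return DatasetTable(molecules=molecules, labels=labels,
                        task_names=list(label_props),
                        task_types=[_infer_task_type(labels[:, j])
                                    for j in range(labels.shape[1])])


def write_table(table: DatasetTable, path, sep: str = ",") -> None:
    """Write a DatasetTable as delimited text (inverse of read_molecule_table)."""
    df = pd.DataFrame({"mol_id": [m.mol_id for m in table.molecules],
                       "smiles": [m.smiles for m in table.molecules]})
    for j, name in enumerate(table.task_names):
        df[name] = table.labels[:, j]
    # %.17g: labels survive the text round trip bit-exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_predictions(table: DatasetTable, predictions: np.ndarray, path,
                      sep: str = ",") -> None:
    """Write per-molecule predictions: mol_id, smiles, one column per task."""
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.ndim == 1:
        predictions = predictions[:, None]
    if predictions.shape[0] != len(table.molecules):
        raise ValueError(
            f"prediction rows ({predictions.shape[0]}) != molecules "
            f"({len(table.molecules)})")
    names = table.task_names if predictions.shape[1] == table.n_tasks \
        else [f"task{j}" for j in range(predictions.shape[1])]
    df = pd.DataFrame({"mol_id": [m.mol_id for m in table.molecules],
                       "smiles": [m.smiles for m in table.molecules]})
    for j, name in enumerate(names):
        df[name] = predictions[:, j]
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
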