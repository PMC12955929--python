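"""Refract a molecular graph into three node-aligned chemical views.

Each molecule is viewed through three complementary lenses sharing the same
atom set and order (node alignment is what licenses concatenating the three
encoded views feature-wise):

* **scaffold** — the ring systems plus the linker atoms connecting them
  (Murcko-style framework); only edges internal to the scaffold survive,
  substituent atoms become isolated nodes.
* **functional group** — per-atom one-hot annotation over a prioritized
  SMARTS vocabulary of reactive groups; edges are the base edges.
* **pharmacophore** — per-atom multi-hot annotation over interaction
  families (H-bond donor/acceptor, hydrophobe, aromatic, positive/negative
  ionizable); edges are the base edges.

Pattern vocabularies ship as versioned YAML under ``specmol/data`` and can
be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from rdkit import Chem

from .molgraph import MolecularGraph

__all__ = ["ViewGraph", "ViewBundle", "make_scaffold_view",
           "make_functional_group_view", "make_pharmacophore_view",
           "make_views", "functional_group_names", "pharmacophore_names",
           "scaffold_atom_mask"]


@dataclass
class ViewGraph:
    kind: str                     # scaffold | functional_group | pharmacophore
    n_atoms: int
    edge_list: np.ndarray         # [n_edges, 2]
    annotation: np.ndarray        # [n_atoms, d_view]
    member_mask: np.ndarray       # [n_atoms] bool


@dataclass
class ViewBundle:
    base: MolecularGraph
    scaffold: ViewGraph
    functional_group: ViewGraph
    pharmacophore: ViewGraph

    def __iter__(self):
        return iter((self.scaffold, self.functional_group, self.pharmacophore))


def _load_yaml(name: str) -> dict:
    with resources.files("specmol.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def _fg_vocabulary() -> list[tuple[str, tuple[Chem.Mol, ...]]]:
    cfg = _load_yaml("functional_groups.yaml")
    vocab = []
    for entry in cfg["groups"]:
        pats = tuple(Chem.MolFromSmarts(s) for s in entry["smarts"])
        assert all(p is not None for p in pats), entry["name"]
        vocab.append((entry["name"], pats))
    return vocab


@lru_cache(maxsize=None)
def _ph_vocabulary() -> list[tuple[str, tuple[Chem.Mol, ...]]]:
    cfg = _load_yaml("pharmacophores.yaml")
    vocab = []
    for entry in cfg["families"]:
        pats = tuple(Chem.MolFromSmarts(s) for s in entry["smarts"])
        assert all(p is not None for p in pats), entry["name"]
        vocab.append((entry["name"], pats))
    return vocab


def functional_group_names() -> list[str]:
    """Vocabulary order = match priority (most specific first)."""
    return [name for name, _ in _fg_vocabulary()]


def pharmacophore_names() -> list[str]:
    return [name for name, _ in _ph_vocabulary()]


def scaffold_atom_mask(graph: MolecularGraph) -> np.ndarray:
    """Boolean mask of Murcko-framework atoms: rings plus ring-ring linkers.

    Computed by iteratively pruning degree-1 atoms from the bond graph
    (the 2-core), which leaves exactly the cycles and the paths connecting
    them; acyclic molecules prune to nothing.
    """
    n = graph.n_atoms
    adj = [set() for _ in range(n)]
    for i, j in graph.bond_list:
        adj[i].add(int(j))
        adj[j].add(int(i))
    alive = np.ones(n, dtype=bool)
    frontier = [v for v in range(n) if len(adj[v]) <= 1]
    while frontier:
        v = frontier.pop()
        if not alive[v] or len(adj[v]) > 1:
            continue
        alive[v] = False
        for u in adj[v]:
            adj[u].discard(v)
            if alive[u] and len(adj[u]) <= 1:
                frontier.append(u)
        adj[v] = set()
    return alive


def make_scaffold_view(graph: MolecularGraph) -> ViewGraph:
    """Scaffold view: member atoms = Murcko framework; edges internal to it."""
    mask = scaffold_atom_mask(graph)
    if graph.n_bonds:
        keep = mask[graph.bond_list[:, 0]] & mask[graph.bond_list[:, 1]]
        edges = graph.bond_list[keep]
    else:
        edges = graph.bond_list.copy()
    annotation = mask.astype(np.float64)[:, None]
    return ViewGraph(kind="scaffold", n_atoms=graph.n_atoms, edge_list=edges,
                     annotation=annotation, member_mask=mask)


def _match_atoms(mol: Chem.Mol, patterns) -> set[int]:
    atoms: set[int] = set()
    for pat in patterns:
        for match in mol.GetSubstructMatches(pat):
            atoms.update(match)
    return atoms


def functional_group_atoms(mol: Chem.Mol) -> dict[str, set[int]]:
    """Raw per-group matched atom sets, before priority resolution."""
    return {name: _match_atoms(mol, pats) for name, pats in _fg_vocabulary()}


def make_functional_group_view(graph: MolecularGraph) -> ViewGraph:
    """One-hot group annotation (+ trailing "none" slot); priority = vocab order."""
    vocab = _fg_vocabulary()
    n = graph.n_atoms
    annotation = np.zeros((n, len(vocab) + 1))
    assigned = np.full(n, -1, dtype=np.int64)
    for gi, (_, pats) in enumerate(vocab):
        for a in _match_atoms(graph.rdkit_mol, pats):
            if assigned[a] < 0:
                assigned[a] = gi
    for a in range(n):
        annotation[a, assigned[a] if assigned[a] >= 0 else len(vocab)] = 1.0
    return ViewGraph(kind="functional_group", n_atoms=n,
                     edge_list=graph.bond_list.copy(), annotation=annotation,
                     member_mask=assigned >= 0)


def make_pharmacophore_view(graph: MolecularGraph) -> ViewGraph:
    """Multi-hot interaction-family annotation; an atom may hit several."""
    vocab = _ph_vocabulary()
    n = graph.n_atoms
    annotation = np.zeros((n, len(vocab)))
    for fi, (_, pats) in enumerate(vocab):
        for a in _match_atoms(graph.rdkit_mol, pats):
            annotation[a, fi] = 1.0
    return ViewGraph(kind="pharmacophore", n_atoms=n,
                     edge_list=graph.bond_list.copy(), annotation=annotation,
                     member_mask=annotation.any(axis=1))


def make_views(graph: MolecularGraph) -> ViewBundle:
    """All three views of one molecule, node-aligned with the base graph."""
    return ViewBundle(base=graph,
                      scaffold=make_scaffold_view(graph),
                      functional_group=make_functional_group_view(graph),
                      pharmacophore=make_pharmacophore_view(graph))
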