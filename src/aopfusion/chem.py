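"""Linear-peptide SMILES construction and molecular-graph featurization.

Each residue is emitted from a hand-written SMILES fragment of the form
``N...C(=O)`` so that plain string concatenation forms the peptide bonds;
appending a final ``O`` yields the free C-terminal carboxylic acid.  No
stereochemistry is written: the downstream featurization is purely
2D-topological.  RDKit parses, sanitizes and canonicalizes the result and
provides atom/bond perception for the graph features.

The node/edge feature layout is versioned (`FEATURIZER_VERSION`) because
cached graphs and model checkpoints must be self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .data import AMINO_ACIDS, DatasetManifest

RDLogger.DisableLog("rdApp.*")

FEATURIZER_VERSION = "aopfusion-feat-1"

# Residue fragments: start with the backbone N, end with the carbonyl C(=O);
# concatenating fragments N->C and appending "O" closes the C-terminal acid.
# Ring-closure digits are safely reused because each closes within a fragment.
RESIDUE_SMILES: dict[str, str] = {
    "A": "NC(C)C(=O)",
    "R": "NC(CCCNC(=N)N)C(=O)",
    "N": "NC(CC(N)=O)C(=O)",
    "D": "NC(CC(O)=O)C(=O)",
    "C": "NC(CS)C(=O)",
    "E": "NC(CCC(O)=O)C(=O)",
    "Q": "NC(CCC(N)=O)C(=O)",
    "G": "NCC(=O)",
    "H": "NC(Cc1c[nH]cn1)C(=O)",
    "I": "NC(C(C)CC)C(=O)",
    "L": "NC(CC(C)C)C(=O)",
    "K": "NC(CCCCN)C(=O)",
    "M": "NC(CCSC)C(=O)",
    "F": "NC(Cc1ccccc1)C(=O)",
    "P": "N1CCCC1C(=O)",
    "S": "NC(CO)C(=O)",
    "T": "NC(C(C)O)C(=O)",
    "W": "NC(Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "NC(Cc1ccc(O)cc1)C(=O)",
    "V": "NC(C(C)C)C(=O)",
}
assert set(RESIDUE_SMILES) == set(AMINO_ACIDS)


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        super().__init__(f"unparseable SMILES {smiles!r}{': ' + detail if detail else ''}")
        self.smiles = smiles


@dataclass(frozen=True)
class MolGraph:
    """Attributed molecular graph over heavy atoms.

    ``edges`` lists each undirected bond once; ``edge_features`` rows align
    with ``edges``.
    """

    node_features: np.ndarray      # (n_atoms, NODE_FEATURE_DIM)
    edges: np.ndarray              # (n_bonds, 2) int
    edge_features: np.ndarray      # (n_bonds, EDGE_FEATURE_DIM)

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edges.shape[0]


_ELEMENTS = ("C", "N", "O", "S")          # + "other" slot
_MAX_DEGREE = 4

# element one-hot (5) + degree one-hot 1..4 (4) + charge + aromatic + n_H + ring
NODE_FEATURE_DIM = 13
# bond order one-hot {single, double, aromatic} + conjugated + ring
EDGE_FEATURE_DIM = 5


def peptide_to_smiles(sequence: str) -> str:
    """Canonical SMILES of the linear peptide (free N/C termini, no stereo)."""
    unknown = set(sequence) - set(RESIDUE_SMILES)
    if unknown:
        raise ValueError(f"no residue template for {sorted(unknown)}")
    raw = "".join(RESIDUE_SMILES[a] for a in sequence) + "O"
    mol = Chem.MolFromSmiles(raw)
    if mol is None:  # cannot happen for the 20 templates; guard regardless
        raise SmilesError(raw, "template assembly failed")
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def _node_features(atom: Chem.Atom) -> list[float]:
    symbol = atom.GetSymbol()
    element = [0.0] * (len(_ELEMENTS) + 1)
    element[_ELEMENTS.index(symbol) if symbol in _ELEMENTS else len(_ELEMENTS)] = 1.0
    degree = [0.0] * _MAX_DEGREE
    degree[min(atom.GetDegree(), _MAX_DEGREE) - 1] = 1.0
    return element + degree + [
        float(atom.GetFormalCharge()),
        float(atom.GetIsAromatic()),
        float(atom.GetTotalNumHs()),
        float(atom.IsInRing()),
    ]


def _edge_features(bond: Chem.Bond) -> list[float]:
    order = [0.0, 0.0, 0.0]
    if bond.GetIsAromatic():
        order[2] = 1.0
    elif bond.GetBondType() == Chem.BondType.DOUBLE:
        order[1] = 1.0
    else:
        order[0] = 1.0
    return order + [float(bond.GetIsConjugated()), float(bond.IsInRing())]


def smiles_to_graph(smiles: str) -> MolGraph:
    """Parse a SMILES string into a heavy-atom graph with fixed feature layout."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles)
    nodes = np.array([_node_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    edges, efeats = [], []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeats.append(_edge_features(bond))
    return MolGraph(node_features=nodes,
                    edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
                    edge_features=np.array(efeats, dtype=np.float64).reshape(
                        -1, EDGE_FEATURE_DIM))


def sequence_to_graph(sequence: str) -> MolGraph:
    return smiles_to_graph(peptide_to_smiles(sequence))


class GraphCache:
    """Per-dataset graph store keyed by sequence and featurizer version.

    Serialized as JSON beside the dataset it was built from; a version
    mismatch on load invalidates the whole cache.  ``n_computed`` counts
    actual featurizations so cache hits are observable.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self._store: dict[str, MolGraph] = {}
        self.n_computed = 0
        self.skipped: list[str] = []
        if self.path and self.path.exists():
            self._load()

    def _load(self) -> None:
        payload = json.loads(self.path.read_text())
        if payload.get("featurizer_version") != FEATURIZER_VERSION:
            return  # stale cache: ignore, will be recomputed and overwritten
        for seq, g in payload["graphs"].items():
            self._store[seq] = MolGraph(
                node_features=np.array(g["node_features"], dtype=np.float64),
                edges=np.array(g["edges"], dtype=np.int64).reshape(-1, 2),
                edge_features=np.array(g["edge_features"],
                                       dtype=np.float64).reshape(-1, EDGE_FEATURE_DIM))

    def save(self) -> None:
        if not self.path:
            return
        payload = {
            "featurizer_version": FEATURIZER_VERSION,
            "graphs": {seq: {"node_features": g.node_features.tolist(),
                             "edges": g.edges.tolist(),
                             "edge_features": g.edge_features.tolist()}
                       for seq, g in self._store.items()},
        }
        self.path.write_text(json.dumps(payload))

    def get(self, sequence: str) -> MolGraph:
        if sequence not in self._store:
            self._store[sequence] = sequence_to_graph(sequence)
            self.n_computed += 1
        return self._store[sequence]


def graph_cache(manifest: DatasetManifest,
                path: str | Path | None = None) -> tuple[dict[str, MolGraph], GraphCache]:
    """Build (or reload) one graph per record; failures are reported, not fatal."""
    cache = GraphCache(path)
    graphs: dict[str, MolGraph] = {}
    for rec in manifest.records:
        try:
            graphs[rec.id] = cache.get(rec.sequence)
        except (SmilesError, ValueError) as err:
            cache.skipped.append(f"{rec.id}: {err}")
    if path:
        cache.save()
    return graphs, cache
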