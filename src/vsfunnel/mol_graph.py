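"""Molecule-to-graph featurization with score-augmented node features.

A molecule becomes a heavy-atom graph: one node per non-hydrogen atom with a
fixed base feature vector, one undirected edge per bond.  Global per-molecule
scalars — an external docking/surface score plus RDKit descriptors (TPSA, MW,
rotatable bonds) — are z-scored against the training population and broadcast
to every node as extra feature columns, so that graph-level context is
available to local attention during message passing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + 'other' slot
MAX_DEGREE = 5
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)  # + 'other' slot
BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

#: Base node feature dimension: element one-hot + degree one-hot + charge +
#: aromatic + ring + implicit-H count + hybridization one-hot.
BASE_NODE_DIM = (len(ELEMENTS) + 1) + (MAX_DEGREE + 1) + 1 + 1 + 1 + 1 + (len(HYBRIDIZATIONS) + 1)
EDGE_DIM = len(BOND_ORDERS) + 2  # bond-order one-hot + conjugation + ring

#: Default global scalars injected into node features.
DEFAULT_GLOBAL_SCALARS = ("external_score", "tpsa", "mw", "rot_bonds")


@dataclass
class MolGraph:
    """Attributed heavy-atom graph for one molecule.

    ``edges`` lists each undirected bond once (i < j); symmetric closure is
    materialized by consumers that need directed message passing.
    """

    mol_id: str
    node_features: np.ndarray  # (n_atoms, d) float64
    edges: np.ndarray          # (n_bonds, 2) int
    edge_features: np.ndarray  # (n_bonds, EDGE_DIM) float64
    base_dim: int = BASE_NODE_DIM
    global_names: tuple = ()

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mol_id": self.mol_id,
                "node_features": self.node_features.tolist(),
                "edges": self.edges.tolist(),
                "edge_features": self.edge_features.tolist(),
                "base_dim": self.base_dim,
                "global_names": list(self.global_names),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "MolGraph":
        d = json.loads(payload)
        return cls(
            mol_id=d["mol_id"],
            node_features=np.asarray(d["node_features"], dtype=float),
            edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            edge_features=np.asarray(d["edge_features"], dtype=float).reshape(-1, EDGE_DIM),
            base_dim=d["base_dim"],
            global_names=tuple(d["global_names"]),
        )


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value) if isinstance(choices, tuple) else choices[value]] = 1.0
    except (ValueError, KeyError, IndexError):
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), ELEMENTS)
    degree = min(atom.GetDegree(), MAX_DEGREE)
    deg_vec = [0.0] * (MAX_DEGREE + 1)
    deg_vec[degree] = 1.0
    feats += deg_vec
    feats.append(float(atom.GetFormalCharge()))
    feats.append(float(atom.GetIsAromatic()))
    feats.append(float(atom.IsInRing()))
    feats.append(float(atom.GetTotalNumHs()))
    feats += _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
    return feats


def build_graph(m: MoleculeRecord) -> MolGraph:
    """Featurize a standardized molecule as a heavy-atom graph."""
    mol = m.to_mol()
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"{m.id}: no heavy atoms")
    nodes = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    edges, efeats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeats.append(
            _one_hot(bond.GetBondType(), BOND_ORDERS)[:-1]
            + [float(bond.GetIsConjugated()), float(bond.IsInRing())]
        )
    edges_arr = np.asarray(edges, dtype=int).reshape(-1, 2)
    efeats_arr = np.asarray(efeats, dtype=float).reshape(-1, EDGE_DIM)
    assert np.isfinite(nodes).all()
    return MolGraph(mol_id=m.id, node_features=nodes, edges=edges_arr, edge_features=efeats_arr)


@dataclass
class FeatureScaler:
    """Per-column z-score parameters fitted on the training population.

    Population (ddof=0) standard deviation; a constant column gets sd 1 so
    its transform is identically zero rather than undefined.
    """

    names: tuple
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, scalars: Mapping[str, float] | np.ndarray) -> np.ndarray:
        if isinstance(scalars, Mapping):
            missing = [n for n in self.names if n not in scalars]
            if missing:
                raise KeyError(f"missing scalars: {missing}")
            vec = np.array([float(scalars[n]) for n in self.names])
        else:
            vec = np.asarray(scalars, dtype=float)
        if not np.isfinite(vec).all():
            raise ValueError("non-finite scalar value")
        return (vec - self.mean) / self.sd

    def to_json(self) -> str:
        return json.dumps(
            {"names": list(self.names), "mean": self.mean.tolist(), "sd": self.sd.tolist()}
        )

    @classmethod
    def from_json(cls, payload: str) -> "FeatureScaler":
        d = json.loads(payload)
        return cls(tuple(d["names"]), np.asarray(d["mean"]), np.asarray(d["sd"]))


def fit_scaler(values: pd.DataFrame, columns: Sequence[str] | None = None) -> FeatureScaler:
    """Fit z-score parameters on the training split only.

    ``values`` holds one row per training molecule; ``columns`` defaults to
    every numeric column.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    if columns is None:
        columns = [c for c in values.columns if np.issubdtype(values[c].dtype, np.number)]
    sub = values[list(columns)].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return FeatureScaler(names=tuple(columns), mean=mean, sd=sd)


def inject_global_features(
    g: MolGraph, scalars: Mapping[str, float], scaler: FeatureScaler
) -> MolGraph:
    """Broadcast z-scored global scalars into every node feature vector.

    The node dimension grows by ``len(scaler.names)``; edges and the base
    feature prefix are untouched.
    """
    z = scaler.transform(scalars)
    tail = np.tile(z, (g.n_atoms, 1))
    return MolGraph(
        mol_id=g.mol_id,
        node_features=np.hstack([g.node_features, tail]),
        edges=g.edges,
        edge_features=g.edge_features,
        base_dim=g.base_dim,
        global_names=g.global_names + scaler.names,
    )


def normalize_score_by_property(score: float, prop: float, eps: float = 1e-9) -> float:
    """Alternative reading of score normalization: divide the external score
    by a molecular property instead of appending z-scored properties.

    Provided as a config option only; the default pipeline appends z-scored
    scalars (see ``inject_global_features``).
    """
    return score / (prop if abs(prop) > eps else eps)
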