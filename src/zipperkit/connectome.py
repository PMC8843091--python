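"""Connectome contact-similarity and centrality analyses.

Works on named, weighted neuron-neuron adjacency matrices (contact areas or
synapse weights) from multiple developmental stages.  Two analyses:

* cosine similarity of a focal neuron's contact profile across datasets,
  restricted to the neurons common to all datasets, and
* normalized binary betweenness centrality for connector-hub
  identification: BC_v = sum over s != v != t of lambda_stv / lambda_st,
  divided by (N-1)(N-2)/2 (undirected) or (N-1)(N-2) (directed) so values
  lie in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyMatrix",
    "ContactVector",
    "common_contact_vectors",
    "cosine_similarity",
    "binarize",
    "betweenness_centrality",
    "hub_report",
]


@dataclass
class AdjacencyMatrix:
    """Square nonnegative neuron-neuron contact matrix with named rows."""

    neuron_names: tuple[str, ...]
    weights: np.ndarray
    dataset_id: str = ""
    directed: bool = False

    def __post_init__(self) -> None:
        names = tuple(self.neuron_names)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(names) != w.shape[0]:
            raise ValueError("neuron_names length must match matrix size")
        if len(set(names)) != len(names):
            raise ValueError("neuron names must be unique")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and >= 0")
        if not self.directed and not np.allclose(w, w.T):
            raise ValueError("undirected adjacency matrix must be symmetric")
        self.neuron_names = names
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.neuron_names)

    def index_of(self, name: str) -> int:
        try:
            return self.neuron_names.index(name)
        except ValueError:
            raise KeyError(f"neuron {name!r} not in dataset {self.dataset_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.neuron_names, columns=self.neuron_names)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, dataset_id: str = "", directed: bool = False
    ) -> "AdjacencyMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("adjacency frame must have identical row and column names")
        return cls(tuple(frame.index), frame.to_numpy(dtype=float), dataset_id, directed)

    def subset(self, names: "list[str]") -> "AdjacencyMatrix":
        """Restrict to a user-supplied neuron subset (e.g. nerve-ring only)."""
        idx = [self.index_of(n) for n in names]
        return AdjacencyMatrix(
            tuple(names), self.weights[np.ix_(idx, idx)], self.dataset_id, self.directed
        )


@dataclass(frozen=True)
class ContactVector:
    """A focal neuron's contact weights over a shared, ordered neuron set."""

    focal_neuron: str
    common_neurons: tuple[str, ...]
    weights: np.ndarray
    dataset_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != len(self.common_neurons):
            raise ValueError("weights must align with common_neurons")
        if np.any(w < 0):
            raise ValueError("contact weights must be >= 0")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "common_neurons", tuple(self.common_neurons))


def common_contact_vectors(
    datasets: "list[AdjacencyMatrix]", focal: str
) -> "list[ContactVector]":
    """Extract the focal neuron's contact vector from each dataset.

    All vectors are aligned to the lexicographically sorted intersection of
    neuron sets (excluding the focal neuron); absent contacts are zero.
    The sorted order makes similarity values reproducible bit-exactly.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    for ds in datasets:
        ds.index_of(focal)  # raises KeyError if missing
    common: set[str] = set(datasets[0].neuron_names)
    for ds in datasets[1:]:
        common &= set(ds.neuron_names)
    common.discard(focal)
    if not common:
        raise ValueError("datasets share no neurons besides the focal one")
    order = tuple(sorted(common))
    out = []
    for ds in datasets:
        row = ds.weights[ds.index_of(focal)]
        idx = [ds.index_of(n) for n in order]
        out.append(ContactVector(focal, order, row[idx], ds.dataset_id))
    return out


def cosine_similarity(a, b) -> float:
    """Cosine similarity sum(A_i B_i) / (sqrt(sum A_i^2) sqrt(sum B_i^2)).

    For nonnegative contact vectors the value lies in [0, 1]; it is
    symmetric and invariant to positive rescaling of either vector.
    """
    av = np.asarray(a.weights if isinstance(a, ContactVector) else a, dtype=float)
    bv = np.asarray(b.weights if isinstance(b, ContactVector) else b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    na, nb = math.sqrt(float(av @ av)), math.sqrt(float(bv @ bv))
    if na == 0.0 or nb == 0.0:
        raise ValueError(
            "cosine similarity is undefined for a zero vector; "
            "check that the focal neuron has contacts among the common neurons"
        )
    return float(av @ bv) / (na * nb)


def binarize(adj: AdjacencyMatrix, threshold: float = 0.0) -> AdjacencyMatrix:
    """Binary connectivity matrix: edge iff weight > threshold; zero diagonal."""
    w = (adj.weights > threshold).astype(float)
    np.fill_diagonal(w, 0.0)
    return AdjacencyMatrix(adj.neuron_names, w, adj.dataset_id, adj.directed)


def betweenness_centrality(adj: AdjacencyMatrix, directed: bool | None = None) -> pd.Series:
    """Normalized binary betweenness centrality per neuron, in [0, 1].

    Shortest paths are counted on the binarized graph; a vertex scores for
    every shortest path between two *other* vertices that passes through it
    (endpoints excluded — the convention under which the stated
    normalization bounds the value by 1).  Disconnected pairs contribute
    zero.  Requires N >= 3.
    """
    if directed is None:
        directed = adj.directed
    if adj.n < 3:
        raise ValueError("betweenness normalization requires at least 3 neurons")
    b = binarize(adj)
    cls = nx.DiGraph if directed else nx.Graph
    g = cls()
    g.add_nodes_from(b.neuron_names)
    rows, cols = np.nonzero(b.weights)
    g.add_edges_from(
        (b.neuron_names[i], b.neuron_names[j]) for i, j in zip(rows, cols) if i != j
    )
    bc = nx.betweenness_centrality(g, normalized=True)
    return pd.Series([bc[n] for n in b.neuron_names], index=list(b.neuron_names), name="bc")


def hub_report(bc: pd.Series, focal: "list[str] | None" = None) -> pd.DataFrame:
    """Rank neurons by betweenness and annotate focal neurons' percentiles.

    Percentile is the fraction of neurons with strictly lower centrality.
    """
    focal = list(focal or [])
    missing = [f for f in focal if f not in bc.index]
    if missing:
        raise KeyError(f"unknown focal neuron(s): {missing}")
    vals = bc.to_numpy(dtype=float)
    pct = np.array([(vals < v).mean() for v in vals])
    table = pd.DataFrame(
        {
            "neuron": bc.index,
            "bc": vals,
            "percentile": pct,
            "is_focal": [n in set(focal) for n in bc.index],
        }
    ).sort_values(["bc", "neuron"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
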