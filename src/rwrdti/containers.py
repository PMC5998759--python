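"""Core in-memory containers shared across the pipeline.

The package moves four kinds of objects between stages:

* :class:`InteractionNetwork` — a weighted undirected interactome
  (protein-protein or drug-drug), the substrate of the random walk.
* :class:`BipartiteDTI` — the set of known positive (drug, protein) pairs.
* :class:`FeatureMatrix` — entities-by-features table with an aligned
  identifier index (drug fingerprints or protein descriptors, raw or
  network-weighted).
* :class:`AffinityMatrix` — row-per-seed converged random-walk-with-restart
  distributions over a network's nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "InteractionNetwork",
    "BipartiteDTI",
    "FeatureMatrix",
    "AffinityMatrix",
]


class InteractionNetwork:
    """Weighted undirected graph over drugs or proteins.

    Thin wrapper around a :class:`networkx.Graph` that pins down an ordered
    node index (needed so adjacency/affinity matrices align with feature
    rows), forbids self-loops, and requires strictly positive edge weights.
    Unscored interactions carry weight 1.0.
    """

    def __init__(
        self,
        node_ids: Iterable[str] = (),
        edges: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        g = nx.Graph()
        for n in node_ids:
            g.add_node(str(n))
        for a, b, w in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            w = float(w)
            if not w > 0:
                raise ValueError(f"edge ({a}, {b}) has non-positive weight {w}")
            if a not in g or b not in g:
                missing = [n for n in (a, b) if n not in g]
                raise ValueError(f"edge endpoint(s) {missing} not in node_ids")
            if g.has_edge(a, b):
                raise ValueError(f"duplicate edge ({a}, {b})")
            g.add_edge(a, b, weight=w)
        self._graph = g

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "InteractionNetwork":
        """Adopt an existing undirected graph (weights default to 1.0)."""
        net = cls()
        net._graph = nx.Graph()
        net._graph.add_nodes_from(graph.nodes)
        for a, b, data in graph.edges(data=True):
            if a == b:
                continue
            net._graph.add_edge(a, b, weight=float(data.get("weight", 1.0)))
        return net

    # -- basic queries -----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def node_ids(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._graph

    def has_edge(self, a: str, b: str) -> bool:
        return self._graph.has_edge(a, b)

    def edge_weight(self, a: str, b: str) -> float:
        return float(self._graph.edges[a, b]["weight"])

    def degree_weight(self, node_id: str) -> float:
        return float(self._graph.degree(node_id, weight="weight"))

    def neighbors(self, node_id: str) -> list[str]:
        return list(self._graph.neighbors(node_id))

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges with canonical (lexicographic) endpoint orientation."""
        return [
            (a, b, float(d["weight"])) if a <= b else (b, a, float(d["weight"]))
            for a, b, d in self._graph.edges(data=True)
        ]

    def with_nodes(self, node_ids: Iterable[str]) -> "InteractionNetwork":
        """Return a copy with the given ids added as (possibly isolated) nodes."""
        out = InteractionNetwork.from_graph(self._graph)
        for n in node_ids:
            out._graph.add_node(str(n))
        return out

    def adjacency(self) -> sp.csr_array:
        """Symmetric weighted adjacency in node order (CSR)."""
        return sp.csr_array(
            nx.to_scipy_sparse_array(self._graph, nodelist=self.node_ids, weight="weight")
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<InteractionNetwork: {self.n_nodes} nodes, {self.n_edges} edges>"
        )


@dataclass(frozen=True)
class BipartiteDTI:
    """Known positive (drug, protein) interaction pairs.

    ``drug_ids`` / ``protein_ids`` are the induced entity sets (sorted for
    determinism): exactly the drugs and proteins that appear in ``pairs``.
    """

    pairs: frozenset[tuple[str, str]]

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        object.__setattr__(
            self, "pairs", frozenset((str(d), str(p)) for d, p in pairs)
        )

    @property
    def drug_ids(self) -> list[str]:
        return sorted({d for d, _ in self.pairs})

    @property
    def protein_ids(self) -> list[str]:
        return sorted({p for _, p in self.pairs})

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


class FeatureMatrix:
    """N entities x D features with an aligned entity-id index.

    Rows align one-to-one with ``entity_ids``; ``feature_names`` labels the
    D columns. Fingerprint matrices are binary before any weighting.
    """

    def __init__(
        self,
        entity_ids: Sequence[str],
        values: np.ndarray,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(entity_ids) != values.shape[0]:
            raise ValueError(
                f"{len(entity_ids)} entity ids for {values.shape[0]} rows"
            )
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(values.shape[1])]
        if len(feature_names) != values.shape[1]:
            raise ValueError(
                f"{len(feature_names)} feature names for {values.shape[1]} columns"
            )
        self.entity_ids = [str(e) for e in entity_ids]
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        self.values = values
        self.feature_names = list(feature_names)
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self._index[entity_id]]

    def rows(self, entity_ids: Sequence[str]) -> np.ndarray:
        missing = [e for e in entity_ids if e not in self._index]
        if missing:
            raise KeyError(f"entities missing from feature matrix: {missing}")
        return self.values[[self._index[e] for e in entity_ids]]

    def subset(self, entity_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(entity_ids, self.rows(entity_ids), self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            [str(i) for i in frame.index],
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FeatureMatrix: {self.n_entities} x {self.n_features}>"


@dataclass
class AffinityMatrix:
    """Row-stacked converged RWR distributions.

    Row ``i`` is the fixed point of ``r = (1-c) A r + c q`` seeded at entity
    ``i``; entry ``(i, j)`` measures how closely node ``j`` is connected to
    seed ``i``. Within a seed's connected component each row sums to 1 and
    the diagonal (seed self-affinity) is at least the restart probability.
    """

    entity_ids: list[str]
    values: np.ndarray
    restart_c: float
    _index: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.entity_ids)):
            raise ValueError("affinity matrix must be square over entity_ids")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self._index[entity_id]]

    def affinity(self, seed_id: str, node_id: str) -> float:
        return float(self.values[self._index[seed_id], self._index[node_id]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_ids, columns=self.entity_ids
        )
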