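"""Hierarchical brain-tissue ontology.

The ontology is a rooted tree whose most fine-grained tissues (the leaves)
are the prediction targets of the imputation model, and whose coarse
composite tissues (GTEx-style sampled regions) each map to a non-empty set
of subordinate leaves.  The tree also supplies the graph operator for the
tissue-embedding network: the symmetric-normalized adjacency with self
loops, the standard first-order graph-convolution propagation matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BrainOntology",
    "OntologyError",
    "load_ontology",
    "subordinate_leaves",
    "normalized_adjacency",
    "tree_distance",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontology documents."""


@dataclass
class BrainOntology:
    """A rooted tissue tree with a distinguished leaf layer and composite map.

    Parameters
    ----------
    nodes : list of dict
        Tissue records with keys ``id``, ``name``, ``level``, ``parent``
        (parent is ``None`` for the root).  Document order is preserved and
        defines the row/column order of the graph operator.
    leaf_ids : list of str
        The fine-grained tissues, in stable order.
    composite_map : dict
        composite tissue id -> ordered list of subordinate leaf ids.
    """

    nodes: list[dict]
    leaf_ids: list[str]
    composite_map: dict[str, list[str]]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {n["id"]: i for i, n in enumerate(self.nodes)}
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n["id"] for n in self.nodes]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def composite_ids(self) -> list[str]:
        """Canonical composite order: key order of the document."""
        return list(self.composite_map)

    def parent_of(self, node_id: str) -> str | None:
        return self.nodes[self._index[node_id]]["parent"]

    def node_index(self, node_id: str) -> int:
        return self._index[node_id]

    def leaf_index(self, leaf_id: str) -> int:
        return self.leaf_ids.index(leaf_id)

    def graph(self) -> nx.Graph:
        """Undirected tree graph over all nodes (hierarchy edges symmetrized)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for n in self.nodes:
            if n["parent"] is not None:
                g.add_edge(n["parent"], n["id"])
        return g

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [n["id"] for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise OntologyError(f"duplicate node ids: {dupes}")
        known = set(ids)
        roots = [n["id"] for n in self.nodes if n["parent"] is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {roots}")
        for n in self.nodes:
            if n["parent"] is not None and n["parent"] not in known:
                raise OntologyError(
                    f"node {n['id']!r} has unknown parent {n['parent']!r}"
                )
        g = self.graph()
        if g.number_of_edges() != len(self.nodes) - 1 or not nx.is_connected(g):
            raise OntologyError("parent links do not form a tree (cycle or disconnect)")
        has_child = {n["parent"] for n in self.nodes if n["parent"] is not None}
        for leaf in self.leaf_ids:
            if leaf not in known:
                raise OntologyError(f"unknown leaf id {leaf!r}")
            if leaf in has_child:
                raise OntologyError(f"leaf {leaf!r} has children")
        leaf_set = set(self.leaf_ids)
        for comp, leaves in self.composite_map.items():
            if not leaves:
                raise OntologyError(f"composite {comp!r} maps to no leaves")
            bad = [l for l in leaves if l not in leaf_set]
            if bad:
                raise OntologyError(f"composite {comp!r} references unknown leaves {bad}")
        # flag overlapping composites explicitly (allowed, but surfaced)
        seen: dict[str, str] = {}
        self.overlapping_composites: list[tuple[str, str, str]] = []
        for comp, leaves in self.composite_map.items():
            for l in leaves:
                if l in seen:
                    self.overlapping_composites.append((seen[l], comp, l))
                seen[l] = comp


def load_ontology(path) -> BrainOntology:
    """Load and validate an ontology JSON document.

    Schema: ``{"nodes": [{"id", "name", "level", "parent"}...],
    "composites": {compositeId: [leafId, ...]}}``.  Leaves are the nodes
    without children, in document order, unless the document lists them
    explicitly under ``"leaves"``.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise OntologyError(f"malformed ontology document: {e}") from e
    for key in ("nodes", "composites"):
        if key not in doc:
            raise OntologyError(f"ontology document missing {key!r}")
    nodes = []
    for raw in doc["nodes"]:
        missing = {"id", "name", "level", "parent"} - set(raw)
        if missing:
            raise OntologyError(f"node {raw.get('id', raw)!r} missing fields {sorted(missing)}")
        nodes.append({k: raw[k] for k in ("id", "name", "level", "parent")})
    if "leaves" in doc:
        leaf_ids = list(doc["leaves"])
    else:
        has_child = {n["parent"] for n in nodes if n["parent"] is not None}
        leaf_ids = [n["id"] for n in nodes if n["id"] not in has_child]
    composites = {str(k): list(v) for k, v in doc["composites"].items()}
    return BrainOntology(nodes=nodes, leaf_ids=leaf_ids, composite_map=composites)


def save_ontology(ont: BrainOntology, path) -> None:
    doc = {"nodes": ont.nodes, "leaves": ont.leaf_ids, "composites": ont.composite_map}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def subordinate_leaves(ont: BrainOntology, composite_id: str) -> list[str]:
    """Leaves subordinate to a composite tissue, in leaf_ids order."""
    if composite_id not in ont.composite_map:
        raise KeyError(f"unknown composite tissue {composite_id!r}")
    members = set(ont.composite_map[composite_id])
    return [l for l in ont.leaf_ids if l in members]


def normalized_adjacency(ont: BrainOntology) -> np.ndarray:
    """Symmetric-normalized adjacency with self loops over all nodes.

    Returns ``D^{-1/2} (A + I) D^{-1/2}`` where ``A`` is the undirected
    parent-child adjacency and ``D`` the degree matrix of ``A + I``.
    Row/column order is the document node order.  All eigenvalues lie in
    ``[-1, 1]``.
    """
    n = ont.n_nodes
    a = np.zeros((n, n))
    for node in ont.nodes:
        if node["parent"] is not None:
            i = ont.node_index(node["id"])
            j = ont.node_index(node["parent"])
            a[i, j] = a[j, i] = 1.0
    a_hat = a + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def tree_distance(ont: BrainOntology, a: str, b: str) -> int:
    """Number of edges on the unique path between two tissue nodes."""
    for x in (a, b):
        if x not in ont._index:
            raise KeyError(f"unknown tissue id {x!r}")
    if a == b:
        return 0
    # walk both nodes to the root, compare ancestor chains
    def chain(x: str) -> list[str]:
        out = [x]
        while (p := ont.parent_of(out[-1])) is not None:
            out.append(p)
        return out

    ca, cb = chain(a), chain(b)
    set_a = set(ca)
    steps_b = 0
    for node in cb:
        if node in set_a:
            return ca.index(node) + steps_b
        steps_b += 1
    raise OntologyError("nodes share no ancestor (not a tree)")
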