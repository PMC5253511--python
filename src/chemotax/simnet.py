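"""Structural-similarity network of metabolites.

An undirected simple graph over metabolites in which an edge joins every
pair whose Tanimoto similarity strictly exceeds a threshold (default
0.85, the conventional cut-off above which two compounds are considered
to share bioactive features).  Metabolites similar to nothing remain as
isolated nodes so that downstream singleton-group accounting is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .chem_fingerprints import Fingerprint, fingerprint_matrix

logger = logging.getLogger(__name__)

DEFAULT_TANIMOTO_THRESHOLD = 0.85


@dataclass
class SimilarityNetwork:
    """Simple undirected graph; each edge carries its Tanimoto value."""

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def isolated_nodes(self) -> set[str]:
        return {n for n, d in self.graph.degree() if d == 0}


def n_pairs(n: int) -> int:
    """Number of unordered pairs n(n-1)/2 evaluated for n metabolites."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def build_network(
    fingerprints: Sequence[Fingerprint],
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> SimilarityNetwork:
    """All-pairs Tanimoto scan; edge iff similarity > threshold (strict).

    All n(n-1)/2 unordered pairs are evaluated with one integer matrix
    product.  Empty (all-zero) fingerprints cannot clear any positive
    threshold; they are kept as isolated nodes and logged, and no pair
    similarity involving them is materialised.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if len(fingerprints) < 2:
        raise ValueError("need at least 2 fingerprints")
    ids, B = fingerprint_matrix(fingerprints)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate metabolite ids")

    pop = B.sum(axis=1).astype(np.int64)
    empty = pop == 0
    if empty.any():
        logger.warning("%d empty fingerprints kept as isolated nodes", int(empty.sum()))

    inter = (B.astype(np.int64) @ B.T.astype(np.int64)).astype(np.float64)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)

    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = sim[iu, ju] > threshold
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], tanimoto=float(sim[i, j]))
    return SimilarityNetwork(graph=g, threshold=threshold)


def connected_components(net: SimilarityNetwork) -> tuple[list[set[str]], set[str]]:
    """Components of the non-isolated subgraph, plus the isolated set.

    Mirrors the usual bookkeeping in which degree-0 metabolites are "not
    included in the network": they are reported separately and never
    counted as size-1 components.
    """
    isolated = net.isolated_nodes()
    sub = net.graph.subgraph(set(net.graph.nodes) - isolated)
    comps = sorted(
        (set(c) for c in nx.connected_components(sub)),
        key=lambda c: (-len(c), min(c)),
    )
    return comps, isolated


def degree_distribution(net: SimilarityNetwork) -> dict[int, int]:
    """Map degree -> node count; satisfies the handshake identity."""
    dist: dict[int, int] = {}
    for _, d in net.graph.degree():
        dist[d] = dist.get(d, 0) + 1
    return dist


def write_edge_tsv(net: SimilarityNetwork, path: str | Path) -> None:
    """Edge list as ``id_a<TAB>id_b<TAB>tanimoto`` (6 decimals), sorted."""
    rows = sorted(
        (min(u, v), max(u, v), d["tanimoto"]) for u, v, d in net.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        for a, b, t in rows:
            fh.write(f"{a}\t{b}\t{t:.6f}\n")


def write_component_tsv(net: SimilarityNetwork, path: str | Path) -> None:
    comps, isolated = connected_components(net)
    with open(path, "w") as fh:
        fh.write("component_id\tsize\tmembers\n")
        for i, comp in enumerate(comps, 1):
            fh.write(f"C{i}\t{len(comp)}\t{','.join(sorted(comp))}\n")
        fh.write(f"isolated\t{len(isolated)}\t{','.join(sorted(isolated))}\n")


def write_degree_tsv(net: SimilarityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("degree\tcount\n")
        for d, c in sorted(degree_distribution(net).items()):
            fh.write(f"{d}\t{c}\n")
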