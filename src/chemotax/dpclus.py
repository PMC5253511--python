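"""DPClus density–periphery graph clustering of the similarity network.

DPClus extracts densely connected node sets from a simple undirected
graph, controlled by two parameters:

* cluster density ``d_k = |E| / |E|_max`` — internal edge count over the
  maximum possible ``N_k (N_k - 1) / 2`` for a cluster of ``N_k`` nodes;
* cluster property ``cp_nk = E_nk / (d_k * N_k)`` — the connectivity of a
  candidate node ``n`` to cluster ``k`` (``E_nk`` edges into the cluster),
  normalised by cluster density and size.

The variant implemented here is deterministic seed-and-grow-and-remove:

1. weight each edge by the number of common neighbours of its endpoints
   and each node by the sum of its incident edge weights;
2. seed a cluster at the highest-weight node (ties: higher degree, then
   lexicographically smallest id);
3. grow greedily: consider non-member neighbours in descending ``E_nk``
   (same tie-break) and add the first whose addition keeps density
   ``>= d`` and whose ``cp_nk >= cp``; stop when none qualifies;
4. in overlapping mode, extend the finished cluster once more by the same
   acceptance test over the *original* graph, so nodes already claimed by
   earlier clusters may join;
5. remove the cluster from the working graph and repeat while edges
   remain.

Metabolites left in no cluster become singleton groups, so the union of
all groups always covers the input node set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .simnet import SimilarityNetwork

DEFAULT_DENSITY = 0.9
DEFAULT_CP = 0.5
DEFAULT_MIN_SIZE = 2


@dataclass(frozen=True)
class MetaboliteGroup:
    """A cluster of structurally similar metabolites, or a singleton."""

    group_id: str
    member_ids: frozenset[str]
    is_singleton: bool

    def __post_init__(self) -> None:
        if self.is_singleton and len(self.member_ids) != 1:
            raise ValueError("singleton group must have exactly one member")
        if not self.member_ids:
            raise ValueError("empty group")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def density(members: Iterable[str], graph: nx.Graph) -> float:
    """Cluster density |E| / (N(N-1)/2) for the induced subgraph."""
    members = set(members)
    n = len(members)
    if n < 2:
        raise ValueError("density requires at least 2 members")
    e = graph.subgraph(members).number_of_edges()
    return e / (n * (n - 1) / 2)


def cluster_property(node: str, members: set[str], graph: nx.Graph) -> float:
    """cp_nk = E_nk / (d_k * N_k) for a node outside the cluster."""
    if node in members:
        raise ValueError(f"node {node!r} is already a cluster member")
    d_k = density(members, graph)
    if d_k == 0:
        raise ValueError("cluster property undefined for zero-density cluster")
    e_nk = sum(1 for m in members if graph.has_edge(node, m))
    return e_nk / (d_k * len(members))


def _node_weights(g: nx.Graph) -> dict[str, float]:
    """Node weight = sum over incident edges of |common neighbours|."""
    w: dict[str, float] = {n: 0.0 for n in g.nodes}
    for u, v in g.edges:
        cw = len(set(g[u]) & set(g[v]))
        w[u] += cw
        w[v] += cw
    return w


def _grow(members: set[str], g: nx.Graph, d_in: float, cp_in: float) -> None:
    """Greedy growth of ``members`` in place over graph ``g``."""
    while True:
        frontier = set()
        for m in members:
            frontier.update(g[m])
        frontier -= members
        if not frontier:
            return
        n_k = len(members)
        internal = g.subgraph(members).number_of_edges()
        d_k = internal / (n_k * (n_k - 1) / 2) if n_k >= 2 else None
        def attachment(n: str) -> int:
            # common-neighbour weight of the candidate's edges into the
            # cluster; separates tightly embedded neighbours from bridge
            # endpoints when raw edge counts tie
            return sum(
                len(set(g[n]) & set(g[m])) for m in members if g.has_edge(n, m)
            )

        candidates = sorted(
            frontier,
            key=lambda n: (
                -sum(1 for m in members if g.has_edge(n, m)),
                -attachment(n),
                -g.degree(n),
                n,
            ),
        )
        added = False
        for cand in candidates:
            e_nk = sum(1 for m in members if g.has_edge(cand, m))
            new_density = (internal + e_nk) / ((n_k + 1) * n_k / 2)
            if new_density < d_in:
                continue
            # a lone seed has no defined density; its first neighbour
            # always forms a density-1 pair, so cp is not tested
            if d_k is not None and d_k > 0:
                cp_nk = e_nk / (d_k * n_k)
                if cp_nk < cp_in:
                    continue
            members.add(cand)
            added = True
            break
        if not added:
            return


def dpclus(
    net: SimilarityNetwork | nx.Graph,
    d_in: float = DEFAULT_DENSITY,
    cp_in: float = DEFAULT_CP,
    min_size: int = DEFAULT_MIN_SIZE,
    overlapping: bool = True,
) -> list[MetaboliteGroup]:
    """Cluster the network into overlapping metabolite groups.

    Returns non-singleton groups (size >= ``min_size``, density >= ``d_in``)
    in extraction order followed by singleton groups for every node that
    ended up in no cluster.  Output is a deterministic function of the
    edge set alone — node insertion order does not matter.
    """
    if not 0 < d_in <= 1:
        raise ValueError(f"d must be in (0, 1], got {d_in}")
    if not 0 < cp_in <= 1:
        raise ValueError(f"cp must be in (0, 1], got {cp_in}")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    original = net.graph if isinstance(net, SimilarityNetwork) else net
    work = nx.Graph()
    work.add_nodes_from(sorted(original.nodes))
    work.add_edges_from(original.edges)

    clusters: list[set[str]] = []
    while work.number_of_edges() > 0:
        weights = _node_weights(work)
        seed = min(work.nodes, key=lambda n: (-weights[n], -work.degree(n), n))
        members = {seed}
        _grow(members, work, d_in, cp_in)
        if overlapping:
            _grow(members, original, d_in, cp_in)
        if len(members) >= min_size:
            clusters.append(set(members))
        work.remove_nodes_from(members & set(work.nodes))

    groups: list[MetaboliteGroup] = []
    covered: set[str] = set()
    for i, members in enumerate(clusters, 1):
        groups.append(MetaboliteGroup(f"G{i:04d}", frozenset(members), False))
        covered |= members
    for j, node in enumerate(sorted(set(original.nodes) - covered), 1):
        groups.append(MetaboliteGroup(f"S{j:04d}", frozenset({node}), True))
    return groups


def group_size_distribution(groups: Sequence[MetaboliteGroup]) -> dict[int, int]:
    """Map group size -> number of groups (singletons counted at size 1)."""
    return dict(Counter(g.size for g in groups))


def write_groups_tsv(groups: Sequence[MetaboliteGroup], path: str | Path) -> None:
    """One row per membership: ``group_id<TAB>metabolite_id<TAB>is_singleton``."""
    with open(path, "w") as fh:
        fh.write("group_id\tmetabolite_id\tis_singleton\n")
        for g in groups:
            for m in sorted(g.member_ids):
                fh.write(f"{g.group_id}\t{m}\t{int(g.is_singleton)}\n")


def read_groups_tsv(path: str | Path) -> list[MetaboliteGroup]:
    rows: dict[str, tuple[set[str], bool]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_id"):
            raise ValueError(f"{path}: missing groups header")
        for line in fh:
            gid, mid, singleton = line.rstrip("\n").split("\t")
            if gid not in rows:
                rows[gid] = (set(), singleton == "1")
                order.append(gid)
            rows[gid][0].add(mid)
    return [MetaboliteGroup(g, frozenset(rows[g][0]), rows[g][1]) for g in order]


def write_group_size_tsv(groups: Sequence[MetaboliteGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("size\tcount\n")
        for size, count in sorted(group_size_distribution(groups).items()):
            fh.write(f"{size}\t{count}\n")
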