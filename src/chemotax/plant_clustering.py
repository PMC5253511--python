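"""Plant classification from binary metabolite-group profiles.

Two plants with profile vectors x, y of length p are compared through the
binary pair counts

    a = |{j : x_j = 1, y_j = 1}|,  b = |{j : x_j = 1, y_j = 0}|,
    c = |{j : x_j = 0, y_j = 1}|,

from which the Simpson coefficient  S_s = a / min(a+b, a+c)  and the
Jaccard coefficient  S_j = a / (a+b+c)  are formed.  Simpson divides by
the smaller profile size, so it is insensitive to how unequally well two
plants' metabolite contents are recorded and equals 1 for nested
profiles; Jaccard penalises any asymmetry.  Similarities are transformed
to distances d = 1 - s and clustered with Ward's agglomerative method.

Two Ward dialects are exposed, mirroring the long-standing hclust
ambiguity: ``ward.D`` applies the Lance–Williams Ward update directly to
the supplied distances (the default), ``ward.D2`` applies it to squared
distances.  Both are realised through SciPy's Ward linkage, which
operates on squared input internally: feeding sqrt(d) and squaring the
resulting heights reproduces ward.D exactly; feeding d directly is
ward.D2.

Trees are compared with Baker's Gamma: for each unordered leaf pair,
record in each tree the lowest number of clusters k at which the pair
first co-clusters under k-cuts (equivalently, n minus the merge stage
uniting them); the coefficient is the Spearman rank correlation (average
ranks on ties) between the two pair vectors, in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr


# ---------------------------------------------------------------- coefficients

def pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """Binary pair counts (a, b, c) for equal-length 0/1 vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    return a, b, c


def simpson(x: np.ndarray, y: np.ndarray) -> float:
    """Simpson similarity a / min(a+b, a+c); errors on an all-zero vector."""
    a, b, c = pair_counts(x, y)
    denom = min(a + b, a + c)
    if denom == 0:
        raise ValueError("Simpson undefined: one vector is all-zero")
    return a / denom


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard similarity a / (a+b+c); errors when both vectors are all-zero."""
    a, b, c = pair_counts(x, y)
    if a + b + c == 0:
        raise ValueError("Jaccard undefined: both vectors are all-zero")
    return a / (a + b + c)


def distance_matrix(M, coefficient: str = "simpson") -> pd.DataFrame:
    """Pairwise plant distances D_ij = 1 - s(row_i, row_j).

    ``M`` is a PlantGroupMatrix (or binary DataFrame).  Every row must be
    nonzero.  Vectorised over the a-counts matrix ``X X^T``.
    """
    df = M.df if hasattr(M, "df") else M
    X = df.to_numpy().astype(np.int64)
    rows = X.sum(axis=1)
    if (rows == 0).any():
        bad = list(df.index[rows == 0])
        raise ValueError(f"all-zero profile rows: {bad[:5]}")
    A = X @ X.T
    if coefficient == "simpson":
        denom = np.minimum(rows[:, None], rows[None, :])
    elif coefficient == "jaccard":
        denom = rows[:, None] + rows[None, :] - A
    else:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    D = 1.0 - A / denom
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=df.index, columns=df.index)


# ------------------------------------------------------------------ dendrogram

@dataclass
class Dendrogram:
    """Agglomerative merge tree: SciPy linkage matrix plus leaf labels."""

    Z: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for t, (i, j, h, _) in enumerate(self.Z):
            height[n + t] = float(h)

        def render(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_h - height[node]:.6g}"
            i, j = int(self.Z[node - n, 0]), int(self.Z[node - n, 1])
            h = height[node]
            return f"({render(i, h)},{render(j, h)}):{parent_h - h:.6g}"

        root = n + len(self.Z) - 1
        h = height[root]
        i, j = int(self.Z[-1, 0]), int(self.Z[-1, 1])
        return f"({render(i, h)},{render(j, h)});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def ward_cluster(D, dialect: str = "ward.D") -> Dendrogram:
    """Ward hierarchical clustering of a symmetric distance matrix."""
    if hasattr(D, "to_numpy"):
        labels = [str(i) for i in D.index]
        A = D.to_numpy(dtype=float)
    else:
        A = np.asarray(D, dtype=float)
        labels = [str(i) for i in range(A.shape[0])]
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(A, A.T):
        raise ValueError("distance matrix must be symmetric")
    if (A < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(A), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    y = squareform(A, checks=False)
    if dialect == "ward.D":
        Z = sch.linkage(np.sqrt(y), method="ward")
        Z[:, 2] **= 2  # undo the internal square root: heights on the d scale
    elif dialect == "ward.D2":
        Z = sch.linkage(y, method="ward")
    else:
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    return Dendrogram(Z=Z, labels=labels)


# ----------------------------------------------------------------- partitions

@dataclass
class PlantPartition:
    """Flat assignment of plants to groups from a dendrogram cut."""

    assignment: dict[str, str]

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for plant, gid in self.assignment.items():
            out.setdefault(gid, set()).add(plant)
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("plant_id\tgroup_id\n")
            for plant in sorted(self.assignment):
                fh.write(f"{plant}\t{self.assignment[plant]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlantPartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["plant_id"], df["group_id"])))


def _relabel(raw: Sequence[int], labels: Sequence[str]) -> PlantPartition:
    # stable group ids: numbered by first appearance in sorted-label order
    order: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for lab in sorted(labels):
        g = raw[list(labels).index(lab)]
        if g not in order:
            order[g] = f"P{len(order) + 1:02d}"
        assignment[lab] = order[g]
    return PlantPartition(assignment)


def cut_tree(t: Dendrogram, k: int) -> PlantPartition:
    """Cut the dendrogram into exactly k flat groups."""
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = sch.cut_tree(t.Z, n_clusters=k).ravel()
    return _relabel(list(raw), t.labels)


def cut_tree_heights(
    t: Dendrogram,
    default_height: float,
    subtree_heights: Mapping[int, float] | None = None,
) -> PlantPartition:
    """Cut with per-subtree thresholds.

    The tree is walked from the root; a node whose merge height does not
    exceed the applicable threshold closes its whole subtree into one
    group.  ``subtree_heights`` maps internal node ids (SciPy convention:
    leaf i has id i, the t-th merge has id n+t) to thresholds that replace
    the inherited one for that subtree.  This makes the manual practice of
    cutting different parts of a tree at different heights explicit and
    reproducible.
    """
    subtree_heights = dict(subtree_heights or {})
    n = t.n_leaves
    root = n + len(t.Z) - 1
    for node in subtree_heights:
        if not 0 <= node <= root:
            raise ValueError(f"invalid node id {node}")
    raw = [0] * n
    counter = 0

    def leaves_of(node: int) -> list[int]:
        if node < n:
            return [node]
        i, j = int(t.Z[node - n, 0]), int(t.Z[node - n, 1])
        return leaves_of(i) + leaves_of(j)

    def walk(node: int, threshold: float) -> None:
        nonlocal counter
        threshold = subtree_heights.get(node, threshold)
        h = 0.0 if node < n else float(t.Z[node - n, 2])
        if node < n or h <= threshold:
            counter += 1
            for leaf in leaves_of(node):
                raw[leaf] = counter
            return
        walk(int(t.Z[node - n, 0]), threshold)
        walk(int(t.Z[node - n, 1]), threshold)

    walk(root, default_height)
    return _relabel(raw, t.labels)


# -------------------------------------------------------------- Baker's Gamma

def _pair_levels_from_linkage(t: Dendrogram) -> dict[frozenset, int]:
    """For each leaf pair, k = n - (merge stage uniting the pair)."""
    n = t.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    levels: dict[frozenset, int] = {}
    for stage, (i, j, _, _) in enumerate(t.Z, start=1):
        left, right = members.pop(int(i)), members.pop(int(j))
        for u in left:
            for v in right:
                levels[frozenset((t.labels[u], t.labels[v]))] = n - stage
        members[n + stage - 1] = left + right
    return levels


def _pair_levels_from_newick(newick: str) -> dict[frozenset, int]:
    """Pair co-clustering levels for an arbitrary rooted tree.

    Internal nodes are ranked bottom-up by their height above the leaves
    (ties: smallest descendant label); a pair's level is n minus the rank
    of its most recent common ancestor.
    """
    tree = _parse_newick(newick)

    leaves_below: dict[int, list[str]] = {}
    age: dict[int, float] = {}
    internal: list[int] = []

    def fill(node_id: int) -> tuple[list[str], float]:
        children, label, _ = tree[node_id]
        if not children:
            leaves_below[node_id] = [label]
            age[node_id] = 0.0
            return [label], 0.0
        labs: list[str] = []
        node_age = 0.0
        for child in children:
            cl, ca = fill(child)
            _, _, blen = tree[child]
            labs += cl
            node_age = max(node_age, ca + blen)
        leaves_below[node_id] = labs
        age[node_id] = node_age
        internal.append(node_id)
        return labs, node_age

    fill(0)
    n = len(leaves_below[0])
    ranked = sorted(internal, key=lambda nd: (age[nd], min(leaves_below[nd])))
    levels: dict[frozenset, int] = {}
    for rank, nd in enumerate(ranked, start=1):
        children, _, _ = tree[nd]
        for ci in range(len(children)):
            for cj in range(ci + 1, len(children)):
                for u in leaves_below[children[ci]]:
                    for v in leaves_below[children[cj]]:
                        levels[frozenset((u, v))] = n - rank
    return levels


def _parse_newick(newick: str) -> dict[int, tuple[list[int], str, float]]:
    """Minimal Newick reader -> {node_id: (children_ids, label, branch_len)}.

    Node 0 is the root.  Supports labels, branch lengths, and arbitrary
    (non-binary) internal nodes; comments and quoting are not supported.
    """
    s = newick.strip().rstrip(";")
    nodes: dict[int, tuple[list[int], str, float]] = {}
    pos = 0

    def new_node() -> int:
        nid = len(nodes)
        nodes[nid] = ([], "", 0.0)
        return nid

    def parse(nid: int) -> None:
        nonlocal pos
        children, _, _ = nodes[nid]
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = new_node()
                children.append(child)
                parse(child)
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in Newick string")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        label = s[start:pos].strip()
        blen = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            blen = float(s[start:pos])
        nodes[nid] = (children, label, blen)

    root = new_node()
    parse(root)
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string: {s[pos:]!r}")
    return nodes


def _pair_levels(t) -> dict[frozenset, int]:
    if isinstance(t, Dendrogram):
        return _pair_levels_from_linkage(t)
    if isinstance(t, (str, Path)):
        text = str(t)
        if "(" not in text:  # a path rather than a Newick literal
            text = Path(t).read_text()
        return _pair_levels_from_newick(text)
    raise TypeError(f"cannot interpret {type(t).__name__} as a tree")


def bakers_gamma(t1, t2) -> float:
    """Baker's Gamma rank correlation between two trees, in [-1, 1].

    Accepts Dendrogram objects, Newick strings, or Newick file paths.
    Both trees must have identical leaf sets.
    """
    l1, l2 = _pair_levels(t1), _pair_levels(t2)
    if set(l1) != set(l2):
        raise ValueError("trees have different leaf sets")
    pairs = sorted(l1, key=lambda p: tuple(sorted(p)))
    v1 = [l1[p] for p in pairs]
    v2 = [l2[p] for p in pairs]
    if len(set(v1)) == 1 and len(set(v2)) == 1:
        return 1.0  # both trees star-like: identical pair structure
    rho = spearmanr(v1, v2).statistic
    return float(rho)


# ------------------------------------------------------------------- taxonomy

def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read ``plant_id<TAB>genus<TAB>family`` rows (optional header)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            if lineno == 1 and parts[0] == "plant_id":
                continue
            out[parts[0]] = (parts[1], parts[2])
    return out


def taxon_enrichment(
    partition: PlantPartition, taxonomy: Mapping[str, tuple[str, str]]
) -> tuple[dict[str, dict[str, int]], float]:
    """How strongly plant groups are enriched for shared taxa.

    For each group, counts the plants that share a genus (or, failing
    that, a family) with at least one other group member.  Returns the
    per-group table and the overall fraction of co-taxon plants.
    """
    missing = set(partition.assignment) - set(taxonomy)
    if missing:
        raise ValueError(f"taxonomy missing for plant {sorted(missing)[0]!r}")
    per_group: dict[str, dict[str, int]] = {}
    co_total = 0
    for gid, members in sorted(partition.groups().items()):
        genus_count: dict[str, int] = {}
        family_count: dict[str, int] = {}
        for p in members:
            g, f = taxonomy[p]
            genus_count[g] = genus_count.get(g, 0) + 1
            family_count[f] = family_count.get(f, 0) + 1
        co = sum(
            1
            for p in members
            if genus_count[taxonomy[p][0]] > 1 or family_count[taxonomy[p][1]] > 1
        )
        per_group[gid] = {"size": len(members), "co_taxon": co}
        co_total += co
    n = len(partition.assignment)
    return per_group, co_total / n if n else 0.0
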