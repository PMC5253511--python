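"""Plant x metabolite-group binary matrix.

Plant–metabolite relations (a bipartite presence table) are lifted to
plant–group relations: ``M[i, j] = 1`` iff plant *i* contains at least
one metabolite of group *j*.  Grouping structurally similar metabolites
compensates for incompleteness of recorded metabolite content — a plant
missing one compound usually still records a structural relative from the
same group.  Singleton groups are retained as columns so that the binary
pair counts used downstream are computed over the complete group set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .dpclus import MetaboliteGroup

logger = logging.getLogger(__name__)

DEFAULT_MIN_METABOLITES = 30


@dataclass(frozen=True)
class RelationTable:
    """De-duplicated set of (plant_id, metabolite_id) presence records."""

    relations: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "RelationTable":
        pairs = list(pairs)
        unique = frozenset(pairs)
        if len(unique) != len(pairs):
            logger.info("dropped %d duplicate relation rows", len(pairs) - len(unique))
        return cls(unique)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationTable":
        """Read ``plant_id<TAB>metabolite_id`` rows (optional header)."""
        pairs: list[tuple[str, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                if lineno == 1 and parts == ["plant_id", "metabolite_id"]:
                    continue
                pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("plant_id\tmetabolite_id\n")
            for p, m in sorted(self.relations):
                fh.write(f"{p}\t{m}\n")

    @property
    def plants(self) -> set[str]:
        return {p for p, _ in self.relations}

    @property
    def metabolites(self) -> set[str]:
        return {m for _, m in self.relations}

    def metabolites_of(self, plant: str) -> set[str]:
        return {m for p, m in self.relations if p == plant}

    def __len__(self) -> int:
        return len(self.relations)


@dataclass
class PlantGroupMatrix:
    """Binary DataFrame; rows = plants, columns = metabolite groups."""

    df: pd.DataFrame  # 0/1 int8, lexicographic row and column order

    @property
    def plants(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> list[str]:
        return list(self.df.columns)

    @property
    def p(self) -> int:
        """Number of group columns (the binary vector length)."""
        return self.df.shape[1]

    def row(self, plant: str):
        return self.df.loc[plant].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="plant_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlantGroupMatrix":
        df = pd.read_csv(path, sep="\t", index_col="plant_id").astype("int8")
        return cls(df)

    def to_sparse_tsv(self, path: str | Path) -> None:
        """Coordinate triples ``plant_id<TAB>group_id<TAB>1`` for nonzeros."""
        with open(path, "w") as fh:
            fh.write("plant_id\tgroup_id\tvalue\n")
            for plant in self.df.index:
                for group in self.df.columns[self.df.loc[plant] == 1]:
                    fh.write(f"{plant}\t{group}\t1\n")


def filter_plants(
    relations: RelationTable, min_metabolites: int = DEFAULT_MIN_METABOLITES
) -> RelationTable:
    """Keep plants with at least ``min_metabolites`` distinct metabolites.

    Plants with sparsely recorded content carry too little signal to
    place in a metabolite-content classification; the inclusive threshold
    drops them together with their relations.
    """
    counts: dict[str, int] = {}
    for p, _ in relations.relations:
        counts[p] = counts.get(p, 0) + 1
    keep = {p for p, c in counts.items() if c >= min_metabolites}
    if not keep:
        raise ValueError(
            f"no plant has >= {min_metabolites} metabolites; "
            "lower the min_metabolites threshold"
        )
    return RelationTable(frozenset((p, m) for p, m in relations.relations if p in keep))


def build_matrix(
    relations: RelationTable, groups: Sequence[MetaboliteGroup]
) -> PlantGroupMatrix:
    """Lift relations to the binary plant x group matrix.

    Every metabolite appearing in ``relations`` must belong to at least
    one group (the singleton rule upstream guarantees this); a metabolite
    in several overlapping groups sets every corresponding column.
    """
    member_of: dict[str, list[str]] = {}
    for g in groups:
        for m in g.member_ids:
            member_of.setdefault(m, []).append(g.group_id)
    missing = relations.metabolites - set(member_of)
    if missing:
        raise ValueError(
            f"{len(missing)} metabolites in relations belong to no group, "
            f"e.g. {sorted(missing)[:5]}"
        )
    plants = sorted(relations.plants)
    group_ids = sorted(g.group_id for g in groups)
    df = pd.DataFrame(0, index=plants, columns=group_ids, dtype="int8")
    for p, m in relations.relations:
        for gid in member_of[m]:
            df.at[p, gid] = 1
    return PlantGroupMatrix(df)
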