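"""Prediction of unrecorded plant-metabolite relations.

Recorded metabolite content is incomplete: when taxonomically close
plants fall in the same metabolite-content cluster and share different
subsets of one small group of structurally similar metabolites, the
missing combinations are likely real but unrecorded, because similar
metabolic pathways are expected to be active across a taxon.  The
procedure:

1. within each plant cluster, select maximal plant sets S sharing a
   genus (plants left over may form family-level sets); sets of fewer
   than two plants are discarded;
2. collect the candidate metabolite groups K: groups of at most
   ``max_group_size`` members (small groups track single pathways) that
   are associated with at least ``min_support`` plants of S;
3. assign every unrecorded member of each group in K to the plants of S
   that are associated with that group (a plant with no recorded member
   of the group receives nothing).

Metabolites that are mainly structural isomers of each other can be
produced by unrelated pathways, so a user-supplied exclusion list of
metabolite ids is honoured; a helper flags same-molecular-formula group
members for manual review but never auto-excludes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dpclus import MetaboliteGroup
from .plant_matrix import RelationTable
from .plant_clustering import PlantPartition

DEFAULT_MAX_GROUP_SIZE = 8
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class PlantSet:
    """Plants sharing one cluster and one genus (or family)."""

    plants: frozenset[str]
    shared_taxon: str
    taxon_rank: str  # "genus" or "family"
    source_group: str


@dataclass(frozen=True)
class PredictedRelation:
    plant_id: str
    metabolite_id: str
    group_id: str
    n_supporting_plants: int
    evidence: tuple[tuple[str, str], ...] = field(default=(), compare=False)


def select_plant_sets(
    partition: PlantPartition, taxonomy: Mapping[str, tuple[str, str]]
) -> list[PlantSet]:
    """Step 1: same-cluster, same-genus plant sets (genus before family).

    Genus is the finer rank, so genus-level sets are taken first; plants
    not covered by any genus set of size >= 2 may still combine into
    family-level sets within their cluster.
    """
    missing = set(partition.assignment) - set(taxonomy)
    if missing:
        raise ValueError(f"taxonomy missing for plant {sorted(missing)[0]!r}")
    sets: list[PlantSet] = []
    for cluster_id, members in sorted(partition.groups().items()):
        by_genus: dict[str, set[str]] = {}
        for p in members:
            by_genus.setdefault(taxonomy[p][0], set()).add(p)
        covered: set[str] = set()
        for genus, plants in sorted(by_genus.items()):
            if len(plants) >= 2:
                sets.append(PlantSet(frozenset(plants), genus, "genus", cluster_id))
                covered |= plants
        by_family: dict[str, set[str]] = {}
        for p in members - covered:
            by_family.setdefault(taxonomy[p][1], set()).add(p)
        for family, plants in sorted(by_family.items()):
            if len(plants) >= 2:
                sets.append(PlantSet(frozenset(plants), family, "family", cluster_id))
    return sets


def candidate_groups(
    S: PlantSet,
    relations: RelationTable,
    groups: Sequence[MetaboliteGroup],
    max_group_size: int = DEFAULT_MAX_GROUP_SIZE,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[MetaboliteGroup]:
    """Step 2: small groups associated with >= min_support plants of S."""
    plant_metabolites = {p: relations.metabolites_of(p) for p in S.plants}
    K: list[MetaboliteGroup] = []
    for g in sorted(groups, key=lambda g: g.group_id):
        if g.size > max_group_size:
            continue
        support = sum(1 for p in S.plants if plant_metabolites[p] & g.member_ids)
        if support >= min_support:
            K.append(g)
    return K


def assign_predictions(
    S: PlantSet,
    K: Sequence[MetaboliteGroup],
    relations: RelationTable,
    isomer_exclusions: Iterable[str] = (),
) -> list[PredictedRelation]:
    """Step 3: fill unrecorded group members into associated plants.

    For each group in K, every plant of S with at least one recorded
    member of the group receives the group's remaining members as
    predicted relations, minus anything recorded already and minus the
    isomer exclusion list.
    """
    excluded = set(isomer_exclusions)
    plant_metabolites = {p: relations.metabolites_of(p) for p in S.plants}
    predictions: list[PredictedRelation] = []
    for g in K:
        associated = sorted(p for p in S.plants if plant_metabolites[p] & g.member_ids)
        evidence = tuple(
            sorted(
                (p, m)
                for p in associated
                for m in plant_metabolites[p] & g.member_ids
            )
        )
        for p in associated:
            for m in sorted(g.member_ids - plant_metabolites[p] - excluded):
                predictions.append(
                    PredictedRelation(
                        plant_id=p,
                        metabolite_id=m,
                        group_id=g.group_id,
                        n_supporting_plants=len(associated),
                        evidence=evidence,
                    )
                )
    return predictions


def predict_all(
    partition: PlantPartition,
    taxonomy: Mapping[str, tuple[str, str]],
    relations: RelationTable,
    groups: Sequence[MetaboliteGroup],
    max_group_size: int = DEFAULT_MAX_GROUP_SIZE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    isomer_exclusions: Iterable[str] = (),
) -> list[PredictedRelation]:
    """Run steps 1-3 over every qualifying plant set; de-duplicated."""
    excluded = set(isomer_exclusions)
    seen: set[tuple[str, str]] = set()
    out: list[PredictedRelation] = []
    for S in select_plant_sets(partition, taxonomy):
        K = candidate_groups(S, relations, groups, max_group_size, min_support)
        for pred in assign_predictions(S, K, relations, excluded):
            key = (pred.plant_id, pred.metabolite_id)
            if key not in seen:
                seen.add(key)
                out.append(pred)
    return out


def flag_same_formula(
    group: MetaboliteGroup, formulas: Mapping[str, str]
) -> list[frozenset[str]]:
    """Flag group members sharing a molecular formula (isomer review aid).

    Returns the sets of >= 2 members with identical formulas.  Purely
    advisory: nothing is excluded automatically.
    """
    by_formula: dict[str, set[str]] = {}
    for m in group.member_ids:
        if m in formulas:
            by_formula.setdefault(formulas[m], set()).add(m)
    return [frozenset(v) for f, v in sorted(by_formula.items()) if len(v) >= 2]


def read_exclusions(path: str | Path) -> set[str]:
    """One metabolite id per line; blank lines and # comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_predictions_tsv(
    predictions: Sequence[PredictedRelation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("plant_id\tmetabolite_id\tgroup_id\tn_supporting_plants\n")
        for p in predictions:
            fh.write(
                f"{p.plant_id}\t{p.metabolite_id}\t{p.group_id}\t{p.n_supporting_plants}\n"
            )
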