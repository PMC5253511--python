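"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator plants the ground truth every stage is supposed to recover:

* **metabolite groups** — each group has a random base bit pattern; the
  members are copies with independent per-bit flips, so within-group
  Tanimoto similarity stays above the network threshold while distinct
  base patterns keep between-group similarity below it.  Separation is
  enforced empirically (an all-pairs check at generation time; a group
  violating it is redrawn);
* **taxa** — plant families, each owning a disjoint set of metabolite
  groups (its pathway profile).  Every plant of a taxon receives all
  metabolites of its taxon's groups;
* **missingness** — each plant-metabolite relation is deleted
  independently with probability q, emulating incompletely recorded
  metabolite content;
* **usage labels** — one label per taxon, so labels are perfectly
  correlated with group profiles.

Everything is a deterministic function of (config, seed), and the files
emitted are exactly the dialects the pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .chem_fingerprints import (
    Fingerprint,
    write_fingerprint_tsv,
)
from .plant_matrix import RelationTable
from .dpclus import MetaboliteGroup

_USAGE_CYCLE = ["M", "E", "T", "L", "P"]


@dataclass
class SimulationConfig:
    """Knobs of the planted-structure generator.

    Defaults give 5 taxa x 6 plants = 30 plants over 40 planted groups
    (~200 metabolites), with 20% of relations deleted — small enough to
    run the full pipeline in seconds while leaving real work for every
    stage.
    """

    n_taxa: int = 5
    plants_per_taxon: int = 6
    groups_per_taxon: int = 8
    metabolites_per_group: tuple[int, int] = (2, 8)  # inclusive range
    fingerprint_length: int = 166
    n_bits_on: int = 40  # set bits in each group's base pattern
    within_group_bitflip: float = 0.01
    min_base_hamming: int = 50  # base-pattern separation, redraw below this
    tanimoto_threshold: float = 0.85
    missingness: float = 0.2
    usage_profile: dict[int, str] = field(default_factory=dict)  # taxon -> label
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        lo, hi = self.metabolites_per_group
        if not 2 <= lo <= hi:
            raise ValueError("metabolites_per_group range must satisfy 2 <= lo <= hi")
        if self.n_bits_on >= self.fingerprint_length:
            raise ValueError("n_bits_on must be below the fingerprint length")


@dataclass
class SyntheticDataset:
    fingerprints: list[Fingerprint]
    relations: RelationTable
    taxonomy: dict[str, tuple[str, str]]
    labels: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fingerprint_tsv(self.fingerprints, outdir / "fingerprints.tsv")
        self.relations.to_tsv(outdir / "relations.tsv")
        with open(outdir / "taxonomy.tsv", "w") as fh:
            fh.write("plant_id\tgenus\tfamily\n")
            for p in sorted(self.taxonomy):
                g, f = self.taxonomy[p]
                fh.write(f"{p}\t{g}\t{f}\n")
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("plant_id\tuse\n")
            for p in sorted(self.labels):
                fh.write(f"{p}\t{self.labels[p]}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _tanimoto_bits(x: np.ndarray, y: np.ndarray) -> float:
    inter = int((x & y).sum())
    union = int(x.sum() + y.sum()) - inter
    return inter / union if union else 0.0


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset; deterministic given (config, seed).

    Raises after 100 failed redraws of a group whose empirical Tanimoto
    separation violates the threshold (infeasible configurations fail
    loudly rather than silently degrading the planted structure).
    """
    rng = np.random.default_rng(config.seed)
    L = config.fingerprint_length
    n_groups = config.n_taxa * config.groups_per_taxon
    lo, hi = config.metabolites_per_group

    base_patterns: list[np.ndarray] = []
    group_bits: list[list[np.ndarray]] = []
    accepted: list[np.ndarray] = []  # all accepted member fingerprints
    for _ in range(n_groups):
        size = int(rng.integers(lo, hi + 1))
        for attempt in range(100):
            base = np.zeros(L, dtype=np.uint8)
            base[rng.choice(L, size=config.n_bits_on, replace=False)] = 1
            if any(
                int((base != b).sum()) < config.min_base_hamming for b in base_patterns
            ):
                continue
            members = []
            for _ in range(size):
                flips = rng.random(L) < config.within_group_bitflip
                members.append((base ^ flips.astype(np.uint8)).astype(np.uint8))
            ok = all(
                _tanimoto_bits(members[i], members[j]) > config.tanimoto_threshold
                for i in range(size)
                for j in range(i + 1, size)
            ) and all(
                _tanimoto_bits(m, prev) < config.tanimoto_threshold
                for m in members
                for prev in accepted
            )
            if ok:
                break
        else:
            raise RuntimeError(
                "could not plant a separated metabolite group after 100 redraws; "
                "relax min_base_hamming / within_group_bitflip"
            )
        base_patterns.append(base)
        group_bits.append(members)
        accepted.extend(members)

    fingerprints: list[Fingerprint] = []
    planted_groups: dict[str, list[str]] = {}
    mid = 0
    for gi, members in enumerate(group_bits):
        gid = f"T{gi:03d}"
        planted_groups[gid] = []
        for bits in members:
            m = f"m{mid:04d}"
            mid += 1
            fingerprints.append(Fingerprint(m, bits))
            planted_groups[gid].append(m)

    group_ids = sorted(planted_groups)
    taxa_groups = {
        t: group_ids[t * config.groups_per_taxon : (t + 1) * config.groups_per_taxon]
        for t in range(config.n_taxa)
    }

    relations: list[tuple[str, str]] = []
    deleted: list[tuple[str, str]] = []
    taxonomy: dict[str, tuple[str, str]] = {}
    labels: dict[str, str] = {}
    taxa: dict[str, int] = {}
    pi = 0
    for t in range(config.n_taxa):
        label = config.usage_profile.get(t, _USAGE_CYCLE[t % len(_USAGE_CYCLE)])
        for _ in range(config.plants_per_taxon):
            plant = f"p{pi:03d}"
            pi += 1
            taxa[plant] = t
            taxonomy[plant] = (f"Genus{t}", f"Family{t}")
            labels[plant] = label
            for gid in taxa_groups[t]:
                for m in planted_groups[gid]:
                    if rng.random() < config.missingness:
                        deleted.append((plant, m))
                    else:
                        relations.append((plant, m))

    truth = {
        "groups": {g: sorted(ms) for g, ms in planted_groups.items()},
        "taxa": taxa,
        "taxa_groups": {str(t): gs for t, gs in taxa_groups.items()},
        "deleted_relations": sorted(deleted),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    return SyntheticDataset(
        fingerprints=fingerprints,
        relations=RelationTable.from_pairs(relations),
        taxonomy=taxonomy,
        labels=labels,
        truth=truth,
    )


# ---------------------------------------------------------------- scoring

def _membership_ari(
    truth_groups: Mapping[str, Sequence[str]],
    found_groups: Sequence[MetaboliteGroup],
) -> float:
    """ARI between planted and recovered metabolite-group memberships.

    Overlapping recovered groups are flattened by first (deterministic)
    assignment; metabolites present in only one side raise.
    """
    truth_of = {m: g for g, ms in truth_groups.items() for m in ms}
    found_of: dict[str, str] = {}
    for g in found_groups:
        for m in sorted(g.member_ids):
            found_of.setdefault(m, g.group_id)
    if set(truth_of) != set(found_of):
        raise ValueError("metabolite id mismatch between truth and recovered groups")
    ms = sorted(truth_of)
    return float(
        adjusted_rand_score([truth_of[m] for m in ms], [found_of[m] for m in ms])
    )


def score_recovery(
    truth: Mapping,
    groups: Sequence[MetaboliteGroup] | None = None,
    partition=None,
    predictions=None,
    relations: RelationTable | None = None,
    max_group_size: int = 8,
    min_support: int = 2,
) -> dict[str, float]:
    """Score pipeline outputs against the generator's ground truth.

    Reports whichever of these the supplied outputs allow: ``group_ari``
    (planted vs recovered metabolite groups), ``taxon_ari`` (planted taxa
    vs the plant partition), and masked-relation ``recall`` /
    ``recall_recoverable`` / ``precision``.  The recoverable subset of
    deleted relations is re-derived here with an independent brute-force
    triple loop over (plant set, small group, plant): a deleted (p, m) is
    recoverable iff m's planted group has at most ``max_group_size``
    members, p still records another member of it, and at least
    ``min_support`` plants of p's taxon cluster do too.
    """
    report: dict[str, float] = {}
    if groups is not None:
        report["group_ari"] = _membership_ari(truth["groups"], groups)
    if partition is not None:
        taxa = truth["taxa"]
        missing = set(taxa) - set(partition.assignment)
        if missing:
            raise ValueError(f"partition missing plant {sorted(missing)[0]!r}")
        plants = sorted(taxa)
        report["taxon_ari"] = float(
            adjusted_rand_score(
                [taxa[p] for p in plants], [partition.assignment[p] for p in plants]
            )
        )
    if predictions is not None:
        if relations is None or partition is None:
            raise ValueError("prediction scoring needs relations and partition")
        predicted = {(p.plant_id, p.metabolite_id) for p in predictions}
        deleted = {tuple(d) for d in truth["deleted_relations"]}
        group_of = {m: g for g, ms in truth["groups"].items() for m in ms}
        gsize = {g: len(ms) for g, ms in truth["groups"].items()}
        members = {g: set(ms) for g, ms in truth["groups"].items()}
        recorded = {p: relations.metabolites_of(p) for p in relations.plants}
        cluster_of = partition.assignment
        taxa = truth["taxa"]

        recoverable = set()
        for p, m in deleted:
            g = group_of[m]
            if gsize[g] > max_group_size:
                continue
            if p not in recorded or not (recorded[p] & members[g]):
                continue
            peers = [
                q
                for q in recorded
                if taxa.get(q) == taxa[p] and cluster_of.get(q) == cluster_of.get(p)
            ]
            support = sum(1 for q in peers if recorded[q] & members[g])
            if support >= min_support:
                recoverable.add((p, m))

        report["recall"] = len(predicted & deleted) / len(deleted) if deleted else 1.0
        report["recall_recoverable"] = (
            len(predicted & recoverable) / len(recoverable) if recoverable else 1.0
        )
        report["precision"] = (
            len(predicted & deleted) / len(predicted) if predicted else 0.0
        )
    return report
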