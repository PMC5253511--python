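"""Bundled worked-example data.

Small literature-derived tables used in documentation, validation, and
the reproduction script: the six-species *Citrus* example for relation
prediction (one two-metabolite group with its recorded presence table,
and the full per-species lists of predicted unrecorded metabolites), and
a published five-class confusion matrix from a metabolite-content usage
classification of 162 plants.
"""

from __future__ import annotations

import numpy as np

from .dpclus import MetaboliteGroup
from .plant_matrix import RelationTable
from .usage_classification import ConfusionMatrix

# Published dataset summary counts for the 216-plant study: metabolite
# totals and the network/cluster bookkeeping they imply.
REFERENCE_TOTALS = {
    "n_plants": 216,
    "n_metabolites": 6522,
    "n_in_network": 5085,
    "n_clustered": 4700,
}

CITRUS_PLANTS = [
    "Citrus limon",
    "Citrus aurantifolia",
    "Citrus paradisi",
    "Citrus sinensis",
    "Citrus reticulata",
    "Citrus aurantium",
]

# Recorded presence of a two-metabolite structural group across the six
# Citrus species: limonene is recorded in all six, cyclohexane in four.
CITRUS_GROUP = MetaboliteGroup("G0001", frozenset({"Limonene", "Cyclohexane"}), False)

_LIMONENE_IN = CITRUS_PLANTS
_CYCLOHEXANE_IN = [
    "Citrus aurantifolia",
    "Citrus paradisi",
    "Citrus sinensis",
    "Citrus reticulata",
]

CITRUS_RELATIONS = RelationTable.from_pairs(
    [(p, "Limonene") for p in _LIMONENE_IN]
    + [(p, "Cyclohexane") for p in _CYCLOHEXANE_IN]
)

# Full published lists of predicted unrecorded metabolites per species
# (38 plant-metabolite relations in total).
CITRUS_PREDICTED = {
    "Citrus limon": [
        "Gibberellin A4",
        "methyl salicylate",
        "cyclohexane",
        "o-isopropenyl toluene",
        "jasmonic acid",
        "10'-apoviolaxanthal",
        "alpha-trans-bergamotene",
    ],
    "Citrus aurantifolia": [
        "Methyl salicylate",
        "citral",
        "benzeneacetaldehyde",
        "o-isopropenyl toluene",
        "methyl epijasmonate",
        "salvigenin",
    ],
    "Citrus paradisi": [
        "Rhoifolin",
        "isopropanol",
        "methyl salicylate",
        "citral",
        "benzeneacetaldehyde",
        "o-isopropenyl toluene",
    ],
    "Citrus sinensis": [
        "Isoscutellarein 7,8-dimethyl ether",
        "isoscutellarein 7,8,4'-trimethyl ether",
        "o-isopropenyl toluene",
        "methyl epijasmonate",
        "salvigenin",
        "gibberellin A53",
        "violaxanthin",
    ],
    "Citrus reticulata": [
        "Gibberellin A81",
        "gibberellin A9",
        "isopropanol",
        "citral",
        "6-demethoxytangeritin",
        "tetramethylscutellarein",
    ],
    "Citrus aurantium": [
        "Apigenin 7-rutinoside",
        "methyl salicylate",
        "salvigenin",
        "cyclohexane",
        "benzeneacetaldehyde",
        "o-isopropenyl toluene",
    ],
}

# Published usage confusion matrix over 162 plants; rows actual, columns
# predicted, class order M, E, T, L, P.
USAGE_CLASSES = ["M", "E", "T", "L", "P"]
USAGE_CONFUSION = ConfusionMatrix(
    USAGE_CLASSES,
    np.array(
        [
            [81, 0, 0, 0, 0],
            [1, 47, 0, 0, 0],
            [6, 0, 8, 0, 0],
            [8, 1, 0, 5, 0],
            [4, 1, 0, 0, 0],
        ]
    ),
)


def usage_label_lists() -> tuple[list[str], list[str]]:
    """Reconstruct paired (actual, predicted) label lists from the matrix."""
    y_true: list[str] = []
    y_pred: list[str] = []
    for i, actual in enumerate(USAGE_CLASSES):
        for j, predicted in enumerate(USAGE_CLASSES):
            n = int(USAGE_CONFUSION.counts[i, j])
            y_true += [actual] * n
            y_pred += [predicted] * n
    return y_true, y_pred
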