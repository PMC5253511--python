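"""Molecular structures, binary fingerprints, and Tanimoto similarity.

Metabolite structures are read from SDF (multi-record) or MOL (single
record) files with RDKit and turned into fixed-length binary fingerprints.
The Tanimoto coefficient between two fingerprints is

    T(A, B) = AB / (A + B - AB)

where ``A`` and ``B`` are the numbers of set bits in each fingerprint and
``AB`` the number of bits set in both.  Downstream stages consume only the
binary vectors, so the fingerprint scheme is pluggable; hashed atom-pair
fingerprints (default length 166) and MACCS structural keys are provided.

Fingerprints may also be loaded directly from a TSV of
``metabolite_id<TAB>bitstring`` rows, bypassing chemistry I/O entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

logger = logging.getLogger(__name__)

DEFAULT_FP_LENGTH = 166


@dataclass
class Metabolite:
    """A small molecule, optionally carrying a parsed structure."""

    id: str
    name: str
    mol: "Chem.Mol | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError(f"metabolite {self.id!r} has an empty name")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure descriptor of one metabolite."""

    metabolite_id: str
    bits: np.ndarray  # uint8 vector of 0/1

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("fingerprint bits must be binary")
        object.__setattr__(self, "bits", b)

    @property
    def length(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def bitstring(self) -> str:
        return "".join("1" if v else "0" for v in self.bits)

    @classmethod
    def from_bitstring(cls, metabolite_id: str, s: str) -> "Fingerprint":
        if set(s) - {"0", "1"}:
            raise ValueError(f"non-binary character in bitstring for {metabolite_id!r}")
        return cls(metabolite_id, np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))


def load_structures(path: str | Path) -> list[Metabolite]:
    """Read an SDF or MOL file into a list of metabolites.

    Record order is preserved.  Ids come from the record title line when
    present, otherwise ``MOL_<index>`` is generated.  Malformed records are
    skipped with a warning naming the record index; an unreadable file
    raises.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        logger.warning("no valid records in %s", path)
        return []
    RDLogger.DisableLog("rdApp.*")
    metabolites: list[Metabolite] = []
    if path.suffix.lower() == ".mol":
        mol = Chem.MolFromMolFile(str(path))
        if mol is None:
            logger.warning("record 0 of %s is malformed; skipped", path)
        else:
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            mid = name or "MOL_0"
            metabolites.append(Metabolite(id=mid, name=name or mid, mol=mol))
        return metabolites
    supplier = Chem.SDMolSupplier(str(path))
    seen: set[str] = set()
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("record %d of %s is malformed; skipped", i, path)
            continue
        name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mid = name or f"MOL_{i}"
        if mid in seen:  # duplicate titles would break id uniqueness
            mid = f"{mid}_{i}"
        seen.add(mid)
        metabolites.append(Metabolite(id=mid, name=name or mid, mol=mol))
    if not metabolites:
        logger.warning("no valid records in %s", path)
    return metabolites


def compute_fingerprint(
    metabolite: Metabolite,
    length: int = DEFAULT_FP_LENGTH,
    scheme: str = "atompair",
) -> Fingerprint:
    """Fingerprint a parsed structure.

    ``scheme`` is ``"atompair"`` (topological atom pairs hashed to
    ``length`` bits) or ``"maccs"`` (166 structural keys; ``length`` is
    ignored).  Deterministic: the same structure always yields the same
    bit vector.
    """
    if metabolite.mol is None:
        raise ValueError(f"metabolite {metabolite.id!r} has no parsed structure")
    if metabolite.mol.GetNumAtoms() == 0:
        raise ValueError(f"metabolite {metabolite.id!r} has zero atoms")
    if scheme == "atompair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=length)
        bv = gen.GetFingerprint(metabolite.mol)
        arr = np.zeros(length, dtype=np.uint8)
        for b in bv.GetOnBits():
            arr[b] = 1
    elif scheme == "maccs":
        bv = rdMolDescriptors.GetMACCSKeysFingerprint(metabolite.mol)
        arr = np.zeros(166, dtype=np.uint8)
        for b in bv.GetOnBits():
            if b > 0:  # RDKit MACCS bit 0 is always unset padding
                arr[b - 1] = 1
    else:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}")
    return Fingerprint(metabolite.id, arr)


def molecular_formula(metabolite: Metabolite) -> str:
    """Molecular formula of a parsed structure (used by isomer review)."""
    if metabolite.mol is None:
        raise ValueError(f"metabolite {metabolite.id!r} has no parsed structure")
    return rdMolDescriptors.CalcMolFormula(metabolite.mol)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto similarity AB / (A + B - AB) in [0, 1].

    Raises if the fingerprints differ in length or are both empty — a
    0/0 similarity is undefined and returning 0 would silently fabricate
    dissimilarity.
    """
    if fp_a.length != fp_b.length:
        raise ValueError("fingerprint lengths differ")
    a = fp_a.popcount
    b = fp_b.popcount
    if a == 0 and b == 0:
        raise ValueError(
            f"Tanimoto undefined: both fingerprints empty "
            f"({fp_a.metabolite_id!r}, {fp_b.metabolite_id!r})"
        )
    ab = int(np.bitwise_and(fp_a.bits, fp_b.bits).sum())
    return ab / (a + b - ab)


def read_fingerprint_tsv(path: str | Path) -> list[Fingerprint]:
    """Read ``metabolite_id<TAB>bitstring`` rows; all lengths must agree."""
    fps: list[Fingerprint] = []
    length: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                mid, bits = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields") from exc
            fp = Fingerprint.from_bitstring(mid, bits)
            if length is None:
                length = fp.length
            elif fp.length != length:
                raise ValueError(f"{path}:{lineno}: fingerprint length {fp.length} != {length}")
            fps.append(fp)
    ids = [fp.metabolite_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate metabolite ids in {path}")
    return fps


def write_fingerprint_tsv(fps: Iterable[Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fp in fps:
            fh.write(f"{fp.metabolite_id}\t{fp.bitstring}\n")


def fingerprint_matrix(fps: Sequence[Fingerprint]) -> tuple[list[str], np.ndarray]:
    """Stack fingerprints into an (n, L) uint8 matrix in input order."""
    if not fps:
        return [], np.zeros((0, 0), dtype=np.uint8)
    lengths = {fp.length for fp in fps}
    if len(lengths) != 1:
        raise ValueError("fingerprints have mixed lengths")
    return [fp.metabolite_id for fp in fps], np.stack([fp.bits for fp in fps])
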