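"""Similarity-driven synergy-data augmentation.

New labeled instances are created by substituting one drug of an original
pair with library drugs that pass a combined structural / pharmacological
similarity filter:

* structural similarity — Tanimoto coefficient between path-based
  fingerprints, required to be <= ``tc_max`` (default 0.95) so that exact
  or near-identical structures are excluded;
* target-profile similarity — Matthews correlation coefficient between the
  drugs' binary target profiles over the network node set, mapped to
  [0, 1];
* the combined score (default: equal-weight mean of the two terms) must
  reach ``dacs_min`` (default 0.53).

Labels of augmented instances are transferred verbatim from the parent
pair; provenance records the parent and the replaced slot so that
evaluation can exclude descendants of held-out instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from synergnet.features import DrugRecord

__all__ = [
    "Fingerprint",
    "TargetProfile",
    "DACSResult",
    "DACSThresholds",
    "SynergyInstance",
    "DrugLibrary",
    "fingerprint_from_smiles",
    "tanimoto",
    "target_mcc",
    "dacs_score",
    "candidate_substitutes",
    "augment_pair",
    "augment_dataset",
    "read_synergy_table",
    "write_synergy_table",
]

LABELS = ("synergy", "antagonism")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width bit-set fingerprint (indices of set bits)."""

    bits: frozenset[int]
    width: int = 1024

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.width):
            raise ValueError("fingerprint bit index outside [0, width)")


def fingerprint_from_smiles(smiles: str, width: int = 1024) -> Fingerprint:
    """Path-based fingerprint of a SMILES string (requires rdkit)."""
    from rdkit import Chem  # local import: chemistry backend is optional

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=width)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), width=width)


@dataclass(frozen=True)
class TargetProfile:
    """Binary vector over the network node set: 1 iff the drug has a
    recorded association with that protein."""

    values: tuple[int, ...]

    @classmethod
    def from_record(
        cls, record: DrugRecord, node_order: Sequence[str]
    ) -> "TargetProfile":
        targets = record.targets
        return cls(tuple(int(n in targets) for n in node_order))

    def __len__(self) -> int:
        return len(self.values)


def tanimoto(f1: Fingerprint, f2: Fingerprint) -> float:
    """|intersection| / |union| of set bits; 0 when both are empty."""
    if f1.width != f2.width:
        raise ValueError(f"fingerprint widths differ: {f1.width} vs {f2.width}")
    union = f1.bits | f2.bits
    if not union:
        return 0.0
    return len(f1.bits & f2.bits) / len(union)


def target_mcc(p1: TargetProfile, p2: TargetProfile) -> float:
    """Matthews correlation coefficient of the 2x2 contingency of two
    binary target profiles; 0 when either profile is constant."""
    if len(p1) != len(p2):
        raise ValueError(f"profile lengths differ: {len(p1)} vs {len(p2)}")
    a = np.asarray(p1.values)
    b = np.asarray(p2.values)
    tp = int(np.sum((a == 1) & (b == 1)))
    tn = int(np.sum((a == 0) & (b == 0)))
    fp = int(np.sum((a == 0) & (b == 1)))
    fn = int(np.sum((a == 1) & (b == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


@dataclass(frozen=True)
class DACSThresholds:
    """Filter thresholds and the structural/target mixing weight."""

    tc_max: float = 0.95
    dacs_min: float = 0.53
    weight_tc: float = 0.5


@dataclass(frozen=True)
class DACSResult:
    """Similarity assessment of a candidate substitute against a drug."""

    tc: float
    target_mcc: float
    dacs: float
    passes_tc: bool
    passes_dacs: bool

    @property
    def passes(self) -> bool:
        return self.passes_tc and self.passes_dacs


@dataclass(frozen=True)
class SynergyInstance:
    """A labeled (drug pair, cell line) instance with provenance."""

    drug_a: str
    drug_b: str
    cell_line: str
    label: str
    provenance: str = "original"  # "original" or "augmented"
    parent_id: str | None = None
    replaced_slot: str | None = None  # "a" or "b" for augmented instances

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError("degenerate pair: drug_a == drug_b")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.provenance == "augmented" and self.parent_id is None:
            raise ValueError("augmented instance requires a parent id")

    @property
    def instance_id(self) -> str:
        return f"{self.drug_a}:{self.drug_b}@{self.cell_line}"

    @property
    def pair_key(self) -> tuple[str, str, str]:
        a, b = sorted((self.drug_a, self.drug_b))
        return (a, b, self.cell_line)


class DrugLibrary:
    """Drug records with fingerprints and target profiles over a fixed
    node order."""

    def __init__(
        self,
        records: Mapping[str, DrugRecord],
        node_order: Sequence[str],
        fingerprints: Mapping[str, Fingerprint] | None = None,
        fingerprint_width: int = 1024,
    ):
        self.records = dict(records)
        self.node_order = list(node_order)
        self._profiles: dict[str, TargetProfile] = {}
        if fingerprints is not None:
            self.fingerprints = dict(fingerprints)
        else:
            self.fingerprints = {}
            for drug_id, rec in self.records.items():
                if rec.smiles is None:
                    raise ValueError(
                        f"drug {drug_id!r} has no SMILES and no precomputed "
                        "fingerprint"
                    )
                self.fingerprints[drug_id] = fingerprint_from_smiles(
                    rec.smiles, width=fingerprint_width
                )
        missing = set(self.records) - set(self.fingerprints)
        if missing:
            raise ValueError(f"missing fingerprints for {sorted(missing)[:5]}")

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.records)

    def profile(self, drug_id: str) -> TargetProfile:
        if drug_id not in self._profiles:
            self._profiles[drug_id] = TargetProfile.from_record(
                self.records[drug_id], self.node_order
            )
        return self._profiles[drug_id]

    def fingerprint(self, drug_id: str) -> Fingerprint:
        return self.fingerprints[drug_id]


def dacs_score(
    drug_1: str,
    drug_2: str,
    library: DrugLibrary,
    thresholds: DACSThresholds | None = None,
) -> DACSResult:
    """Combined structural + target-profile similarity of two drugs.

    ``dacs = w * tc + (1 - w) * (mcc + 1) / 2`` with default w = 0.5; the
    target MCC is mapped from [-1, 1] onto [0, 1] so both terms share a
    scale.
    """
    thresholds = thresholds or DACSThresholds()
    for d in (drug_1, drug_2):
        if d not in library:
            raise KeyError(f"drug {d!r} not in library")
    tc = tanimoto(library.fingerprint(drug_1), library.fingerprint(drug_2))
    mcc = target_mcc(library.profile(drug_1), library.profile(drug_2))
    w = thresholds.weight_tc
    dacs = w * tc + (1.0 - w) * (mcc + 1.0) / 2.0
    return DACSResult(
        tc=tc,
        target_mcc=mcc,
        dacs=dacs,
        passes_tc=tc <= thresholds.tc_max,
        passes_dacs=dacs >= thresholds.dacs_min,
    )


def candidate_substitutes(
    drug_id: str,
    library: DrugLibrary,
    thresholds: DACSThresholds | None = None,
) -> list[tuple[str, DACSResult]]:
    """Library drugs (query excluded) passing both the Tanimoto ceiling and
    the combined-score floor, sorted by score descending (ties by id)."""
    thresholds = thresholds or DACSThresholds()
    out = []
    for other in library.drug_ids:
        if other == drug_id:
            continue
        result = dacs_score(drug_id, other, library, thresholds)
        if result.passes:
            out.append((other, result))
    out.sort(key=lambda item: (-item[1].dacs, item[0]))
    return out


def augment_pair(
    inst: SynergyInstance,
    library: DrugLibrary,
    thresholds: DACSThresholds | None = None,
    existing_pairs: set[tuple[str, str, str]] | None = None,
) -> list[SynergyInstance]:
    """Generate augmented instances by substituting each slot of a pair.

    For slot "b" first and then slot "a", every passing candidate replaces
    the slot's drug; the cell line and label are kept and provenance points
    back to the parent.  Degenerate pairs (X:X) and duplicates of existing
    original pairs on the same cell line are dropped.
    """
    for d in (inst.drug_a, inst.drug_b):
        if d not in library:
            raise KeyError(f"instance drug {d!r} not in library")
    existing = set(existing_pairs or ())
    out: list[SynergyInstance] = []
    seen: set[tuple[str, str, str]] = set()
    for slot, replaced, kept in (
        ("b", inst.drug_b, inst.drug_a),
        ("a", inst.drug_a, inst.drug_b),
    ):
        for candidate, _result in candidate_substitutes(
            replaced, library, thresholds
        ):
            if candidate == kept:
                continue
            drug_a, drug_b = (
                (kept, candidate) if slot == "b" else (candidate, kept)
            )
            key_a, key_b = sorted((drug_a, drug_b))
            key = (key_a, key_b, inst.cell_line)
            if key in existing or key in seen:
                continue
            seen.add(key)
            out.append(
                SynergyInstance(
                    drug_a=drug_a,
                    drug_b=drug_b,
                    cell_line=inst.cell_line,
                    label=inst.label,
                    provenance="augmented",
                    parent_id=inst.instance_id,
                    replaced_slot=slot,
                )
            )
    return out


def augment_dataset(
    originals: Sequence[SynergyInstance],
    library: DrugLibrary,
    thresholds: DACSThresholds | None = None,
) -> list[SynergyInstance]:
    """Augment every original instance, suppressing duplicates of any
    original pair."""
    existing = {inst.pair_key for inst in originals}
    out: list[SynergyInstance] = []
    for inst in originals:
        if inst.provenance != "original":
            raise ValueError("augment_dataset expects original instances only")
        out.extend(
            augment_pair(inst, library, thresholds, existing_pairs=existing)
        )
    return out


# ---------------------------------------------------------------------------
# Synergy-table serialization
# ---------------------------------------------------------------------------

_HEADER = ["drug_a", "drug_b", "cell_line", "label", "provenance", "parent"]


def write_synergy_table(
    instances: Iterable[SynergyInstance], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for inst in instances:
            parent = (
                f"{inst.parent_id}|{inst.replaced_slot}"
                if inst.provenance == "augmented"
                else "-"
            )
            fh.write(
                f"{inst.drug_a}\t{inst.drug_b}\t{inst.cell_line}\t"
                f"{inst.label}\t{inst.provenance}\t{parent}\n"
            )


def read_synergy_table(path: str | Path) -> list[SynergyInstance]:
    out: list[SynergyInstance] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_HEADER):
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            drug_a, drug_b, cell_line, label, provenance, parent = parts
            parent_id, slot = None, None
            if provenance == "augmented":
                parent_id, slot = parent.rsplit("|", 1)
            out.append(
                SynergyInstance(
                    drug_a=drug_a,
                    drug_b=drug_b,
                    cell_line=cell_line,
                    label=label,
                    provenance=provenance,
                    parent_id=parent_id,
                    replaced_slot=slot,
                )
            )
    return out
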