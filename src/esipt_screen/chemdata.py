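"""Molecule records, I/O, canonicalization and similarity-based set curation.

Training-set curation for the screening models follows the usual QSAR
hygiene: canonical-SMILES deduplication within each class, and
Tanimoto-similarity filters between candidate negative sets and the
ESIPT-positive set so that near-duplicates of positives do not contaminate
the negatives.  A greedy internal similarity dedup (one representative per
>threshold similarity neighbourhood, first kept wins) supports the
structural-innovation arm of the screen.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, List, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

from esipt_screen.fingerprints import bulk_tanimoto, fingerprints

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")


class Label(str, enum.Enum):
    """Class label of a molecule in the screening problem."""

    ESIPT = "ESIPT"
    CONVENTIONAL = "CONVENTIONAL"
    FLUOR_NON_ESIPT = "FLUOR_NON_ESIPT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: id, SMILES, optional class label and ESIPT energy barrier.

    ``barrier`` is the excited-state proton-transfer activation energy in
    kcal/mol; when present it must be positive and finite.
    """

    id: str
    smiles: str
    label: Label = Label.UNKNOWN
    barrier: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.barrier is not None:
            if not math.isfinite(self.barrier) or self.barrier <= 0:
                raise ValueError(
                    f"record {self.id!r}: barrier must be a positive finite "
                    f"kcal/mol value, got {self.barrier!r}"
                )

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"record {self.id!r}: unparseable SMILES {self.smiles!r}")
        return m


@dataclass
class MoleculeSet:
    """Ordered collection of molecule records with unique ids."""

    records: List[MoleculeRecord] = field(default_factory=list)
    name: str = ""
    n_skipped: int = 0  # unparseable rows dropped while reading

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set = set()
            dup = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate ids in set {self.name!r}: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> List[str]:
        return [r.smiles for r in self.records]

    def mols(self) -> List[Chem.Mol]:
        return [r.mol() for r in self.records]


def canonicalize_smiles(smiles: str) -> Optional[str]:
    """Canonical isomeric SMILES of the largest covalent fragment.

    Salt/solvate components are stripped by keeping the fragment with the
    most heavy atoms (ties broken by canonical SMILES order, so the result
    is deterministic).  Returns None for unparseable input.  The output is a
    fixed point: canonicalizing it again returns the same string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        keyed = sorted(
            frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
        )
        mol = keyed[0]
    return Chem.MolToSmiles(mol)


def _parse_barrier(raw: str) -> Optional[float]:
    raw = (raw or "").strip()
    if not raw:
        return None
    return float(raw)


def _parse_label(raw: str) -> Label:
    raw = (raw or "").strip()
    if not raw:
        return Label.UNKNOWN
    return Label(raw)


def read_molecules(path, fmt: Optional[str] = None) -> MoleculeSet:
    """Read a molecule set from CSV (id,smiles[,label,barrier,source]),
    .smi ("SMILES id" per line) or SDF.

    Rows whose SMILES (or molblock) cannot be parsed are skipped with a
    warning and counted in ``MoleculeSet.n_skipped`` — a broken entry must
    never abort a large library screen.  Raises on missing required CSV
    columns or if no molecule at all could be parsed.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".smi": "smi", ".sdf": "sdf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    if fmt not in ("csv", "smi", "sdf"):
        raise ValueError(f"unknown format {fmt!r}")

    records: List[MoleculeRecord] = []
    skipped = 0

    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            if "id" not in cols or "smiles" not in cols:
                raise ValueError(
                    f"{path.name}: CSV must have 'id' and 'smiles' columns, got {cols}"
                )
            for row in reader:
                smi = (row.get("smiles") or "").strip()
                if Chem.MolFromSmiles(smi) is None:
                    skipped += 1
                    logger.warning("%s: skipping unparseable SMILES %r (id=%r)",
                                   path.name, smi, row.get("id"))
                    continue
                records.append(
                    MoleculeRecord(
                        id=str(row["id"]).strip(),
                        smiles=smi,
                        label=_parse_label(row.get("label", "")),
                        barrier=_parse_barrier(row.get("barrier", "")),
                        source=(row.get("source") or "").strip() or None,
                    )
                )
    elif fmt == "smi":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smi = parts[0]
                mid = parts[1] if len(parts) > 1 else f"mol{ln}"
                if Chem.MolFromSmiles(smi) is None:
                    skipped += 1
                    logger.warning("%s:%d skipping unparseable SMILES %r", path.name, ln, smi)
                    continue
                records.append(MoleculeRecord(id=mid, smiles=smi))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("%s: skipping unparseable molblock #%d", path.name, i)
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            records.append(MoleculeRecord(id=mid, smiles=Chem.MolToSmiles(mol)))

    if not records:
        raise ValueError(f"{path.name}: no parseable molecules found")
    return MoleculeSet(records=records, name=path.stem, n_skipped=skipped)


def write_molecules(mols: MoleculeSet, path, fmt: Optional[str] = None) -> None:
    """Write a molecule set; mirrors :func:`read_molecules` for round-trips."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".smi": "smi", ".sdf": "sdf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "label", "barrier", "source"])
            for r in mols:
                w.writerow([
                    r.id, r.smiles,
                    "" if r.label is Label.UNKNOWN else r.label.value,
                    "" if r.barrier is None else repr(r.barrier),
                    r.source or "",
                ])
    elif fmt == "smi":
        with open(path, "w") as fh:
            for r in mols:
                fh.write(f"{r.smiles} {r.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for r in mols:
            m = r.mol()
            m.SetProp("_Name", r.id)
            writer.write(m)
        writer.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")


def canonical_dedup(mols: MoleculeSet) -> MoleculeSet:
    """One record per canonical SMILES; first occurrence kept, order preserved.

    Output records carry the canonical SMILES, so the operation is
    idempotent.  Records whose SMILES cannot be canonicalized are dropped
    (they cannot be compared for uniqueness).
    """
    seen = set()
    kept: List[MoleculeRecord] = []
    for r in mols:
        canon = canonicalize_smiles(r.smiles)
        if canon is None:
            logger.warning("canonical_dedup: dropping unparseable record %r", r.id)
            continue
        if canon in seen:
            continue
        seen.add(canon)
        kept.append(replace(r, smiles=canon))
    return MoleculeSet(records=kept, name=mols.name)


def similarity_filter(
    candidates: MoleculeSet,
    references: MoleculeSet,
    fingerprint: str = "MACCS",
    threshold: float = 0.95,
    mode: str = "keep_below",
) -> MoleculeSet:
    """Filter candidates by their maximum Tanimoto similarity to a reference set.

    ``keep_below`` retains candidates whose maximum similarity to any
    reference is strictly below ``threshold`` (the default curation move:
    exclude near-duplicates of the positive set from a negative set);
    ``keep_above`` is the exact complement, for selecting molecules that do
    resemble the references.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("keep_below", "keep_above"):
        raise ValueError(f"mode must be keep_below or keep_above, got {mode!r}")
    if len(candidates) == 0 or len(references) == 0:
        raise ValueError("similarity_filter requires non-empty candidate and reference sets")

    ref_fps = fingerprints(references.mols(), fingerprint)
    kept: List[MoleculeRecord] = []
    for r, fp in zip(candidates, fingerprints(candidates.mols(), fingerprint)):
        max_sim = max(bulk_tanimoto(fp, ref_fps))
        below = max_sim < threshold
        if (mode == "keep_below") == below:
            kept.append(r)
    return MoleculeSet(records=kept, name=candidates.name)


def internal_dedup_by_similarity(
    mols: MoleculeSet, fingerprint: str = "ECFP4", threshold: float = 0.8
) -> MoleculeSet:
    """Greedy single-pass internal similarity dedup.

    Walking the set in input order, a record is retained iff its Tanimoto
    similarity to every previously retained record is <= ``threshold``; the
    first member of each similarity neighbourhood therefore survives.  The
    output is maximal under that rule: no retained pair exceeds the
    threshold, and every dropped record exceeds it against some survivor.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept: List[MoleculeRecord] = []
    kept_fps: list = []
    for r, fp in zip(mols, fingerprints(mols.mols(), fingerprint)):
        sims = bulk_tanimoto(fp, kept_fps)
        if not sims or max(sims) <= threshold:
            kept.append(r)
            kept_fps.append(fp)
    return MoleculeSet(records=kept, name=mols.name)
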