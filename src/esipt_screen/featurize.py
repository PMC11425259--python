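"""Fingerprint and 2D-descriptor featurization with variance/correlation pruning.

Three representations feed the screening models:

* MACCS keys — 166 keyed substructure bits (bit index = published key
  number, so interpretation can map a bit back to its SMARTS fragment);
* ECFP4 — Morgan circular fingerprint of radius 2 folded to 2048 bits;
* a 2D descriptor panel — RDKit's full 2D physicochemical/topological
  descriptor list (molecular weight, Crippen logP, TPSA, H-bond donor and
  acceptor counts, ring and rotatable-bond counts, partial-charge
  summaries, ...) extended with an ESOL-style logS estimate and rule-based
  acidic/basic group counts as pKa/protonation proxies.

Descriptor matrices are pruned before modelling: zero-variance columns are
dropped, then for every surviving pair with |Pearson r| above the cutoff
(default 0.95) the later-ordered column is dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from esipt_screen.chemdata import MoleculeSet
from esipt_screen.fingerprints import ECFP4_NBITS, fingerprint_mol

logger = logging.getLogger(__name__)

# Ipc grows combinatorially with molecule size and overflows to inf for
# mid-sized molecules, which breaks the finite-features contract downstream.
_EXCLUDED_DESCRIPTORS = {"Ipc"}

_DONOR_GROUP = Chem.MolFromSmarts("[#7,#8;!H0]")


def _num_h_donor_groups(mol: Chem.Mol) -> int:
    """Donor-group count: every N/O bearing at least one H is one donor.

    Group-counting convention (water counts 1) rather than the Lipinski
    H1-only SMARTS, which assigns water zero donors.
    """
    return len(mol.GetSubstructMatches(_DONOR_GROUP))


_OVERRIDE_DESCRIPTORS = {"NumHDonors": _num_h_donor_groups}

_ACIDIC_SMARTS = [
    "[CX3](=O)[OX2H1]",          # carboxylic acid
    "[SX4](=O)(=O)[OX2H1]",      # sulfonic acid
    "[PX4](=O)([OX2H1])",        # phosphonic/phosphoric acid
    "c[OX2H1]",                  # phenol
    "[NX3H1]C(=O)[NX3H1]",       # imide-like N-H between carbonyls
]
_BASIC_SMARTS = [
    "[NX3;H2;!$(NC=O);!$(N[a])]",        # primary aliphatic amine
    "[NX3;H1;!$(NC=O);!$(N[a])]([C])[C]",  # secondary aliphatic amine
    "[NX3;H0;!$(NC=O);!$(N[a])]([C])([C])[C]",  # tertiary aliphatic amine
    "[nX2;$(n1ccccc1)]",                 # pyridine-type aromatic N
    "[NX2]=C[NX3]",                      # amidine
]
_ACIDIC_PATTS = [Chem.MolFromSmarts(s) for s in _ACIDIC_SMARTS]
_BASIC_PATTS = [Chem.MolFromSmarts(s) for s in _BASIC_SMARTS]


@dataclass
class FeatureMatrix:
    """Molecules × named features.

    ``kind`` records the representation (ECFP4, MACCS or DESC2D); fingerprint
    matrices contain only {0, 1}.  Row order matches ``molecule_ids``.
    """

    molecule_ids: List[str]
    feature_names: List[str]
    values: np.ndarray
    kind: str
    failed_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.molecule_ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.feature_names)

    def subset_features(self, names: List[str]) -> "FeatureMatrix":
        """Column subset (and reorder) by feature name."""
        index = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        cols = [index[n] for n in names]
        return FeatureMatrix(
            molecule_ids=list(self.molecule_ids),
            feature_names=list(names),
            values=self.values[:, cols].copy(),
            kind=self.kind,
            failed_ids=list(self.failed_ids),
        )

    def subset_rows(self, ids: List[str]) -> "FeatureMatrix":
        index = {m: i for i, m in enumerate(self.molecule_ids)}
        missing = [m for m in ids if m not in index]
        if missing:
            raise KeyError(f"molecule ids not in matrix: {missing[:5]}")
        rows = [index[m] for m in ids]
        return FeatureMatrix(
            molecule_ids=list(ids),
            feature_names=list(self.feature_names),
            values=self.values[rows, :].copy(),
            kind=self.kind,
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            molecule_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


@dataclass
class PruningReport:
    """Provenance of feature pruning."""

    dropped_zero_variance: List[str] = field(default_factory=list)
    dropped_correlated: List[Tuple[str, str, float]] = field(default_factory=list)
    dropped_nonfinite: List[str] = field(default_factory=list)


def compute_maccs(mols: MoleculeSet) -> FeatureMatrix:
    """166-bit MACCS keys; feature MACCS<k> is key number k (1-166)."""
    n = len(mols)
    values = np.zeros((n, 166))
    for i, mol in enumerate(mols.mols()):
        fp = fingerprint_mol(mol, "MACCS")  # 167 bits, bit 0 unused
        for b in fp.GetOnBits():
            if b >= 1:
                values[i, b - 1] = 1.0
    names = [f"MACCS{k}" for k in range(1, 167)]
    return FeatureMatrix(mols.ids, names, values, kind="MACCS")


def compute_ecfp4(mols: MoleculeSet, n_bits: int = ECFP4_NBITS) -> FeatureMatrix:
    """Morgan radius-2 circular fingerprint folded to ``n_bits``."""
    n = len(mols)
    values = np.zeros((n, n_bits))
    for i, mol in enumerate(mols.mols()):
        fp = fingerprint_mol(mol, "ECFP4", n_bits)
        for b in fp.GetOnBits():
            values[i, b] = 1.0
    width = len(str(n_bits - 1))
    names = [f"ECFP4_{j:0{width}d}" for j in range(n_bits)]
    return FeatureMatrix(mols.ids, names, values, kind="ECFP4")


def _esol_logs(mol: Chem.Mol) -> float:
    # Delaney ESOL: logS = 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    rb = Descriptors.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    aromatic = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _count_matches(mol: Chem.Mol, patts) -> float:
    return float(sum(len(mol.GetSubstructMatches(p)) for p in patts))


def descriptor_panel_names() -> List[str]:
    """Ordered names of the 2D descriptor panel."""
    base = [name for name, _ in Descriptors._descList if name not in _EXCLUDED_DESCRIPTORS]
    return base + ["ESOL_logS", "AcidicGroupCount", "BasicGroupCount"]


def compute_descriptors_2d(mols: MoleculeSet) -> FeatureMatrix:
    """Fixed panel of 2D physicochemical/topological descriptors.

    A descriptor that fails (or returns a non-finite value) for a molecule
    leaves that cell as NaN and flags the molecule in ``failed_ids``;
    downstream pruning can drop incomplete columns.
    """
    calc = [(name, _OVERRIDE_DESCRIPTORS.get(name, fn))
            for name, fn in Descriptors._descList
            if name not in _EXCLUDED_DESCRIPTORS]
    names = [name for name, _ in calc] + ["ESOL_logS", "AcidicGroupCount", "BasicGroupCount"]
    n = len(mols)
    values = np.full((n, len(names)), np.nan)
    failed: List[str] = []
    for i, (rec, mol) in enumerate(zip(mols, mols.mols())):
        row_failed = False
        for j, (name, fn) in enumerate(calc):
            try:
                v = float(fn(mol))
            except Exception:
                v = float("nan")
            if not math.isfinite(v):
                row_failed = True
                v = float("nan")
            values[i, j] = v
        k = len(calc)
        values[i, k] = _esol_logs(mol)
        values[i, k + 1] = _count_matches(mol, _ACIDIC_PATTS)
        values[i, k + 2] = _count_matches(mol, _BASIC_PATTS)
        if row_failed:
            failed.append(rec.id)
    if failed:
        logger.warning("descriptor failures for %d molecule(s): %s",
                       len(failed), failed[:5])
    return FeatureMatrix(mols.ids, names, values, kind="DESC2D", failed_ids=failed)


def prune_features(
    fm: FeatureMatrix,
    variance_eps: float = 0.0,
    corr_cut: float = 0.95,
    drop_nonfinite: bool = True,
) -> Tuple[FeatureMatrix, PruningReport]:
    """Drop zero-variance then highly correlated features.

    Columns with population variance <= ``variance_eps`` are removed first;
    then a single pass over the upper triangle in name (column) order drops
    the later-ordered member of every surviving pair with |Pearson r| >
    ``corr_cut``.  Columns containing non-finite values are removed up front
    when ``drop_nonfinite`` (they have no defined variance/correlation).
    """
    if fm.n_molecules < 2:
        raise ValueError("pruning requires at least 2 molecules")
    report = PruningReport()
    names = list(fm.feature_names)
    X = fm.values

    keep = []
    for j, name in enumerate(names):
        col = X[:, j]
        if not np.all(np.isfinite(col)):
            if drop_nonfinite:
                report.dropped_nonfinite.append(name)
                continue
            raise ValueError(f"non-finite values in feature {name!r}")
        keep.append(j)

    surv = []
    for j in keep:
        if np.var(X[:, j]) <= variance_eps:
            report.dropped_zero_variance.append(names[j])
        else:
            surv.append(j)

    if surv:
        sub = X[:, surv]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        dropped = np.zeros(len(surv), dtype=bool)
        for a in range(len(surv)):
            if dropped[a]:
                continue
            for b in range(a + 1, len(surv)):
                if dropped[b]:
                    continue
                r = corr[a, b]
                if np.isfinite(r) and abs(r) > corr_cut:
                    dropped[b] = True
                    report.dropped_correlated.append(
                        (names[surv[b]], names[surv[a]], float(r))
                    )
        surv = [j for j, d in zip(surv, dropped) if not d]

    pruned = FeatureMatrix(
        molecule_ids=list(fm.molecule_ids),
        feature_names=[names[j] for j in surv],
        values=X[:, surv].copy(),
        kind=fm.kind,
        failed_ids=list(fm.failed_ids),
    )
    return pruned, report
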