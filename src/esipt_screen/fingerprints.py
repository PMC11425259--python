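"""Shared fingerprint helpers (MACCS keys and Morgan/ECFP4 bit vectors).

Thin wrappers around RDKit used by the curation, featurization, cascade and
strategy modules so that every Tanimoto comparison in the package goes
through one code path.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

ECFP4_NBITS = 2048

_morgan_gens: dict = {}


def _morgan_generator(n_bits: int = ECFP4_NBITS):
    if n_bits not in _morgan_gens:
        _morgan_gens[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=n_bits
        )
    return _morgan_gens[n_bits]


def fingerprint_mol(mol: Chem.Mol, kind: str, n_bits: int = ECFP4_NBITS):
    """Return an RDKit ExplicitBitVect for one molecule.

    kind is "MACCS" (167-bit keyed fingerprint, bit index = key number) or
    "ECFP4" (Morgan radius 2 folded to ``n_bits``).
    """
    if kind == "MACCS":
        return MACCSkeys.GenMACCSKeys(mol)
    if kind == "ECFP4":
        return _morgan_generator(n_bits).GetFingerprint(mol)
    raise ValueError(f"unknown fingerprint kind: {kind!r}")


def fingerprints(mols: Iterable[Chem.Mol], kind: str, n_bits: int = ECFP4_NBITS) -> List:
    return [fingerprint_mol(m, kind, n_bits) for m in mols]


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def bulk_tanimoto(fp, fps: Sequence) -> List[float]:
    if not fps:
        return []
    return DataStructs.BulkTanimotoSimilarity(fp, list(fps))
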