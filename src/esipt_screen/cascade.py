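"""The multi-level virtual-screening pipeline.

A molecule library is passed through a physicochemical prefilter (molecular
weight 50-200 Da, logP 1-5 by default), then through the two classifiers in
sequence — the ESIPT-vs-conventional model (E-CM analogue) and the
ESIPT-vs-fluorophore model (E-FL analogue) — each with an independent
predicted-probability threshold (default 0.9, comparison >=).  Survivors
are annotated with the regressor's predicted proton-transfer energy barrier
and its feasibility call (<= ~15 kcal/mol); by default the barrier annotates
rather than filters, with an optional hard cutoff.  Every input molecule
receives a full trace (stage of rejection, both probabilities where
computed), so screening counts by stage always partition the library.

For the structural-innovation arm the survival rule is re-applied at a
relaxed threshold (default 0.8) and the surviving structures are
deduplicated by internal Tanimoto similarity (one representative per
>0.8-similarity neighbourhood).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from esipt_screen.chemdata import MoleculeRecord, MoleculeSet, internal_dedup_by_similarity
from esipt_screen.featurize import (
    FeatureMatrix,
    compute_descriptors_2d,
    compute_ecfp4,
    compute_maccs,
)
from esipt_screen.metrics import barrier_feasibility
from esipt_screen.mlcore import TrainedModel

logger = logging.getLogger(__name__)


class Stage(str, enum.Enum):
    """Where a molecule left the cascade (NONE = survived)."""

    FEATURIZATION_ERROR = "featurization_error"
    PREFILTER = "prefilter"
    ECM = "ecm"
    EFL = "efl"
    BARRIER = "barrier"
    NONE = "none"


@dataclass
class CascadeConfig:
    mw_range: Tuple[float, float] = (50.0, 200.0)
    logp_range: Tuple[float, float] = (1.0, 5.0)
    p_threshold_ecm: float = 0.9
    p_threshold_efl: float = 0.9
    dedup_similarity: float = 0.8
    barrier_cutoff: float = 15.0
    hard_barrier_filter: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("mw_range", self.mw_range), ("logp_range", self.logp_range)):
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        # thresholds live on the probability scale [0, 1]; values above 1 are
        # tolerated as an explicit reject-all sentinel (no probability can
        # reach them), negatives are errors.
        for name, t in (("p_threshold_ecm", self.p_threshold_ecm),
                        ("p_threshold_efl", self.p_threshold_efl)):
            if t < 0.0:
                raise ValueError(f"{name} must be non-negative, got {t}")


@dataclass
class CascadeResult:
    """Per-molecule trace through the cascade."""

    id: str
    smiles: str
    passed_prefilter: bool = False
    p_ecm: Optional[float] = None
    p_efl: Optional[float] = None
    predicted_barrier: Optional[float] = None
    feasibility: Optional[str] = None
    survived: bool = False
    stage_of_rejection: Stage = Stage.NONE


def prefilter(
    mols: MoleculeSet, config: CascadeConfig = CascadeConfig()
) -> Tuple[MoleculeSet, List[Tuple[str, str]]]:
    """Keep molecules inside the closed MW and computed-logP windows.

    Returns (retained set, rejection log of (id, reason)).  logP is the
    Crippen estimate computed here, which can differ from database-supplied
    values for the same structures.
    """
    kept: List[MoleculeRecord] = []
    rejected: List[Tuple[str, str]] = []
    (mw_lo, mw_hi), (lp_lo, lp_hi) = config.mw_range, config.logp_range
    for r in mols:
        try:
            m = r.mol()
        except ValueError:
            rejected.append((r.id, "unparseable"))
            continue
        mw = Descriptors.MolWt(m)
        logp = Crippen.MolLogP(m)
        if not mw_lo <= mw <= mw_hi:
            rejected.append((r.id, f"MW {mw:.1f} outside [{mw_lo}, {mw_hi}]"))
        elif not lp_lo <= logp <= lp_hi:
            rejected.append((r.id, f"logP {logp:.2f} outside [{lp_lo}, {lp_hi}]"))
        else:
            kept.append(r)
    return MoleculeSet(records=kept, name=mols.name), rejected


def _featurize_for(model: TrainedModel, mols: MoleculeSet,
                   cache: Dict[str, FeatureMatrix]) -> FeatureMatrix:
    kind = model.feature_kind
    if kind not in cache:
        if kind == "ECFP4":
            cache[kind] = compute_ecfp4(mols)
        elif kind == "MACCS":
            cache[kind] = compute_maccs(mols)
        elif kind == "DESC2D":
            cache[kind] = compute_descriptors_2d(mols)
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return cache[kind].subset_features(model.feature_names)


def run_cascade(
    mols: MoleculeSet,
    ecm: TrainedModel,
    efl: TrainedModel,
    ebarrier: Optional[TrainedModel],
    config: CascadeConfig = CascadeConfig(),
) -> List[CascadeResult]:
    """Trace every molecule through prefilter -> E-CM -> E-FL -> barrier.

    A molecule survives iff it passes the prefilter and both classifier
    probabilities meet their thresholds (>=).  Survivors are annotated with
    the predicted barrier and feasibility; with ``hard_barrier_filter`` an
    infeasible barrier also rejects.  Featurization failures yield a
    per-molecule failure record, never a pipeline abort.
    """
    results: Dict[str, CascadeResult] = {
        r.id: CascadeResult(id=r.id, smiles=r.smiles) for r in mols
    }

    parseable: List[MoleculeRecord] = []
    for r in mols:
        if Chem.MolFromSmiles(r.smiles) is None:
            results[r.id].stage_of_rejection = Stage.FEATURIZATION_ERROR
            logger.warning("cascade: cannot featurize %r", r.id)
        else:
            parseable.append(r)

    passed, _ = prefilter(MoleculeSet(records=parseable, name=mols.name), config)
    passed_ids = set(passed.ids)
    for r in parseable:
        if r.id in passed_ids:
            results[r.id].passed_prefilter = True
        else:
            results[r.id].stage_of_rejection = Stage.PREFILTER

    if len(passed) == 0:
        return [results[r.id] for r in mols]

    cache: Dict[str, FeatureMatrix] = {}
    p_ecm = ecm.predict_proba_positive(_featurize_for(ecm, passed, cache))
    p_efl = efl.predict_proba_positive(_featurize_for(efl, passed, cache))
    barrier_pred = (
        ebarrier.predict(_featurize_for(ebarrier, passed, cache))
        if ebarrier is not None else None
    )

    for i, r in enumerate(passed):
        res = results[r.id]
        res.p_ecm = float(p_ecm[i])
        res.p_efl = float(p_efl[i])
        if res.p_ecm < config.p_threshold_ecm:
            res.stage_of_rejection = Stage.ECM
            continue
        if res.p_efl < config.p_threshold_efl:
            res.stage_of_rejection = Stage.EFL
            continue
        if barrier_pred is not None:
            res.predicted_barrier = float(barrier_pred[i])
            res.feasibility = barrier_feasibility(
                res.predicted_barrier, config.barrier_cutoff
            )
            if config.hard_barrier_filter and res.feasibility == "infeasible":
                res.stage_of_rejection = Stage.BARRIER
                continue
        res.survived = True
        res.stage_of_rejection = Stage.NONE

    return [results[r.id] for r in mols]


def survivors(mols: MoleculeSet, results: List[CascadeResult]) -> MoleculeSet:
    by_id = {r.id: r for r in mols}
    kept = [by_id[res.id] for res in results if res.survived]
    return MoleculeSet(records=kept, name=f"{mols.name}_survivors")


def relax_and_diversify(
    mols: MoleculeSet,
    results: List[CascadeResult],
    relaxed_threshold: float = 0.8,
    dedup_similarity: float = 0.8,
    fingerprint: str = "ECFP4",
) -> MoleculeSet:
    """Re-apply survival at a relaxed probability threshold, then dedup.

    Both classifier thresholds are lowered to ``relaxed_threshold`` and the
    surviving structures are reduced to one representative per internal
    Tanimoto-similarity neighbourhood (> ``dedup_similarity``), yielding the
    skeleton-diverse candidate pool for the structural-innovation strategy.
    """
    by_id = {r.id: r for r in mols}
    kept: List[MoleculeRecord] = []
    for res in results:
        if not res.passed_prefilter or res.p_ecm is None or res.p_efl is None:
            continue
        if res.p_ecm >= relaxed_threshold and res.p_efl >= relaxed_threshold:
            kept.append(by_id[res.id])
    relaxed = MoleculeSet(records=kept, name=f"{mols.name}_relaxed")
    return internal_dedup_by_similarity(relaxed, fingerprint, dedup_similarity)


def results_frame(results: List[CascadeResult]) -> pd.DataFrame:
    """One row per molecule with the full cascade trace."""
    return pd.DataFrame([
        {
            "id": r.id,
            "smiles": r.smiles,
            "passed_prefilter": r.passed_prefilter,
            "p_ecm": np.nan if r.p_ecm is None else r.p_ecm,
            "p_efl": np.nan if r.p_efl is None else r.p_efl,
            "predicted_barrier": np.nan if r.predicted_barrier is None else r.predicted_barrier,
            "feasibility": r.feasibility or "",
            "survived": r.survived,
            "stage_of_rejection": r.stage_of_rejection.value,
        }
        for r in results
    ])
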