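"""Candidate-scoring strategies: safety, pharmacokinetics, structural innovation.

Safety and pharmacokinetic scores aggregate categorical ADMET ratings per
property — +1 for "Excellent", +0.5 for "Medium", +0 for "Poor" — over five
properties each (safety: LD50, AMES, skin sensitization, hERG, DILI;
pharmacokinetics: VDss, Fu, CL, T1/2, PPB), giving scores in [0, 5] under
unit weights.  Ratings come from a pluggable provider (CSV import of
precomputed predictions, or the synthetic generator); the rule tables —
property lists, rating points and per-property weights — are plain data and
fully configurable.

The structural-innovation strategy works on structure alone: Murcko
scaffolds, a diversity score defined as one minus the mean pairwise
Tanimoto similarity (ECFP4 by default; a unique-scaffold-fraction variant
is available), and a novelty ranking that combines distance to the known
ESIPT reference set with scaffold rarity within the candidate pool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from esipt_screen.chemdata import MoleculeRecord, MoleculeSet, canonical_dedup
from esipt_screen.fingerprints import bulk_tanimoto, fingerprints

RATING_POINTS = {"Excellent": 1.0, "Medium": 0.5, "Poor": 0.0}

SAFETY_PROPERTIES = ["LD50", "AMES", "SkinSensitization", "hERG", "DILI"]
PK_PROPERTIES = ["VDss", "Fu", "CL", "T1/2", "PPB"]


@dataclass
class StrategyRuleTable:
    """Property -> rating -> points rules for one scoring strategy."""

    strategy: str
    properties: List[str]
    rating_points: Dict[str, float] = field(default_factory=lambda: dict(RATING_POINTS))
    weights: Optional[Dict[str, float]] = None  # default: unit weights

    def __post_init__(self) -> None:
        if self.strategy not in ("safety", "pharmacokinetic", "innovation"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.weights is not None:
            missing = set(self.properties) - set(self.weights)
            if missing:
                raise ValueError(f"weights missing for properties: {sorted(missing)}")

    def weight(self, prop: str) -> float:
        return 1.0 if self.weights is None else self.weights[prop]

    @classmethod
    def safety_default(cls) -> "StrategyRuleTable":
        return cls(strategy="safety", properties=list(SAFETY_PROPERTIES))

    @classmethod
    def pharmacokinetic_default(cls) -> "StrategyRuleTable":
        return cls(strategy="pharmacokinetic", properties=list(PK_PROPERTIES))


@dataclass
class PropertyRatingTable:
    """Categorical property ratings per molecule (Excellent/Medium/Poor).

    Missing ratings are allowed (None / empty) and contribute zero points,
    flagged per candidate.
    """

    ratings: pd.DataFrame  # index: molecule id, columns: property names

    def __post_init__(self) -> None:
        allowed = set(RATING_POINTS) | {None, ""}
        bad = {
            v for v in self.ratings.to_numpy().ravel()
            if not (v in allowed or (isinstance(v, float) and np.isnan(v)))
        }
        if bad:
            raise ValueError(f"ratings outside {sorted(RATING_POINTS)}: {sorted(map(str, bad))[:5]}")

    @property
    def ids(self) -> List[str]:
        return [str(i) for i in self.ratings.index]

    def rating(self, mol_id: str, prop: str) -> Optional[str]:
        if prop not in self.ratings.columns:
            return None
        v = self.ratings.loc[mol_id, prop]
        if v in RATING_POINTS:
            return str(v)
        return None

    def to_csv(self, path) -> None:
        df = self.ratings.copy()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PropertyRatingTable":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        df.index = df.index.astype(str)
        df = df.replace("", None)
        return cls(ratings=df)


@dataclass
class ScoredCandidate:
    id: str
    scores: Dict[str, float] = field(default_factory=dict)
    ranks: Dict[str, int] = field(default_factory=dict)
    missing_properties: List[str] = field(default_factory=list)
    scaffold: Optional[str] = None
    novelty: Optional[float] = None
    scaffold_rarity: Optional[float] = None


def score_strategy(
    ratings: PropertyRatingTable, rules: StrategyRuleTable
) -> List[ScoredCandidate]:
    """Aggregate rating points into one strategy score per molecule.

    score = sum over rule properties of weight x points(rating); missing
    ratings contribute 0 and are flagged.  Candidates are ranked descending
    by score, ties broken by id (rank 1 = best).
    """
    scored: List[ScoredCandidate] = []
    for mol_id in ratings.ids:
        total = 0.0
        missing: List[str] = []
        for prop in rules.properties:
            r = ratings.rating(mol_id, prop)
            if r is None:
                missing.append(prop)
                continue
            total += rules.weight(prop) * rules.rating_points[r]
        scored.append(ScoredCandidate(
            id=mol_id, scores={rules.strategy: total}, missing_properties=missing,
        ))
    scored.sort(key=lambda c: (-c.scores[rules.strategy], c.id))
    for rank, c in enumerate(scored, start=1):
        c.ranks[rules.strategy] = rank
    return scored


def murcko_scaffold(mol: MoleculeRecord) -> tuple[str, bool]:
    """Canonical Murcko scaffold SMILES (ring systems plus linkers).

    Returns (scaffold smiles, is_empty): acyclic molecules have no ring
    framework and map to the empty scaffold with the flag set.
    """
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol.mol())
    return scaffold, scaffold == ""


def diversity_score(
    mols: MoleculeSet, fingerprint: str = "ECFP4", method: str = "mean_tanimoto"
) -> float:
    """Structural diversity of a molecule set, in [0, 1].

    Duplicate canonical structures are collapsed before scoring: diversity
    is a property of the distinct structures in a pool, so inserting
    redundant copies can neither raise nor lower it (a plain pair-mean over
    raw records would reward duplicating a structural outlier).

    ``mean_tanimoto`` (default): 1 - mean pairwise Tanimoto similarity over
    all unordered pairs of distinct structures.  ``scaffold_ratio``:
    fraction of distinct Murcko scaffolds among the distinct structures.
    A set that collapses to a single structure scores 0.
    """
    if len(mols) < 2:
        raise ValueError("diversity_score needs at least 2 molecules")
    distinct = canonical_dedup(mols)
    if len(distinct) < 2:
        return 0.0
    if method == "scaffold_ratio":
        scaffolds = {murcko_scaffold(r)[0] for r in distinct}
        return len(scaffolds) / len(distinct)
    if method != "mean_tanimoto":
        raise ValueError(f"unknown method {method!r}")
    fps = fingerprints(distinct.mols(), fingerprint)
    total, n_pairs = 0.0, 0
    for i in range(1, len(fps)):
        sims = bulk_tanimoto(fps[i], fps[:i])
        total += sum(sims)
        n_pairs += len(sims)
    return 1.0 - total / n_pairs


def innovation_rank(
    mols: MoleculeSet,
    reference: MoleculeSet,
    fingerprint: str = "ECFP4",
    novelty_weight: float = 0.5,
    rarity_weight: float = 0.5,
) -> List[ScoredCandidate]:
    """Rank candidates by structural novelty against a known-ESIPT reference.

    novelty = 1 - max Tanimoto similarity to any reference molecule;
    scaffold rarity = 1 / (frequency of the candidate's Murcko scaffold
    within the candidate pool).  The innovation score is the weighted sum,
    ranked descending with ties broken by id.
    """
    ref_fps = fingerprints(reference.mols(), fingerprint)
    cand_fps = fingerprints(mols.mols(), fingerprint)
    scaffolds = [murcko_scaffold(r)[0] for r in mols]
    freq: Dict[str, int] = {}
    for s in scaffolds:
        freq[s] = freq.get(s, 0) + 1

    scored: List[ScoredCandidate] = []
    for r, fp, scaf in zip(mols, cand_fps, scaffolds):
        novelty = 1.0 - (max(bulk_tanimoto(fp, ref_fps)) if ref_fps else 0.0)
        rarity = 1.0 / freq[scaf]
        score = novelty_weight * novelty + rarity_weight * rarity
        scored.append(ScoredCandidate(
            id=r.id, scores={"innovation": score}, scaffold=scaf,
            novelty=novelty, scaffold_rarity=rarity,
        ))
    scored.sort(key=lambda c: (-c.scores["innovation"], c.id))
    for rank, c in enumerate(scored, start=1):
        c.ranks["innovation"] = rank
    return scored


def write_scored_csv(
    candidates: Sequence[ScoredCandidate], path, smiles_by_id: Optional[Dict[str, str]] = None
) -> None:
    strategies = sorted({s for c in candidates for s in c.scores})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["id", "smiles"] + [f"{s}_score" for s in strategies] + \
                 [f"{s}_rank" for s in strategies] + ["scaffold"]
        w.writerow(header)
        for c in candidates:
            w.writerow(
                [c.id, (smiles_by_id or {}).get(c.id, "")]
                + [c.scores.get(s, "") for s in strategies]
                + [c.ranks.get(s, "") for s in strategies]
                + [c.scaffold or ""]
            )
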