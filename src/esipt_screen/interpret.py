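"""Shapley-value interpretation of the screening models.

Global importance (mean |Shapley| over an evaluation set), per-molecule
force-style breakdowns, top-k rankings and their overlap between the two
classifiers, and mapping of MACCS fingerprint bits back to their SMARTS
substructure definitions so that attribution results read as structural
rules (e.g. the hydroxy key promoting the ESIPT class marks the proton
donor).

Tree ensembles get exact interventional Shapley values (closed-form per-leaf
coalition weights, see :mod:`esipt_screen._shapley`); other estimators fall
back to a seeded permutation-sampling estimate.  In both cases additivity
holds: base value + sum of attributions = model output per sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.MACCSkeys import smartsPatts
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from esipt_screen._shapley import permutation_shapley_values, tree_shapley_values
from esipt_screen.featurize import FeatureMatrix
from esipt_screen.mlcore import TrainedModel

_TREE_TYPES = (
    RandomForestClassifier, RandomForestRegressor,
    DecisionTreeClassifier, DecisionTreeRegressor,
)

MAX_BACKGROUND = 200


@dataclass
class AttributionReport:
    """Per-sample Shapley values plus derived global importance."""

    molecule_ids: List[str]
    feature_names: List[str]
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    predictions: np.ndarray

    @property
    def global_importance(self) -> Dict[str, float]:
        return dict(zip(self.feature_names, np.abs(self.values).mean(axis=0)))

    def mean_signed(self) -> Dict[str, float]:
        return dict(zip(self.feature_names, self.values.mean(axis=0)))


@dataclass
class SubstructureRule:
    """A fingerprint feature read as a structural rule."""

    feature: str
    smarts: Optional[str]
    direction: Optional[str] = None  # promotes / suppresses
    evidence: Optional[float] = None  # mean signed Shapley
    composite: bool = False  # count-based or undefined MACCS key

    def pattern(self) -> Optional[Chem.Mol]:
        return Chem.MolFromSmarts(self.smarts) if self.smarts else None


def _check_manifest(model: TrainedModel, fm: FeatureMatrix) -> None:
    if list(fm.feature_names) != list(model.feature_names):
        raise ValueError("feature manifest mismatch between matrix and model")


def shapley_attribution(
    model: TrainedModel,
    X: FeatureMatrix,
    background: FeatureMatrix,
    seed: int = 0,
    n_permutations: int = 64,
) -> AttributionReport:
    """Shapley attribution of model outputs relative to a background set.

    The background (capped at 200 rows, deterministic subsample) defines the
    reference distribution; classifier outputs are positive-class
    probabilities.  Exact for tree models, sampling-based otherwise.
    """
    _check_manifest(model, X)
    _check_manifest(model, background)
    Z = background.values
    if Z.shape[0] > MAX_BACKGROUND:
        rng = np.random.default_rng(seed)
        Z = Z[rng.choice(Z.shape[0], MAX_BACKGROUND, replace=False)]

    predictions = model.decision_value(X.values)
    est = model.estimator
    if isinstance(est, _TREE_TYPES):
        pos_index = None
        if model.config.task == "classify":
            classes = [str(c) for c in est.classes_]
            pos_index = classes.index(str(model.positive_label))
        phi = tree_shapley_values(est, X.values, Z, positive_index=pos_index)
        base = float(np.mean(model.decision_value(Z)))
    else:
        phi, base = permutation_shapley_values(
            model.decision_value, X.values, Z,
            seed=seed, n_permutations=n_permutations,
        )
    return AttributionReport(
        molecule_ids=list(X.molecule_ids),
        feature_names=list(X.feature_names),
        values=phi,
        base_value=base,
        predictions=predictions,
    )


def top_features(report: AttributionReport, k: int = 20) -> List[str]:
    """Top-k features by mean |Shapley|, ties broken lexicographically."""
    if k > len(report.feature_names):
        raise ValueError(f"k={k} exceeds {len(report.feature_names)} features")
    imp = report.global_importance
    ranked = sorted(imp.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


def overlap_features(
    report_a: AttributionReport, report_b: AttributionReport, k: int = 20
) -> Tuple[List[str], Dict[str, int]]:
    """Intersection of two top-k lists with Venn-style counts."""
    if report_a.feature_names != report_b.feature_names:
        raise ValueError("reports use different feature spaces")
    top_a: Set[str] = set(top_features(report_a, k))
    top_b: Set[str] = set(top_features(report_b, k))
    shared = sorted(top_a & top_b)
    counts = {
        "a_only": len(top_a - top_b),
        "shared": len(shared),
        "b_only": len(top_b - top_a),
    }
    return shared, counts


def force_breakdown(
    model: TrainedModel,
    x: FeatureMatrix,
    background: FeatureMatrix,
    seed: int = 0,
) -> List[Tuple[str, float, float]]:
    """Single-molecule force-style breakdown.

    Returns (feature, feature value, signed contribution) sorted by
    |contribution| descending; the contributions sum to prediction - base.
    For fingerprints the feature value is the 0/1 bit, so a positive
    contribution on a present bit reads "this fragment promotes the
    prediction".
    """
    if x.n_molecules != 1:
        raise ValueError("force_breakdown expects a single-sample matrix")
    report = shapley_attribution(model, x, background, seed=seed)
    rows = [
        (name, float(x.values[0, j]), float(report.values[0, j]))
        for j, name in enumerate(report.feature_names)
    ]
    rows.sort(key=lambda r: (-abs(r[2]), r[0]))
    return rows


def bit_to_substructure(feature) -> SubstructureRule:
    """SMARTS definition of a MACCS key, for rule reporting/highlighting.

    Accepts "MACCS139" or the integer key 139 (valid range 1-166).  Keys
    defined only as counts ("more than n occurrences") or left undefined in
    the published key set are flagged composite; undefined keys carry no
    SMARTS.
    """
    if isinstance(feature, str):
        if not feature.startswith("MACCS"):
            raise ValueError(f"not a MACCS feature name: {feature!r}")
        key = int(feature[5:])
    else:
        key = int(feature)
    if not 1 <= key <= 166:
        raise ValueError(f"MACCS key index must be in 1..166, got {key}")
    smarts, count = smartsPatts[key]
    if smarts == "?":
        return SubstructureRule(feature=f"MACCS{key}", smarts=None, composite=True)
    return SubstructureRule(
        feature=f"MACCS{key}", smarts=smarts, composite=count > 0
    )


def substructure_rules(
    report: AttributionReport, k: int = 20
) -> List[SubstructureRule]:
    """Top-k MACCS features as substructure rules with attribution evidence."""
    signed = report.mean_signed()
    rules = []
    for name in top_features(report, k):
        if not name.startswith("MACCS"):
            continue
        rule = bit_to_substructure(name)
        ev = signed[name]
        rules.append(SubstructureRule(
            feature=rule.feature,
            smarts=rule.smarts,
            direction="promotes" if ev > 0 else "suppresses",
            evidence=float(ev),
            composite=rule.composite,
        ))
    return rules


def write_rules_csv(rules: Sequence[SubstructureRule], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature", "smarts", "direction", "evidence", "composite"])
        for r in rules:
            w.writerow([r.feature, r.smarts or "", r.direction or "",
                        "" if r.evidence is None else repr(r.evidence), int(r.composite)])


def match_atoms(smiles: str, rule: SubstructureRule) -> List[Tuple[int, ...]]:
    """Matched-atom index tuples of a rule's SMARTS in one molecule."""
    patt = rule.pattern()
    if patt is None:
        return []
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return [tuple(m) for m in mol.GetSubstructMatches(patt)]
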