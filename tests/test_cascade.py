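"""Prefilter windows, cascade traces, threshold behavior, relaxation + dedup."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from esipt_screen import synthetic as syn
from esipt_screen.cascade import (
    CascadeConfig,
    Stage,
    prefilter,
    relax_and_diversify,
    run_cascade,
    survivors,
)
from esipt_screen.chemdata import MoleculeRecord, MoleculeSet
from esipt_screen.featurize import compute_maccs
from esipt_screen.mlcore import ModelConfig, fit, make_split
from esipt_screen.synthetic import SyntheticSpec


def _set(smiles_list, prefix="m"):
    return MoleculeSet(
        records=[MoleculeRecord(id=f"{prefix}{i}", smiles=s) for i, s in enumerate(smiles_list)]
    )


def _train_pair(seed, n=120, trees=100):
    """Small E-CM / E-FL analogues on MACCS keys."""
    spec = SyntheticSpec(n_per_class=n, seed=seed)
    pos = syn.gen_esipt_positives(spec)
    conv = syn.gen_conventional_negatives(spec)
    fl = syn.gen_fluor_negatives(spec)
    models = []
    for neg in (conv, fl):
        combined = MoleculeSet(records=list(pos) + list(neg), name="t")
        X = compute_maccs(combined)
        y = [r.label.value for r in combined]
        plan = make_split(combined.ids, y, seed=seed)
        cfg = ModelConfig("RF", "classify", {"n_estimators": trees}, seed=seed)
        model, _ = fit(cfg, X, y, plan, positive_label="ESIPT")
        models.append(model)
    return models[0], models[1]


@pytest.fixture(scope="module")
def trained_models():
    return _train_pair(seed=11)


@pytest.fixture(scope="module")
def library():
    spec = SyntheticSpec(n_per_class=60, seed=99)
    pos = syn.gen_esipt_positives(spec)
    conv = syn.gen_conventional_negatives(spec)
    fl = syn.gen_fluor_negatives(spec)
    records = []
    for i, r in enumerate(list(pos) + list(conv) + list(fl)):
        records.append(MoleculeRecord(id=f"lib{i}", smiles=r.smiles, label=r.label))
    return MoleculeSet(records=records, name="library")


class TestPrefilter:
    def test_benzene_inside_both_windows(self):
        out, rejected = prefilter(_set(["c1ccccc1"]))
        assert len(out) == 1 and not rejected

    def test_glucose_rejected_on_logp(self):
        out, rejected = prefilter(_set(["OCC1OC(O)C(O)C(O)C1O"]))
        assert len(out) == 0
        assert "logP" in rejected[0][1]

    def test_boundary_mw_retained_closed_interval(self):
        mw = Descriptors.MolWt(Chem.MolFromSmiles("c1ccccc1"))
        config = CascadeConfig(mw_range=(mw, mw))  # exact boundary on both ends
        out, _ = prefilter(_set(["c1ccccc1"]), config)
        assert len(out) == 1

    def test_oversized_molecule_rejected_on_mw(self):
        out, rejected = prefilter(_set(["c1ccc2cc3cc4ccccc4cc3cc2c1CCCCCCCCCC"]))
        assert len(out) == 0 and "MW" in rejected[0][1]


class TestRunCascade:
    def test_zero_thresholds_survivors_equal_prefilter_output(self, trained_models, library):
        ecm, efl = trained_models
        config = CascadeConfig(p_threshold_ecm=0.0, p_threshold_efl=0.0)
        results = run_cascade(library, ecm, efl, None, config)
        surv = {r.id for r in results if r.survived}
        passed, _ = prefilter(library, config)
        assert surv == set(passed.ids)

    def test_impossible_threshold_zero_survivors(self, trained_models, library):
        ecm, efl = trained_models
        config = CascadeConfig(p_threshold_ecm=1.01, p_threshold_efl=1.01)
        results = run_cascade(library, ecm, efl, None, config)
        assert not any(r.survived for r in results)

    def test_trace_partitions_input(self, trained_models, library):
        ecm, efl = trained_models
        broken = MoleculeSet(
            records=list(library.records) + [MoleculeRecord(id="bad", smiles="CCO")],
        )
        # sneak in an unparseable record (bypassing SMILES validation at read time)
        object.__setattr__(broken.records[-1], "smiles", "not_a_smiles")
        results = run_cascade(broken, ecm, efl, None, CascadeConfig())
        assert len(results) == len(broken)
        assert [r.id for r in results] == broken.ids
        by_stage = {}
        for r in results:
            by_stage[r.stage_of_rejection] = by_stage.get(r.stage_of_rejection, 0) + 1
        assert sum(by_stage.values()) == len(broken)
        assert by_stage.get(Stage.FEATURIZATION_ERROR) == 1
        n_survivors = sum(r.survived for r in results)
        assert by_stage.get(Stage.NONE, 0) == n_survivors

    def test_survivor_count_monotone_in_thresholds(self, trained_models, library):
        ecm, efl = trained_models
        counts = []
        for t in (0.0, 0.5, 0.8, 0.9, 0.95, 1.0):
            config = CascadeConfig(p_threshold_ecm=t, p_threshold_efl=t)
            results = run_cascade(library, ecm, efl, None, config)
            counts.append(sum(r.survived for r in results))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_survivor_precision_against_planted_truth(self, library):
        """Models trained on disjoint synthetic data recover planted positives."""
        hits = []
        for seed in range(5):
            ecm, efl = _train_pair(seed=seed, n=100, trees=60)
            # window wide enough to admit the synthetic scaffolds (HBT ~227 Da)
            config = CascadeConfig(p_threshold_ecm=0.9, p_threshold_efl=0.9,
                                   mw_range=(50, 600), logp_range=(-5, 10))
            results = run_cascade(library, ecm, efl, None, config)
            truth = {r.id: r.label.value for r in library}
            surv = [r.id for r in results if r.survived]
            if surv:
                precision = sum(truth[m] == "ESIPT" for m in surv) / len(surv)
                hits.append(precision)
        assert hits and min(hits) >= 0.8

    def test_barrier_annotation_and_hard_filter(self, trained_models, library):
        from esipt_screen.featurize import compute_descriptors_2d, prune_features

        ecm, efl = trained_models
        spec = SyntheticSpec(n_per_class=100, seed=21)
        pos = syn.gen_esipt_positives(spec)
        bar, _ = syn.gen_barriers(pos, spec)
        X, _ = prune_features(compute_descriptors_2d(bar))
        y = [r.barrier for r in bar]
        plan = make_split(X.molecule_ids, None, seed=21)
        ebarrier, _ = fit(
            ModelConfig("RF", "regress", {"n_estimators": 60}, seed=21), X, y, plan
        )
        wide = dict(mw_range=(50, 600), logp_range=(-5, 10))
        config = CascadeConfig(p_threshold_ecm=0.7, p_threshold_efl=0.7, **wide)
        results = run_cascade(library, ecm, efl, ebarrier, config)
        surv = [r for r in results if r.survived]
        assert surv
        for r in surv:
            assert r.predicted_barrier is not None and r.predicted_barrier > 0
            assert r.feasibility in ("feasible", "infeasible")
        hard = CascadeConfig(p_threshold_ecm=0.7, p_threshold_efl=0.7,
                             hard_barrier_filter=True, barrier_cutoff=15.0, **wide)
        results_hard = run_cascade(library, ecm, efl, ebarrier, hard)
        surv_hard = {r.id for r in results_hard if r.survived}
        assert surv_hard <= {r.id for r in surv}


class TestRelaxAndDiversify:
    def test_relaxed_equal_strict_matches_survivors_before_dedup(self, trained_models, library):
        ecm, efl = trained_models
        config = CascadeConfig(p_threshold_ecm=0.9, p_threshold_efl=0.9,
                               mw_range=(50, 600), logp_range=(-5, 10))
        results = run_cascade(library, ecm, efl, None, config)
        strict = set(survivors(library, results).ids)
        relaxed = relax_and_diversify(library, results, relaxed_threshold=0.9,
                                      dedup_similarity=1.0)  # dedup disabled
        assert set(relaxed.ids) == strict

    def test_all_identical_survivors_collapse_to_one(self, trained_models):
        ecm, efl = trained_models
        smiles = "Oc1ccccc1-c1nc2ccccc2s1"
        lib = _set([smiles] * 5)
        results = run_cascade(lib, ecm, efl, None,
                              CascadeConfig(p_threshold_ecm=0.0, p_threshold_efl=0.0,
                                            mw_range=(50, 600), logp_range=(-5, 10)))
        out = relax_and_diversify(lib, results, relaxed_threshold=0.0)
        assert len(out) == 1

    def test_known_clusters_one_representative_each(self, trained_models):
        ecm, efl = trained_models
        centers = ["Oc1ccccc1-c1nc2ccccc2s1", "Oc1ccccc1-c1nc2ccccc2o1",
                   "O=c1ccc2ccccc2o1", "c1ccc2cc3ccccc3cc2c1",
                   "CC(C)Cc1ccccc1", "CN1CCCCC1"]
        records = [
            MoleculeRecord(id=f"c{i}_{k}", smiles=s)
            for i, s in enumerate(centers) for k in range(4)
        ]
        lib = MoleculeSet(records=records)
        results = run_cascade(lib, ecm, efl, None,
                              CascadeConfig(p_threshold_ecm=0.0, p_threshold_efl=0.0,
                                            mw_range=(0, 1000), logp_range=(-10, 10)))
        out = relax_and_diversify(lib, results, relaxed_threshold=0.0, dedup_similarity=0.8)
        assert len(out) == 6
        assert {i.split("_")[0] for i in out.ids} == {f"c{i}" for i in range(6)}
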