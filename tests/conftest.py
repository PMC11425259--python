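import numpy as np
import pytest

from esipt_screen import synthetic as syn
from esipt_screen.chemdata import MoleculeSet
from esipt_screen.featurize import compute_maccs
from esipt_screen.mlcore import ModelConfig, fit, make_split
from esipt_screen.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(n_per_class=80, seed=7)


@pytest.fixture(scope="session")
def positives(small_spec) -> MoleculeSet:
    return syn.gen_esipt_positives(small_spec)


@pytest.fixture(scope="session")
def conventional(small_spec) -> MoleculeSet:
    return syn.gen_conventional_negatives(small_spec)


@pytest.fixture(scope="session")
def fluor(small_spec) -> MoleculeSet:
    return syn.gen_fluor_negatives(small_spec)


@pytest.fixture(scope="session")
def maccs_model(positives, conventional):
    """A small MACCS random forest separating ESIPT from conventional molecules."""
    combined = MoleculeSet(records=list(positives) + list(conventional), name="cm")
    X = compute_maccs(combined)
    y = [r.label.value for r in combined]
    plan = make_split(combined.ids, y, seed=7)
    config = ModelConfig(
        algorithm="RF", task="classify", seed=7,
        hyperparameters={"n_estimators": 100},
    )
    model, report = fit(config, X, y, plan, positive_label="ESIPT")
    return model, report, X, plan


def tanimoto_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Independent Tanimoto on 0/1 vectors, used by test oracles."""
    inter = float(np.sum((a > 0) & (b > 0)))
    union = float(np.sum((a > 0) | (b > 0)))
    return inter / union if union else 0.0
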