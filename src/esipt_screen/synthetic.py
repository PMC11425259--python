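"""Synthetic molecule sets with known ground truth for every pipeline stage.

ESIPT activity hinges on an intramolecular hydrogen bond between a proton
donor (-OH, -NH2) and a nearby acceptor (=N-, C=O) that enables the
excited-state enol -> keto transfer.  The generator plants exactly that
motif: positives are classic ESIPT scaffolds — HBT, HBO, HBI
(2-(2'-hydroxyphenyl)-benzothiazole/-oxazole/-imidazole) and
salicylaldehyde azine — randomly decorated with small substituents, all of
which match the motif SMARTS ``[OX2H]c1ccccc1[#6]~[#7]`` (ortho-phenolic OH
next to a carbon bearing a nitrogen acceptor).  Negatives never match it:
"conventional" negatives are simple acyclic/monocyclic drug-like molecules,
and "fluorophore" negatives are conjugated dye scaffolds (coumarins,
naphthalimide, stilbene, acridine...) lacking the ortho-hydroxy donor —
deliberately closer to the positives than the conventional set, mimicking
the harder second classification stage.

In MACCS-key space the planted motif pins two declared bits: key 139
([O;!H0], the hydroxy donor) and key 97 ([#7]~*~*~*~[#8], nitrogen four
bonds from oxygen — the donor-acceptor spacing).  Attribution tests can
therefore check that these planted bits are recovered as important.

Energy-barrier targets are a smooth monotone function of a few named 2D
descriptors (softplus of a weighted standardized sum plus Gaussian noise,
rescaled into (0.3, 20] kcal/mol): statistical machinery is being tested,
not chemistry.  The true weights are returned for recovery experiments.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from esipt_screen.chemdata import Label, MoleculeRecord, MoleculeSet, write_molecules
from esipt_screen.strategies import PK_PROPERTIES, SAFETY_PROPERTIES, PropertyRatingTable

import pandas as pd

MOTIF_SMARTS = "[OX2H]c1ccccc1[#6]~[#7]"
_MOTIF = Chem.MolFromSmarts(MOTIF_SMARTS)

# MACCS keys pinned by the planted motif (donor OH; N at 4 bonds from O)
PLANTED_DONOR_BIT = "MACCS139"
PLANTED_ACCEPTOR_BIT = "MACCS97"

POSITIVE_SCAFFOLDS = [
    "Oc1ccccc1-c1nc2ccccc2s1",        # HBT
    "Oc1ccccc1-c1nc2ccccc2o1",        # HBO
    "Oc1ccccc1-c1nc2ccccc2[nH]1",     # HBI
    "Oc1ccccc1/C=N/N=C/c1ccccc1O",    # salicylaldehyde azine
]

CONVENTIONAL_TEMPLATES = [
    "CC(C)Cc1ccccc1",
    "COc1ccccc1",
    "CN1CCCCC1",
    "CCN(CC)CC",
    "CC(C)C(=O)OCC",
    "Cc1ccc(C)cc1",
    "CCCCC(C)=O",
    "CC(C)(C)c1ccccc1",
    "CS(=O)(=O)c1ccccc1",
    "CCOC(=O)C1CCCC1",
    "CC(=O)N(C)C",
    "CCOCC1CCCO1",
]

FLUOR_TEMPLATES = [
    "O=c1ccc2ccccc2o1",               # coumarin
    "COc1ccc2ccc(=O)oc2c1",           # 7-methoxycoumarin
    "CN1C(=O)c2cccc3cccc(c23)C1=O",   # N-methyl-1,8-naphthalimide
    "C(=C/c1ccccc1)\\c1ccccc1",       # stilbene
    "c1ccc2cc3ccccc3cc2c1",           # anthracene
    "c1ccc2nc3ccccc3cc2c1",           # acridine
]

DECORATIONS = ["F", "Cl", "Br", "C", "OC", "N(C)C", "C#N", "[N+](=O)[O-]"]

DEFAULT_BARRIER_WEIGHTS = {
    "MolLogP": 1.0,
    "TPSA": -0.8,
    "NumRotatableBonds": 0.5,
    "NumHDonors": 0.7,
    "RingCount": -0.6,
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark."""

    n_per_class: int = 500
    seed: int = 0
    positive_scaffolds: List[str] = field(default_factory=lambda: list(POSITIVE_SCAFFOLDS))
    decorations: List[str] = field(default_factory=lambda: list(DECORATIONS))
    barrier_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BARRIER_WEIGHTS))
    noise_sd: float = 0.3  # fraction of the signal SD
    max_decorations: int = 3

    def __post_init__(self) -> None:
        for s in self.positive_scaffolds:
            if Chem.MolFromSmiles(s) is None:
                raise ValueError(f"unparseable scaffold template {s!r}")


def has_motif(smiles: str) -> bool:
    """True iff the molecule carries the planted ESIPT donor-acceptor motif."""
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and mol.HasSubstructMatch(_MOTIF)


def _decoration_sites(mol: Chem.Mol) -> List[int]:
    return [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _attach(mol: Chem.Mol, substituent: str, rng: np.random.Generator) -> Optional[Chem.Mol]:
    """Bond a substituent fragment (by its first atom) to a random C-H site."""
    sites = _decoration_sites(mol)
    if not sites:
        return None
    frag = Chem.MolFromSmiles(substituent)
    if frag is None:
        return None
    site = int(sites[rng.integers(len(sites))])
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _decorated(template: str, spec: SyntheticSpec, rng: np.random.Generator) -> str:
    mol = Chem.MolFromSmiles(template)
    k = int(rng.integers(0, spec.max_decorations + 1))
    for _ in range(k):
        sub = spec.decorations[int(rng.integers(len(spec.decorations)))]
        for _attempt in range(5):  # invalid valence -> resample, bounded
            new = _attach(mol, sub, rng)
            if new is not None:
                mol = new
                break
    return Chem.MolToSmiles(mol)


def _generate_class(
    templates: Sequence[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    want_motif: bool,
    label: Label,
    prefix: str,
    name: str,
) -> MoleculeSet:
    records: List[MoleculeRecord] = []
    for i in range(spec.n_per_class):
        template = templates[int(rng.integers(len(templates)))]
        smiles = template
        for _attempt in range(20):
            candidate = _decorated(template, spec, rng)
            if has_motif(candidate) == want_motif:
                smiles = candidate
                break
        else:
            # bare template is guaranteed to satisfy the motif requirement
            if has_motif(template) != want_motif:
                raise RuntimeError(f"template {template!r} violates motif requirement")
        records.append(MoleculeRecord(
            id=f"{prefix}{i + 1}", smiles=smiles, label=label, source="synthetic",
        ))
    return MoleculeSet(records=records, name=name)


def gen_esipt_positives(spec: SyntheticSpec) -> MoleculeSet:
    """ESIPT-positive molecules: decorated classic scaffolds, all motif-bearing."""
    rng = np.random.default_rng(spec.seed)
    return _generate_class(
        spec.positive_scaffolds, spec, rng, want_motif=True,
        label=Label.ESIPT, prefix="pos", name="esipt_positives",
    )


def gen_conventional_negatives(spec: SyntheticSpec) -> MoleculeSet:
    """Conventional (non-fluorescent) negatives; none carry the motif."""
    rng = np.random.default_rng(spec.seed + 1)
    return _generate_class(
        CONVENTIONAL_TEMPLATES, spec, rng, want_motif=False,
        label=Label.CONVENTIONAL, prefix="conv", name="conventional_negatives",
    )


def gen_fluor_negatives(spec: SyntheticSpec) -> MoleculeSet:
    """Fluorescent non-ESIPT negatives: conjugated dye scaffolds, no o-hydroxy donor."""
    rng = np.random.default_rng(spec.seed + 2)
    return _generate_class(
        FLUOR_TEMPLATES, spec, rng, want_motif=False,
        label=Label.FLUOR_NON_ESIPT, prefix="fl", name="fluor_negatives",
    )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def gen_barriers(
    mols: MoleculeSet, spec: SyntheticSpec
) -> Tuple[MoleculeSet, Dict[str, float]]:
    """Attach synthetic energy barriers (kcal/mol) driven by named descriptors.

    barrier_i = rescale(softplus(sum_f w_f x~_if + eps_i)) where x~ are
    z-scored descriptor values, eps ~ N(0, noise_sd * sd(signal)), and the
    rescaling maps the set's softplus values into (0.3, 20].  With
    noise_sd = 0 the barrier is a deterministic function of the features.
    Returns the new set and the true weights for recovery experiments.
    """
    rng = np.random.default_rng(spec.seed + 3)
    names = list(spec.barrier_weights)
    fns = []
    for name in names:
        fn = getattr(Descriptors, name, None)
        if fn is None:
            raise ValueError(f"barrier weight {name!r} is not an RDKit 2D descriptor")
        fns.append(fn)
    X = np.array([[fn(m) for fn in fns] for m in mols.mols()], dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    w = np.array([spec.barrier_weights[n] for n in names], dtype=float)
    signal = Xz @ w
    sig_sd = float(signal.std()) or 1.0
    eps = rng.normal(0.0, spec.noise_sd * sig_sd, size=len(signal))
    s = _softplus(signal + eps)
    barriers = 0.3 + (20.0 - 0.3) * s / s.max()

    records = [
        MoleculeRecord(id=r.id, smiles=r.smiles, label=r.label,
                       barrier=float(b), source=r.source)
        for r, b in zip(mols, barriers)
    ]
    return MoleculeSet(records=records, name=mols.name), dict(spec.barrier_weights)


def gen_rating_table(
    ids: Sequence[str],
    seed: int = 0,
    distribution: Sequence[float] = (0.5, 0.3, 0.2),
    properties: Optional[Sequence[str]] = None,
) -> PropertyRatingTable:
    """Random ADMET-style rating table (Excellent/Medium/Poor per property).

    ``distribution`` gives the (Excellent, Medium, Poor) probabilities and
    must sum to 1; ratings are independent per molecule and property.
    """
    p = np.asarray(distribution, dtype=float)
    if p.shape != (3,) or not np.isclose(p.sum(), 1.0):
        raise ValueError("distribution must be 3 probabilities summing to 1")
    props = list(properties) if properties is not None else SAFETY_PROPERTIES + PK_PROPERTIES
    rng = np.random.default_rng(seed)
    data = rng.choice(["Excellent", "Medium", "Poor"], size=(len(ids), len(props)), p=p)
    df = pd.DataFrame(data, index=[str(i) for i in ids], columns=props)
    return PropertyRatingTable(ratings=df)


PRESETS = {"small": 200, "medium": 500}


def write_preset(out_dir, preset: str = "small", seed: int = 0) -> Dict[str, Path]:
    """Write positives/conventional/fluor/barriers/ratings CSVs for a preset."""
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(n_per_class=PRESETS[preset], seed=seed)
    pos = gen_esipt_positives(spec)
    conv = gen_conventional_negatives(spec)
    fluor = gen_fluor_negatives(spec)
    with_barriers, _ = gen_barriers(pos, spec)
    ratings = gen_rating_table(pos.ids, seed=seed)
    paths = {
        "positives": out / "positives.csv",
        "conventional": out / "conventional.csv",
        "fluor": out / "fluor.csv",
        "barriers": out / "barriers.csv",
        "ratings": out / "ratings.csv",
    }
    write_molecules(pos, paths["positives"])
    write_molecules(conv, paths["conventional"])
    write_molecules(fluor, paths["fluor"])
    write_molecules(with_barriers, paths["barriers"])
    ratings.to_csv(paths["ratings"])
    return paths
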