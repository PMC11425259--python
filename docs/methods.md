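# Methods

## Screening model

The screening system treats ESIPT discovery as a three-stage supervised
problem over SMILES libraries.

**Representations.** Three featurizations are used: MACCS keys (166 keyed
substructure bits; feature `MACCS<k>` is published key number *k*, so each
bit maps back to a SMARTS fragment), ECFP4 (Morgan radius-2 circular
fingerprint folded to 2048 bits), and a 2D descriptor panel (RDKit's full
2D descriptor list, ~210 descriptors, minus `Ipc`, which overflows for
mid-sized molecules, plus an ESOL-style logS estimate and rule-based
acidic/basic group counts as pKa/protonation proxies). The H-bond-donor
descriptor counts donor *groups* (every N/O bearing ≥ 1 H; water = 1)
rather than the Lipinski H1-only SMARTS. Descriptor matrices are pruned
before modelling: non-finite columns, then zero-variance columns, then for
each pair with |Pearson r| > 0.95 the later-ordered column (one pass over
the upper triangle in column order, deterministic).

**Models and validation.** Estimators: k-NN, decision tree, random forest
(500 trees), RBF-SVM with cross-validated probability calibration (the
cascade thresholds act on probabilities), gradient-boosted trees (XGBoost,
300 rounds, depth 6) and an optional MLP. Defaults favour reproducibility
over tuning; every fit is deterministic under its seed. Validation uses a
stratified 75/25 train/test split with 5-fold CV on the training partition.
Classification metrics come from the thresholded confusion table plus the
rank-based (Mann–Whitney) AUC with ties counted ½ — equivalent to the
trapezoidal ROC area and invariant under monotone score transforms.
Regression metrics are R² (1 − SS_res/SS_tot), MAE, RMSE, Pearson r, and
fold rates with *strict* inequality (foldᵢ = 1 + |ŷᵢ − yᵢ|/yᵢ < k);
targets must be strictly positive for folds to be defined.

**Feature selection and outlier exclusion.** RFE is a single elimination
order computed by repeatedly refitting the base estimator and dropping the
lowest-importance feature(s); because one order underlies every target
size, the selected set at *m* features is always a superset of the set at
*m − step*. Ties in importance drop the earlier-ordered feature (stable
sort). Sample curation for the regressor uses ECOD: per-dimension empirical
CDF tail probabilities (left = P(Xⱼ ≤ x), right = P(Xⱼ ≥ x), estimated on
the column itself), −log tail scores aggregated per sample as three sums —
left-only, right-only, and skewness-corrected (left tail for left-skewed
columns) — with the final score the maximum of the three; the top
`contamination` fraction (default 0.15) by score is excluded. The default
pipeline order is prune → RFE → outlier-removal → fit.

**Cascade.** A molecule survives iff it passes the physicochemical windows
(closed intervals; logP is the Crippen estimate, which can differ from
database-supplied values) and both classifier probabilities meet their
thresholds (≥, default 0.9 each, applied independently per model). The
barrier prediction annotates survivors (feasible iff ≤ cutoff, default
15 kcal mol⁻¹, configurable within the physically supported 15–20 window)
rather than filtering; a flag enables hard filtering. Threshold values
above 1 are tolerated as an explicit reject-all sentinel. Every molecule
receives a trace (stage of rejection), so per-stage counts always partition
the library; survivor counts are non-increasing in each threshold. For the
structural-innovation arm, survival is re-applied at a relaxed threshold
(default 0.8) and survivors are reduced to one representative per internal
Tanimoto-similarity neighbourhood: a greedy single pass in input order
retains a record iff its similarity to every previously retained record is
≤ 0.8 (first kept wins — deterministic, order documented). The internal
dedup fingerprint defaults to ECFP4.

## Shapley attribution

Tree ensembles get **exact interventional Shapley values**. For explicand
x and background row z, each leaf defines (after collapsing repeated splits
into per-feature intervals) sets A (only x satisfies) and B (only z
satisfies); the Shapley value of the resulting conjunction game is
c·(a−1)!·b!/(a+b)! for members of A and −c·a!·(b−1)!/(a+b)! for members of
B. Summing over leaves, trees and background rows (a numba kernel) gives
attributions whose total is exactly f(x) − mean_z f(z); the implementation
is verified in tests against a brute-force coalition enumeration that only
calls `predict`. Non-tree models fall back to a seeded permutation-sampling
estimator whose telescoping construction also satisfies additivity exactly.
The background is a deterministic subsample of ≤ 200 training rows; global
importance is the mean |Shapley| over the evaluation set (test partition by
default), with ties in rankings broken lexicographically. MACCS keys are
mapped to their published SMARTS definitions for rule reports; count-based
("more than n occurrences") and undefined keys are flagged composite rather
than forced into a single SMARTS.

## Strategy scoring

Safety and pharmacokinetic scores are rule tables: score = Σ weight ×
points(rating) with points {Excellent: 1, Medium: 0.5, Poor: 0}, unit
weights by default, five properties each, so scores lie in [0, 5]. Missing
ratings contribute 0 and are flagged. Ratings come from a pluggable
provider (CSV import of precomputed predictions, or the synthetic
generator); the thresholds that map raw predictions to categories are the
provider's responsibility. Rankings are total and deterministic (descending
score, ties by id).

**Diversity** is 1 − mean pairwise Tanimoto (ECFP4) over the *distinct*
canonical structures of a set; a unique-scaffold-fraction variant is
available. Deduplicating first is deliberate: diversity is a property of
the distinct structures in a pool, and a plain pair-mean over raw records
can *increase* when a structural outlier is duplicated (the new ⟨1.0⟩
self-pair is outweighed by the outlier's low similarities), which would
reward redundancy. Under the dedup-first definition, inserting duplicates
leaves the score unchanged. **Innovation ranking** combines novelty
(1 − max Tanimoto to the known-ESIPT reference set) and Murcko-scaffold
rarity (inverse scaffold frequency within the candidate pool), weighted
0.5/0.5 by default and configurable.

## Synthetic benchmark

The generator plants the ESIPT motif `[OX2H]c1ccccc1[#6]~[#7]`
(ortho-phenolic donor adjacent to a carbon bearing a nitrogen acceptor)
with known ground truth:

* **positives** — HBT, HBO, HBI and salicylaldehyde-azine scaffolds with
  0–3 random substituents (F, Cl, Br, CH₃, OCH₃, NMe₂, CN, NO₂) at C–H
  positions; every output matches the motif SMARTS (resampled otherwise).
  In MACCS space the motif pins two declared bits: MACCS139 ([O;!H0], the
  donor) and MACCS97 ([#7]~*~*~*~[#8], the donor–acceptor spacing), used by
  attribution-recovery tests.
* **conventional negatives** — simple acyclic/monocyclic drug-like
  templates (no O–H groups, no C~N adjacent to a phenol), decorated the
  same way; none match the motif.
* **fluorophore negatives** — conjugated dye templates (coumarins,
  naphthalimide, stilbene, anthracene, acridine) without the ortho-hydroxy
  donor. They are deliberately closer to the positives in fingerprint space
  than the conventional set (verified by class-centroid similarity), making
  the second classification stage harder, as in real screening.
* **barriers** — barrierᵢ = rescale(softplus(Σ w_f x̃ᵢf + εᵢ)) where x̃ are
  z-scored values of five named 2D descriptors (default weights: MolLogP
  +1.0, TPSA −0.8, rotatable bonds +0.5, H-bond donors +0.7, ring count
  −0.6), ε ~ N(0, noise_sd·sd(signal)) with noise_sd = 0.3, and the
  rescaling maps the set's softplus values into (0.3, 20] kcal mol⁻¹ (the
  scale is therefore a property of the whole set; with noise_sd = 0 the
  barrier is a deterministic function of the features). True weights are
  returned for recovery experiments. The barrier model is a smooth monotone
  statistical target, not physics: it exercises the regression and
  fold-rate machinery.
* **ratings** — independent Excellent/Medium/Poor draws per property and
  molecule with configurable probabilities (default 0.5/0.3/0.2).

All generators are deterministic under their seed; a 20-molecule fixture
CSV is regenerated bit-exactly in CI to guard against generator drift.

**What passing tests show — and don't.** The planted motif makes class
separability essentially perfect (CV ACC ≈ 1.0 for both classifiers at 500
molecules/class), so green classification tests certify the pipeline
machinery (featurization, splits, metrics, thresholds, attribution), not
real-world discrimination of ESIPT from look-alike fluorophores, which is
far harder. Likewise the barrier targets are a designed function of 2D
descriptors; real barrier prediction from structure alone is substantially
noisier. The synthetic negatives span a handful of template families, not
the chemical breadth of real screening libraries.

## Problem sizes and numerical choices

Default study sizes: 500 molecules/class for the classifiers, 600 for the
barrier regressor (≈15% removed by ECOD), a 510-molecule screening library,
Shapley evaluation on 100 molecules against a 50-row background. The
acceptance script runs this full study in about two minutes. The ECOD
planted-outlier benchmark uses a 5-D standard-normal cloud with five
outliers displaced +8σ in every coordinate: ECOD is rank-based per
dimension, so a single-axis displacement cannot distinguish a handful of
planted points from the inliers' own per-axis extremes at n = 100, whereas
a full-coordinate displacement is unambiguous. Degenerate inputs are
explicit errors: single-class labels, non-finite features, non-positive
regression targets (fold errors undefined), fewer than 2 molecules for
diversity, fewer than 10 samples for ECOD. Boundary conventions: prefilter
windows are closed intervals; cascade threshold comparisons are ≥; fold
success is strict (<); the barrier-feasibility boundary counts as feasible.

## Known limitations

MOE-style 3D descriptors and conformer-dependent properties are out of
scope (the 2D panel covers the descriptor families attribution analysis
needs). ADMET ratings are consumed as categories from a provider, never
predicted. The exact interventional Shapley kernel covers sklearn decision
trees and random forests; boosted models use the sampling estimator.
Probability calibration for SVM relies on sklearn's internal
cross-validated calibration. Scaffold novelty uses Murcko frameworks, which
treat ring-system decorations as equivalent; positional isomers of one
framework count as one scaffold.
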