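# Methods

`chemfuse` implements a ligand-based virtual-screening workflow for a
single protein target: activity modelling on a ligand set with measured
IC50 values, a learned multi-representation similarity function, diversity
reduction and similarity screening of a candidate library, and post-hoc
cluster/SAR analytics.  This note records the models, the conventions, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Units and activity conventions

All potencies are stored as IC50 in nanomolar and converted as
pIC50 = −log10(IC50 [M]) = 9 − log10(IC50 [nM]), so 100 nM ↔ pIC50 7.
Activity classes partition pIC50 as low < 5 ≤ medium ≤ 7 < high; both
boundaries belong to the medium class.  The binary discretisation that
feeds classification metrics is high = pIC50 > 7 versus low = pIC50 ≤ 7.
Lipinski's Rule of Five is applied with the four strict inequalities
LogP < 5, MW < 500 Da, HBD < 5, HBA < 10, on the average molecular weight
(the conventional choice for this rule), not the monoisotopic mass.

Input tables are validated per row with RDKit; unparsable SMILES and
anomalous IC50s (missing, non-numeric, ≤ 0, or outside 10⁻³–10¹² nM) are
rejected and counted.  Exact duplicates after canonicalisation collapse to
a single record with the median IC50 — the median is robust to the
order-of-magnitude outliers typical of multi-database aggregations.
Multi-fragment SMILES keep their largest organic fragment, so salts and
free bases deduplicate together.  Stereochemistry beyond what RDKit
canonicalisation preserves is not standardised.

## Features

Each molecule gets three representations:

* **Morgan fingerprint** — 1024 bits, radius 2 (ECFP4-equivalent).  The
  radius is configurable; 2 is the field's default for similarity work.
* **Six descriptors**, in fixed order: MolLogP, MolWt (Da),
  NumRotatableBonds, TPSA (Å²), NumHAcceptors, NumHDonors.  LogP is the
  Crippen estimate; printed literature LogP values for reference compounds
  are estimates from unspecified methods and are not used as test oracles.
* **SELFIES token counts.**  Molecules are encoded into SELFIES-style
  token sequences by an in-package encoder (`chemfuse._selfies`) that
  derives tokens from the kekulized canonical SMILES: atoms with bond
  prefixes, branch symbols with base-16 length indices, ring symbols with
  span indices.  Sequences are reduced to a bag-of-tokens count vector
  over a vocabulary built on the training set, plus one unknown-token bin;
  counts are order-insensitive and need no padding policy.  The vocabulary
  is serialised with any trained model so screening uses the training
  inventory.

The QSAR feature matrix is the concatenation [fingerprint | descriptors]
(1030 columns at the defaults).  Standardisation is per-column z-scoring
with training-set statistics only; constant columns are set to zero and
flagged rather than dividing by zero.

## Regression suite

Six regressors are mandatory: ridge, linear SVR, extra trees, LightGBM,
XGBoost and random forest, with default hyperparameters alpha = 1.0;
C = 0.1, epsilon = 0.01; 200 trees (no depth cap); lr 0.05, 300 rounds,
depth 7, 31 leaves; lr 0.1, 200 rounds, depth 6, subsample 0.8; and 150
trees respectively.  Convolutional and graph neural models are optional
model families: without an available backend they are reported as explicit
skips, never silently omitted.  Data are split 80/20; grid search (small
grids centred on the defaults) runs inside 5-fold CV on the training split
only, and an instrumentation hook can record every fit's row indices to
prove the test split stays untouched until final scoring.  CV
classification metrics discretise the pooled out-of-fold predictions; this
convention is recorded in the report metadata.  Precision/recall/F1 are
taken on the high class and flagged undefined (not NaN) in degenerate
cases.

Robustness curves add Gaussian noise N(0, σ²) with σ = intensity to the
(standardised) test features — the perturbation operator had to be chosen
here, and additive noise on standardised features makes intensities
comparable across columns.  Intensity 0 reproduces the baseline metrics
exactly; positive intensities average a configurable number of draws.
Taylor statistics (sd of predictions, correlation, centred RMSE) use
population standard deviations, so the identity
crmse² = sd_p² + sd_o² − 2·sd_p·sd_o·r holds to rounding.

## Fusion similarity model

The similarity model scores molecule pairs in (0, 1).  Per molecule, three
encoders map into a shared hidden space (default 128): a linear layer for
the SELFIES counts, and linear → ReLU → dropout (0.2) → batch norm for the
fingerprint and for the descriptors.  A multi-head attention block
(4 heads) uses the SELFIES embedding as the query over the stacked
fingerprint and descriptor embeddings as a two-token key/value sequence —
the smallest faithful realisation of "topological context decides the
modality weighting".  The attended output is concatenated with the
fingerprint and descriptor embeddings into a 3·hidden embedding.

The published description presents a single-molecule encoder stack yet
scores pairs; this implementation resolves that by sharing all encoder
weights between the two molecules (siamese) and feeding the head the
symmetric combination [|e_a − e_b|, e_a ⊙ e_b], which guarantees
score(a,b) = score(b,a) by construction.  The head is an MLP
(128 → 32 → 1) with ReLU/dropout/batch-norm on hidden layers and a final
sigmoid.

Training pairs come from the activity classes: positives are high×high
pairs, negatives are any pair with a low member; medium molecules are
excluded, and classes are balanced by subsampling.  The loss is MSE
against the {0,1} labels, optimised with Adam (lr 10⁻³, batch 64, up to 50
epochs), halving the learning rate when validation loss (15 % held-out
pairs) plateaus for 5 epochs and stopping after 10 epochs without
improvement; the best-validation weights are restored.  None of the
architecture sizes were published; the defaults here are conventional
small-model choices fixed once.

The network runs on a compact reverse-mode automatic-differentiation tape
(`chemfuse._autograd`) over numpy arrays; gradient correctness is verified
against central finite differences in the test suite, and training is
bit-deterministic for a fixed seed.  Descriptor inputs are z-scored and
SELFIES counts scaled by the mean training token count inside the model,
with the statistics stored in the checkpoint.

The benchmark similarity is the Tanimoto coefficient |A∩B|/|A∪B| over
fingerprint bits, with the convention that two empty bit sets have
similarity 1.  Screening quality is compared via enrichment at k: the
fraction of actives among the top-k ranked candidates and its fold over
the base rate (undefined-flagged at base rate 0), with ties broken by
stable candidate order.

## Screening

Diversity reduction embeds candidate fingerprints into 2-D with UMAP
(n_neighbors 15, min_dist 0.1, Jaccard metric on bits, seeded), collapses
exact fingerprint duplicates first, then overlays the finest square grid
whose occupied-cell count does not exceed the requested target and keeps
the candidate nearest each occupied cell's centroid.  Choosing the finest
not-exceeding grid makes the selection idempotent (re-reducing a kept set
at its own size keeps everything); the realised count can undershoot the
target slightly and is recorded with the grid resolution and seed.  The
published workflow states only that UMAP reduced the library; the
occupied-grid policy is this package's reconstruction.

Screening scores every candidate against the ligand anchors and ranks by
the best (maximum) fusion score, with ties broken by id.  Because the pair
score estimates the probability that *both* members are high-activity, the
default anchor set is the high-activity ligand subset; a score against a
weak ligand carries no evidence of candidate potency, and empirically the
maximum over weak anchors only adds extrapolation noise.  Screening
against all ligands remains available (`anchor_policy="all"`).  Each
result row carries the best anchor, the Tanimoto to it, a predicted pIC50
from the trained extra-trees regressor (the suite's strongest model)
converted to IC50 via the inverse unit map, Lipinski violations, and a hit
flag at fusion score > 0.8.  Top candidates are exported as a delimited
table plus an SDF (one record per hit, title = id) for downstream docking,
which is outside this package's scope.

## Cluster/SAR analytics

K-means runs on [fingerprint bits | standardized pIC50] so structure and
activity contribute on comparable scales.  For each candidate k the
best-of-20 k-means++ inertia (SSE) and silhouette are computed; the chosen
k is the silhouette argmax, with the elbow (SSE) curve reported alongside
— when the two criteria disagree, silhouette wins and both curves remain
inspectable.  PCA provides the 2-D projection with explained-variance
fractions.  Per cluster the toolkit reports fingerprint-bit frequencies
(fraction of members with the bit set), Pearson correlations of each
descriptor with pIC50 (hydrogen-bond acceptors being the conventional
headline), flagged undefined for zero-variance descriptors or clusters
below three members, and the maximum common substructure via RDKit's FMCS
(atoms matched by element, bonds by order, ring bonds to ring bonds,
10 s timeout reported distinctly from an empty result).  Because a SMARTS
pattern carries no hydrogen counts, the hydroxyl check matches the MCS
back onto each member and verifies the matched oxygen bears a hydrogen
everywhere.

## Synthetic benchmark

The generator emulates a target-focused ligand table with a planted,
recoverable structure–activity relationship:

* molecules are scaffold + substituent assemblies over four ligand
  scaffolds (benzene, indole, piperidine, pyrimidine; two substitution
  points each) with a ~12-fragment alphabet and optional short linkers
  (the linkers enlarge the unique-molecule space so deduplication does not
  distort the planted mixture);
* pIC50 = 4.7 + 2.8·[boost] + 0.5·(TPSA/100) + 0.05·rot + ε with
  ε ~ N(0, 0.4²), where "boost" is a hydroxymethyl substituent present
  with probability 0.45; nonlinear mode adds a 2.0·boost·(TPSA/100)
  interaction.  At these defaults the class mixture is ≈ 41 % high / 36 %
  medium / 23 % low;
* the boost fragment carries a hydroxyl so the MCS stage has a planted
  motif to recover, mirroring the qualitative "OH in high-activity
  clusters" pattern the workflow is meant to surface;
* candidate libraries mix analogs (single-substituent edits of ligand
  molecules, boost slots preserved) with decoys on disjoint scaffolds
  (naphthalene, thiophene, furan, cyclohexane), default analog fraction
  0.25;
* the true coefficients and per-molecule flags ship with every dataset,
  and the generator is validated first: regressing generated pIC50 on the
  true design matrix recovers β within three standard errors before the
  data validate anything else.

What passing the synthetic benchmark shows: the pipeline recovers a
planted descriptor/substructure signal end to end — features carry it, the
regressors find it (extra-trees test R² ≈ 0.9 at n = 2000), the fusion
model separates high×high from high×low pairs by ≈ 0.9 in score, analogs
enrich ≈ 3–4-fold in the screen's top decile, and the MCS of a coherent
high-activity cluster contains the hydroxyl.  What it does not show:
performance on real medicinal-chemistry distributions — real ligand sets
have broader scaffold diversity, correlated assay noise, and activity
cliffs the linear-plus-interaction generator does not emulate, so the
synthetic numbers are recovery checks, not accuracy claims.

## Problem sizes and determinism

Desk-scale defaults keep every stage on one CPU in minutes: the regression
benchmark uses the generator's n = 2000 default; similarity training in
tests and the acceptance script uses a few hundred ligands and a few
thousand pairs, which is already past the point where the separation and
enrichment results stabilise.  A single top-level seed fans out
deterministically to the splitters, models, pair samplers and noise draws;
two runs with the same seed reproduce losses to 10⁻⁶ and rankings exactly.

## Known limitations

* The SELFIES encoder implements the encoding direction only and drops
  stereochemistry; its token inventory is deterministic but not guaranteed
  byte-identical to other SELFIES implementations (bag-of-token counts are
  unaffected by index-symbol conventions).
* Pair labels use only the high and low classes; medium molecules are
  unseen at training time, which is why screening defaults to high
  anchors.
* The diversity grid can undershoot the requested count on sparse
  embeddings; the realised count is reported.
* The "CPI" permeability index sometimes quoted alongside screening
  results has no published formula and is not implemented; docking and
  adverse-reaction risk scoring are likewise out of scope (ranked hits are
  exported for external docking instead).
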