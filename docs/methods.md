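# Methods

This note records the models, parameter choices and numerical conventions
behind `phosphoresponse`, and what the synthetic cohort does and does not
establish about real data.

## Measurement model and normalization

Each well of a multiplexed bead assay reports one fluorescence intensity
per analyte; GAPDH is carried in every well as a loading control, and each
sample contributes three DMSO vehicle wells beside its drugged wells. The
normalization arithmetic is:

1. per well, every analyte intensity is divided by the well's GAPDH
   intensity and log2-transformed (this cancels any per-well scaling,
   e.g. lysate amount);
2. per analyte, the median of the log2 ratios over all DMSO wells of the
   plate is subtracted from every well, anchoring the scale on the vehicle
   controls;
3. the change for (sample, drug, analyte) is the centered drugged value
   minus the mean centered value of that sample's DMSO replicates.

Because step 3 is a difference, the centering constant cancels in the
changes; it matters only if centered per-well values are inspected
directly. The order of operations is a package convention (the underlying
one-line description of the procedure is compatible with several
orderings); it was chosen to make changes DMSO-referenced and scale-free,
and it is what the tests pin down.

Non-positive phospho-analyte intensities are clamped to half the smallest
positive intensity on the plate (with a warning) so the logarithm is
defined; a non-positive GAPDH value is unrecoverable and raises an error.

**Regulated-analyte counting** uses a threshold τ on the log2 scale: a
change below −τ is down-regulation, above +τ up-regulation. τ is not
derivable from first principles; the default τ = 0.1 (≈7% change) is a
deliberately permissive screening threshold and is exposed in the config.

**Assay concentrations** equalize unbound drug exposure between plasma and
20%-FBS culture medium: c_assay = Cmax · fu_plasma / fu_medium, with both
unbound fractions in (0, 1].

## Sensitivity quartiles and predictors

GI50 values (72-hour growth inhibition, molar) are quartiled **per drug**:
samples sorted ascending, four contiguous near-equal groups, remainders to
the earlier groups, ties broken by sample id. Q1 = most sensitive by this
package's convention (a `direction` flag reverses it, since the field uses
both conventions).

Predictors are evaluated by **Monte-Carlo cross-validation**: 100
independent random stratified 85/15 train/validation splits rather than a
100-fold partition (a partition of ~245 rows into 100 folds would leave
2–3 rows per fold and no stratification). Feature selection — recursive
elimination driven by random-forest impurity importances, dropping the
lowest 20% per round — runs strictly inside each training split; the
no-leakage property is asserted by test. The headline number is the
one-vs-rest ROC AUC per quartile computed from pooled out-of-fold
predictions, with per-fold mean ± SD alongside; pooling is reported first
because per-fold AUCs on ~37 held-out rows are individually unstable.
Folds whose holdout lacks a class skip that class and are counted.

Model kinds and defaults (all exposed as arguments):

* `rf_classifier` — multiclass random forest, 500 trees, impurity
  importances; class scores are the predicted class probabilities.
* `rf_regressor` — random forest regression on the ordinal quartile code
  1–4; the one-vs-rest score for class k is −|prediction − k|, exploiting
  the ordinal structure of sensitivity.
* `elastic_net` — one-vs-rest linear models with mixing 0.5 at a fixed
  penalty (0.1) inside CV; the standalone `elastic_net_weights` chooses the
  penalty by internal cross-validation. Features are standardized before
  every elastic-net fit so the ±0.1 coefficient-significance rule is
  scale-meaningful; significance is exactly |w| > 0.1 on the standardized
  scale.

The RF-RFE + RF-regression combination (selection to 15 features, 300
trees for the model, 100 trees inside the elimination loop) is the
protocol used by the acceptance script; the lighter elimination forest
trades a negligible amount of selection stability for a ~3× faster loop.

The **genomic baseline** runs the identical CV protocol on three binary
mutation flags (EGFR, KRAS, PIK3CA) broadcast from samples to
(sample, drug) rows. With only 8 possible feature patterns its AUCs
fluctuate visibly around 0.5 for individual quartiles; chance-level
behaviour is asserted for the extreme quartiles Q1/Q4, which are the ones
the phospho-based comparison targets.

**Mutation–sensitivity enrichment** uses the 2×2 table
(mutated vs wild-type) × (Q1∪Q2 vs Q3∪Q4) and the χ² test with Yates
continuity correction, 1 df, the continuity term clipped at zero; a zero
margin returns p = 1 with a warning rather than an error.

## EPS

For a profile of changes Δᵃ and an undirected interaction network with an
analyte→node map, EPS(v) = Σ over analytes a mapped to direct neighbors of
v of |Δᵃ|. The node itself is excluded, which is what lets a quiescent
junction between perturbed neighbors rank highly; options exist for an
include-self weight. Proteins carrying two measured phosphosites (e.g.
AKT1 T308/S473) appear as separate site-level entities that inherit the
protein's neighborhood sum plus an optional per-site self-term
(default 0 — with the default the sites tie, and the tie rule orders
them deterministically). Only tractable (druggable) entities are ranked:
descending EPS, ties at the minimum rank of the block, block order fixed
by entity id. Edges are unweighted; a confidence-weight hook exists in the
data model but no weighting scheme is applied.

Partner nomination orders candidate drugs by the best (minimum) EPS rank
among their target entities in the anchor drug's ranking. Top-k
concordance counts, over combinations whose Bliss summary exceeds 0.1, the
fraction whose partner target sits at rank ≤ k (k ∈ {5, 10}).

## Bliss synergy

Effects are fractional growth inhibition (1 − relative viability), clamped
to [0, 1] with clamps logged. The Bliss expectation fₐ + f_b − fₐ·f_b is
compared cell-wise against the observed combined effect over the dose
grid; the scalar summary is the **mean excess** by default (max and
top-quartile-mean are available) because published per-combination scores
are single numbers without a stated reduction, and the mean is the least
structure-committed choice. The screen is enumerated as **ordered** pairs
(anchor, partner) — 7 drugs × 6 samples → 252 records — with an unordered
21-pair view obtained by averaging the two orientations.

## Rank-bias and permutation statistics

Records are quartiled by Bliss summary (same remainder rule); for each
record in the top and bottom quartiles the partner's best target rank
(default; an all-target-ranks mode exists) enters a two-sided Mann–Whitney
U test. Exact enumeration is used when both groups have ≤ 8 untied values,
otherwise the tie-corrected normal approximation with continuity
correction (cross-checked against scipy to 10 significant digits, and
against the exact path to |Δp| ≤ 0.02 at group sizes 8–15).

The permutation null re-assigns EPS rankings at random — by default
shuffling the rank values **within each (sample, drug) ranking universe**,
which preserves each universe's rank support; a global shuffle is
available. The Mann–Whitney p is recomputed per permutation (10,000 by
default; fewer than 100 warns) with the same normal-approximation path
used for the observed grouping, and the observed p is located by its
mid-quantile (ties split) in the null.

## Cohort comparison and clustering

PCA runs on the per-analyte-centered (condition × analyte) change matrix;
the first three components are reported. Per-cohort density curves use a
Gaussian KDE with Silverman bandwidth (presentation only — no test depends
on the bandwidth). The cell-line vs patient location difference is a Welch
two-sample t-test on the pooled change values. Hierarchical clustering of
analytes or conditions uses average linkage on Euclidean distances with
scipy's deterministic leaf ordering.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the study design: 35 cell lines + 16 patient samples,
7 drugs (gefitinib→EGFR, trametinib→MAP2K1, pictilisib→PIK3CA,
capivasertib→AKT1, everolimus→MTOR, vemurafenib→BRAF,
luminespib→HSP90AA1), a 52-analyte panel (51 proteins, AKT1 with two
sites), and a 6-cell-line pairwise screen (252 ordered records).

* **Network**: a connected Barabási–Albert graph (80 nodes, 3 edges per
  node) with drug targets at the hub positions, mirroring the hub role of
  signalling drug targets; tractability flags are Bernoulli(0.5) with all
  targets forced tractable.
* **Perturbations**: the mean change at an analyte of a node at graph
  distance d from the drug target is −effect_size · 0.5^d, truncated at
  d = 2 — the minimal propagation structure that makes neighborhood scores
  informative; 2 feedback analytes per drug get mean +1; Gaussian noise
  (sd 1) is added, inflated 1.5× for patient samples to reflect the higher
  heterogeneity of fresh ex vivo material. With noise off, planted values
  are reproduced exactly (asserted).
* **Sensitivity**: log10 GI50 = −6.5 + 0.5 · Σ(signature changes) +
  N(0, 0.2), signature = the 5 analytes closest to the target. Because the
  linear score uses the *observed* changes, sensitivity is learnable from
  the measured profiles, and the zero-noise limit makes observed quartiles
  equal the recorded ground truth.
* **Genotypes**: independent Bernoulli flags (EGFR 0.2, KRAS 0.3,
  PIK3CA 0.15) — deliberately uninformative decoys.
* **Combination screen**: single agents follow Hill curves (slope 1)
  sampled at 1/16–1/2 of each GI50, keeping single-agent effects ≤ 1/3 so
  a planted excess of 0.3 never clips at 1 and noiseless summaries recover
  planted values to ≥ 10 significant digits. In the default auto mode the
  excess is planted exactly on ordered pairs whose partner target ranks in
  the anchor's EPS top 5, plus N(0, 0.02) noise.

One master seed drives named `SeedSequence` children per stage (network,
perturbations, sensitivity, genotypes, screen), so stages regenerate
independently and full runs are byte-identical under a fixed seed.

**Limitations.** Because planted synergy is aligned with EPS by
construction, concordance and rank-bias tests on the synthetic cohort are
*recovery* checks — they show the statistics detect a planted signal at
realistic noise, not that EPS predicts synergy in real tumours, where
observed concordance is far from 100%. The generator likewise omits
batch effects, correlated measurement noise across analytes, realistic
mutation spectra and co-occurrence, dose-response curve misspecification,
and any direct biological coupling between feedback up-regulation and
resistance. Regulated-analyte means depend strongly on the noise floor
relative to τ and are not comparable to published cohort means.

## Problem sizes and numerical choices

The acceptance script and test suite run the full-size cohort for the
predictor and rank-bias checks (245 labelled rows, 100 CV folds, 10,000
permutations). Null-calibration checks use reduced sizes chosen for tight
Monte-Carlo behaviour at desk scale: 25 CV folds for the no-signal AUC
band and 200 outer seeds × 400 inner permutations on a compact ranking
universe for the quantile-uniformity KS check. Tolerances in tests follow
the quantity's arithmetic: exact where the computation is exact
(enumeration, χ², exact Mann–Whitney, noiseless recovery at ≥ 10
significant digits), interval-based where Monte-Carlo variation is
intrinsic (AUC bands, binomial null rates). Floating-point comparisons of
round-tripped files require ≥ 12 significant digits (files are written
with 17 significant digits).
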