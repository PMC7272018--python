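# Methods

`pathrisk` implements a pathway-level risk analysis for two-group (case vs
control) expression cohorts, modelled on the question of which smokers
develop lung cancer: individual genes are noisy discriminators, so the
pipeline aggregates differential expression into pathway-level "functional
deviation" scores, weighted by each gene's connectivity in a
protein-interaction network, and classifies samples on those scores with a
linear SVM.

## Pipeline

1. **Preprocessing.** Probe-level rows mapping to the same gene symbol are
   averaged; probes without a map entry, or mapping to several symbols
   (`A /// B`), are dropped (expanding a multi-symbol probe would count one
   measurement twice). Each gene row is then standardised across samples,
   X′ = (X − mean)/SD, with the sample SD (n − 1 denominator); zero-variance
   rows are dropped. Collapsing precedes standardisation.

2. **Differential expression.** Per gene, a two-group empirical-Bayes
   moderated t: the pooled residual variance s²_g (d = n₁ + n₀ − 2 df) is
   shrunk toward a prior s₀², s̃² = (d₀s₀² + d s²_g)/(d₀ + d), with (d₀, s₀²)
   fitted across genes by method of moments on log variances (digamma/
   trigamma moment equations, trigamma inverted by Newton iteration).
   Two-sided p-values use d + d₀ df; BH-FDR adjustment over all genes.
   "logFC" is the case-minus-control difference of group means **on the
   Z-scored matrix** — it is not a true log-fold-change, and the default
   |logFC| > 0.6 threshold is applied on that scale. DEGs require adj-p
   < 0.01 and |logFC| > 0.6, both strict. The design is group-only; no
   covariates. The implementation is cross-checked in the test suite against
   Bioconductor limma on a small matrix.

3. **Unsupervised clustering.** Samples are compared on their DEG vectors by
   Pearson correlation distance d = 1 − r and agglomerated by UPGMA
   (unweighted average linkage, Lance–Williams update). The tree is cut at
   k = 2; when two candidate merges tie in height, the pair with the
   smallest (row, col) index merges, fixing the merge sequence across
   platforms. Each cluster is assigned the observed class that predominates
   in it; per-cluster accuracy is correct-in-column over column total,
   reported exactly and as a rounded percent. A 50/50 tie goes to the class
   no cluster has claimed yet, with a warning.

4. **Enrichment.** Up- and down-DEG lists are tested separately against each
   gene-set collection with the one-sided hypergeometric upper tail
   P(X ≥ k); the background universe is the set of genes on the analysis
   matrix after preprocessing (the measured universe). Terms with raw
   p < 0.05 are kept — no multiple-testing correction on enrichment, so term
   counts are liberal by design. The feature space is the union of
   significant terms across all runs; each term carries `up_members` and
   `down_members` computed against the full DEG lists regardless of which
   run found it.

5. **Interaction network.** Edge lists are merged into one undirected simple
   graph over upper-cased symbols (duplicates and self-loops removed). The
   weight ω of a gene is its degree in this **full union graph**, which is
   stable under DEG-list changes; the induced DEG subnetwork (isolated DEG
   nodes excluded) is reported separately.

6. **Functional deviation score.** For a term with up members i = 1..m and
   down members j = 1..n,

       score(P, s) = log[(ε + Σᵢ ωᵢ(d_{i,s} − d̄ᵢ)²) / (ε + Σⱼ ωⱼ(d_{j,s} − d̄ⱼ)²)]

   with d_{g,s} the Z-scored expression and d̄_g the mean over **control
   samples only** (controls are also scored against it; the scored control
   is not excluded from its own reference mean). Score > 0 means the
   sample's deviation on that term is dominated by the up-regulated members.

7. **Classification.** SVM-RFE on the pathway-score features: at each size,
   stratified 5-fold CV accuracy of a linear SVM (C = 1) is recorded; the
   lowest-squared-coefficient feature is removed (step 1) until one remains;
   the optimum is the size with maximal accuracy, ties toward fewer
   features. Six clinical covariates (age, gender as 0/1, smoking duration,
   smoking index, nodule size, lymphadenopathy as 0/1) can be appended
   *after* RFE, without re-running it. Final evaluation is stratified 5-fold
   CV with per-fold ROC from decision-function scores and trapezoidal AUC;
   predicted labels threshold the decision function at 0. Features are
   standardised with training-fold statistics only; features constant in a
   training fold are dropped within that fold. RFE ranking and the final CV
   use independently seeded folds — reusing the same folds for selection and
   evaluation would bias accuracy upward, a caveat that applies to any RFE
   curve read as an unbiased estimate.

## Numerical choices

- **ε pseudocount (default 1e-8).** The raw log-ratio is undefined when a
  term has no members (or no network weight) on one side — common, since
  enrichment runs per direction. A symmetric ε on both sums keeps every
  score finite and preserves exact antisymmetry under swapping the up and
  down lists (the score is computed as log(ε + up) − log(ε + down) so the
  negation is exact in floating point).
- **Natural log.** The log base only rescales features and is irrelevant to
  scale-invariant classifiers.
- **"Distance" without a root.** The weighted deviation is a sum of squares,
  not a Euclidean norm; taking a square root would only rescale the
  log-ratio by ½ per side and break the clean ω-scale invariance of the
  ratio.
- **Weightless members.** Genes absent from the interaction graph get ω = 0
  and contribute nothing; `min_weight` > 0 floor-weights them instead, for
  sensitivity analysis.
- **Degenerate inputs.** Constant gene rows are dropped before analysis;
  a sample with zero variance across DEGs makes the Pearson distance
  undefined and raises with the sample named; a CV fold containing one class
  raises with a suggestion to reduce the fold count.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions: 85 controls vs 78 cases, 2000 genes
of which 150 are shifted up and 120 down in cases by 1.5 within-group SDs
(Gaussian baselines suffice because rows are Z-scored; a log-normal marginal
would be standardised away), 20 gene sets of 10–30 genes with max(1,
n_terms/4) = 5 informative terms, a Barabási–Albert interaction graph
(3 edges per node) giving the heavy-tailed degree distribution of real
interactomes, and clinical covariates mildly shifted in cases
(clinical_effect = 0.5 ≈ +5 years of age). One master seed spawns
independent child streams per component, so reparameterising one component
never perturbs another's draws.

Two structural choices deserve emphasis:

- **Informative terms are single-direction.** Each informative term draws
  its planted members from one direction only, alternating up and down
  across the collection. This mirrors gene sets discovered by per-direction
  enrichment — and it is a mathematical necessity, not a convenience: the
  squared deviation is direction-blind, so a term with strongly deviating
  genes on *both* sides has numerator and denominator inflate by the same
  factor in cases, and the log-ratio's mean carries no signal at all.
- **What the generator does not emulate:** probe-level array intensities,
  batch effects, gene–gene correlation beyond the planted shifts,
  mean–variance trends, missing clinical fields, or annotation noise in the
  gene sets. Passing tests therefore demonstrate that the chain of
  statistics is implemented correctly and is well calibrated under its own
  assumptions — not that the pipeline's headline numbers transfer to any
  real cohort. On these clean Gaussian cohorts the planted signal is strong:
  clustering and classification are near-perfect, unlike on noisy real
  microarray data.

Problem sizes in the test suite are scaled to the structure being tested
(300–1000 genes, 25–40 samples per group, 20–50 replicate seeds for
calibration checks), keeping the full suite fast while leaving Monte-Carlo
error small relative to the asserted margins.

## Known limitations

- The moderated-t prior fit assumes exchangeable gene variances; intensity-
  dependent variance trends are not modelled.
- Enrichment ignores gene-set overlap and the GO hierarchy; a gene
  contributes to every term containing it.
- The 47-term feature space of the motivating study arises from its specific
  cohort and annotation snapshots; on synthetic data the feature space is
  whatever the enrichment finds (the informative terms, at the defaults).
- RFE is greedy; it is not guaranteed to find the globally best subset
  (the tests check agreement with exhaustive search only probabilistically).
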