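# Methods

## The model

`hmppi` treats host–microbiome interaction inference as interolog
transfer: an experimentally verified bacterial interactor of a human
protein lends its interaction to close homologs.  Homology is organized
through UniRef clusters — human proteins at the 100/90% identity level,
bacterial proteins at the 50% level — so that one edge of the network
("HBNet") connects a human protein cluster to a bacterial UniRef50
cluster, carrying the verified interactors as evidence.  Because UniRef50
clusters are permissive, membership alone is not enough: each member must
additionally score at least 70% similarity to a verified interactor to
count as a putative interactor.

The community-level readout projects metagenomic gene-family abundances
through this gated network: per sample, a human target's profile value is
the summed relative abundance of its putative bacterial interactors.
Case/control differences in these profiles are then mined with a
random-forest ensemble, and the top decile of mean Gini importance defines
the disease-associated target set.

## Similarity score

For verified interactor `v` and candidate `c`, an optimal Smith–Waterman
local alignment is computed under BLOSUM62 with affine gaps (default open
11, extend 1, so a gap of length k costs 11 + (k−1); the penalties are
unstated in the original recipe and exposed in the API).  The score is

    sim(v, c) = #{aligned pairs (i, j) with B62(v_i, c_j) ≥ 0} / len(v)

Favourable pairs are *non-negative* BLOSUM62 entries ("frequent
substitutions"), not exact identities.  The denominator is always the full
verified-interactor length, so a short candidate cannot score highly by
aligning a fragment, and `sim(v, v) = 1` for standard residues (every
diagonal BLOSUM62 entry is positive).  Gaps inside the local alignment
contribute no pairs but do not change the denominator.  Non-standard
residues (U, O, J) map to X and take BLOSUM62's X-column scores, keeping
the ≥ 0 tally well defined.  The traceback tie-break is fixed (diagonal,
then vertical, then horizontal; highest-scoring cell at smallest (i, j)),
so the pair count is deterministic.  "Within 70% similarity" is read as
≥ 0.70 inclusive, and when an edge has several verified interactors a
member passes by scoring ≥ 0.70 against any one of them — each verified
interactor independently evidences the interaction.

The aligner is authored in-package (Gotoh three-matrix recurrence) because
the pair-level traceback is what the score is defined on; its scores are
verified in the test suite against Biopython's `PairwiseAligner` as an
independent dynamic-programming oracle, and that dual-route check is kept
distinct from the implementation.

## Network filtering

Records are retained when the two taxa differ, exactly one side is human
(taxon 9606 by default, configurable), and both the detection-method and
interaction-type codes appear in editable whitelists.  The criterion the
whitelists encode is "binary, experimental determination" — excluding
co-complex associations, small-molecule records and predicted
interactions — but no authoritative code list exists for it, so the
shipped PSI-MI defaults (two-hybrid family, reconstituted-complex and
biophysical methods; direct interaction and pairwise physical association
types) are documented reconstructions that users should override for
their own exports.  Deduplication is on the unordered accession pair with
isoform suffixes stripped, since UniRef maps canonical accessions.

## Metagenomic projection

Samples with fewer than 10⁷ reads are removed (a read count of exactly
10⁷ is retained; the rule is strict).  UniRef90 gene families map to
UniRef50 clusters by best local alignment requiring identity > 0.90 and
query coverage > 0.90, both strict; coverage is the aligned fraction of
the UniRef90 query, matching blastp convention, and ties break by
identity then lexicographic id.  A precomputed mapping table can be
supplied instead.  Aggregation sums each detected interacting cluster's
abundance into every human target it touches; with `normalize=True` the
abundance is first divided by the cluster's number of human interactors,
which makes the projection mass-conserving (per sample, profile totals
equal the summed abundance of detected interacting clusters — an exact
invariant the tests assert at 1e-9).  Prevalence filtering drops targets
with nonzero abundance in fewer than 5% of samples ("present" means
strictly positive; exactly 5% is retained).  No within-sample
renormalization happens after filtering: the classifier consumes raw
aggregated relative abundances.

## Classification and selection

Cross-validation is stratified 5-fold with shuffling at a fixed seed.  The
hyperparameter grid (unstated in the original recipe) defaults to trees
{100, 500} × max depth {none, 10} × min leaf {1, 5}; grid search happens
once per study on F1 of the case class, before the ensemble, rather than
nested inside it — nesting would multiply cost 8-fold without changing
which targets rank highly, since the ensemble reuses one tuned setting.
The importance ensemble trains `n_iterations = 100` forests; each
iteration undersamples the majority class to the minority size with seed
`base_seed + iteration` and records scikit-learn's normalized
mean-decrease-in-impurity importances (summing to 1 per forest), which are
averaged across iterations.  Selection takes targets strictly above the
linear-interpolated 90th percentile of mean importance, which yields ~10%
of targets when importances are distinct.  Feature preclustering for the
correlation-sensitive comparison models (logistic regression, SVM) groups
features by single-linkage over Pearson r > 0.8 and keeps the
highest-variance member per component; zero-variance features become
singletons and contribute no correlation edges.

Mann–Whitney tests are two-sided; the exact null distribution is used when
both groups have ≤ 8 samples and the data are tie-free, otherwise the
tie-corrected normal approximation; all-tied columns report p = 1 (the
asymptotic variance is zero).  scipy provides both paths behind the
module's interface.

## Enrichment statistics

The three-compartment GO binning uses exactly the declared Cellular
Component term groups (shipped as config), with "exclusively
intracellular" meaning Intracellular and neither Extracellular nor
Membrane.  Disease binning keeps gene–disease association scores strictly
above 0.1 and matches disease names against an editable substring → 
category map; the shipped five-category map (CRC, IBD, Obesity, T2D,
Autoimmune) is a labeled reconstruction.  Subset comparisons use the 2×2
chi-square without continuity correction; when any expected count is
below 5 a Fisher fallback p is reported alongside rather than silently
substituted.  Gene-set enrichment is the one-sided hypergeometric tail
with Benjamini–Hochberg adjustment across sets and an enrichment call at
adjusted p < 0.05; it replaces proprietary webserver enrichment engines
and is methodologically comparable, not numerically identical, to them.

## Structural interface module

Solvent accessibility is Shrake–Rupley: each atom's probe-expanded sphere
(probe 1.4 Å) is sampled with a deterministic golden-spiral quadrature
(960 points by default) and a point counts as accessible when outside all
neighbouring expanded spheres.  Van der Waals radii and the per-residue
maximum-SASA reference (Tien et al. 2013 theoretical values) ship as
in-module tables; unknown elements fall back to 1.7 Å with a warning.
Surface residues have relative SASA ≥ 0.15 (inclusive); interface
residues lose more than 1 Å² of SASA between the chain alone and the
chain in the two-chain complex.  Chain matching requires identity > 0.70
over aligned columns and query coverage > 0.50, with an "exclusive" flag
when exactly one chain passes.  SASA from a fixed quadrature grid is
exactly translation-invariant but only approximately rotation-invariant;
the discretization error falls with the point count (about 1% per residue
at 960 points, below 0.1% by 10⁵ points), which is how the invariance is
verified.  This engine is not a numerical reimplementation of
Lee–Richards-family programs; only the thresholds' semantics are shared.

Interface conservation maps each interface residue of the reference row
to its MSA column and reports (a) the fraction of rows whose residue
scores BLOSUM62 ≥ 0 against the reference residue and (b) the base-2
Jensen–Shannon divergence between the column's amino-acid distribution
(gaps excluded, pseudo-count 0 by default) and a background distribution.
The comparison partner for the JSD is genuinely open; the implemented
contract is column-vs-background with a uniform distribution over the 20
amino acids as default and any supplied background as an alternative.
Under this convention a perfectly conserved column has *high* JSD
(point mass vs uniform) and a random column's JSD tends to 0 as rows
accumulate.

## Synthetic data: what it emulates and what it does not

The cohort generator draws log-normal(0, 1) baselines zeroed with
probability 0.3 — heavy-tailed sparse positives, the realistic shape of
community-level relative abundances — links bacterial clusters to human
targets by an Erdős–Rényi bipartite map (density 0.01, every cluster
keeps ≥ 1 target), and plants effects by multiplying the interactors of
10 chosen targets (of 200) by a fold change of 8 in the 100 cases.  These
defaults are the package's stated study conditions for the recovery
experiments.  The generator does **not** emulate compositionality
constraints, phylogenetic correlation between clusters, batch/study
effects, or covariate confounding; passing recovery tests therefore shows
the estimator chain is correct under its own assumptions, not that real
cohorts will yield effects this clean.  Planted effects bleed by design:
a bacterial cluster serving both a planted and an unplanted target is
boosted as a whole, so some unplanted targets legitimately carry signal —
which is why recovery is asserted as ≥ 8/10 rather than exact.

The cluster generator reaches target similarities by greedy hostile point
substitutions (residues scoring negatively against the original) measured
with the production scorer itself, accepting within ±0.03; this couples
generator and scorer, which is acceptable because the scorer is
independently validated against the DP oracle.  The toy complexes are
single-atom-per-residue strands: contact-window residues sit 4 Å from the
partner chain (well inside the 6.2 Å occlusion range of two
probe-expanded carbons) and the rest at the chosen separation, so planted
contacts must be called and only their ±1 lattice neighbours may join
them.  All generators are pure functions of (parameters, seed).

## Numerical and degenerate-input choices

- Alignment of any empty sequence is an input error; an all-negative pair
  matrix yields the empty alignment with score 0.
- Gating an edge whose verified members have no sequences flags the edge
  `ungated`; downstream profiling skips such edges.
- Benjamini–Hochberg is the standard step-up transform (monotone, capped
  at 1); it is not a projection, so re-applying it to already-adjusted
  values rescales them — only flat vectors are fixed points, and the
  tests state the property that way.
- Degenerate 2×2 margins (annotation constant across both sets) return
  statistic 0, p = 1 with a warning instead of raising.
- All-gap MSA columns report NaN conservation values.
- Zero-variance features never enter correlation graphs; constant
  features get Gini importance 0 because they never split.

## Problem sizes

The shipped tests and the acceptance script run the recovery experiments
at the stated study conditions (200 samples × 200 targets × 100 ensemble
iterations, 500 random alignment pairs, 100-pair JSD checks) and finish
in a few minutes on a single CPU; these sizes are the package's chosen
desk-scale defaults, and all of them are parameters.

## Known limitations

- The evidence-code whitelists and disease-bin map are reconstructions;
  results on real exports depend on supplying the intended lists.
- The UniRef90→50 mapper is exact local alignment over supplied FASTA
  sets; it is meant for network-sized inputs, not proteome-scale search.
- The SASA engine targets small complexes (the pairwise-chain interface
  use case); it is O(atoms²) per call.
- Cross-study meta-analysis, interaction-confidence scoring, taxonomic
  assignment and secretion-system prediction are out of scope.
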