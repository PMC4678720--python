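# Methods

This note documents the models, numerical choices and limitations of
`irescan`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Windows and coordinates

All coordinates are 1-based inclusive (GFF convention); conversion to
Python slices happens in exactly one helper (`genome_io._slice`). The
analysis window (*utr60*) is the fixed `width` (default 60) nt immediately
upstream of the translation initiation codon on the sense strand; the
negative-control window (*negctrl60*) is the 60 coding nt immediately 5'
of the stop codon, assumed IRES-free. Multi-exon genes are collapsed to
their min..max CDS span — fungal genes are intron-poor and the window is
taken upstream of the span start. Genes with less than 60 nt of flank to
the contig edge, and all-`N` windows, are skipped and logged; padding was
rejected because a padded window has no interpretable folding energy or
composition. Windows overlapping an upstream gene's CDS are taken
verbatim. Contigs are treated as linear.

The intergenic region of a gene runs from its translation start to the
nearest annotated CDS boundary upstream on the sense strand (a boundary on
either strand counts), or to the contig edge; abutting genes give length
0, in which case the GC reference for *relGCintergenic* falls back to the
chromosome (logged).

## The 29 features

4 scalar features (*MFE*, *relGCintergenic*, *relGCchr*, *relPosChr*),
16 dinucleotide frequencies, 8 orthologous-group dispersion statistics
(mean, mode, sd, skewness of *relGCintergenic* and *MFE* over the group),
and the intergenic length: 29 in total, in a fixed canonical order.

Decisions where the definition was genuinely open:

* **relPosChr** = min(midpoint − 1, L − midpoint)/L ∈ [0, 0.5]: the
  normalized distance of the gene midpoint to the nearest chromosome end,
  capturing subtelomeric placement symmetrically.
* **Mode of a continuous sample**: midpoint of the most populated bin of
  a 10-bin histogram over [min, max], lowest bin on ties; equal to the
  value itself for constant or singleton samples. The choice is isolated
  in one function (`features.histogram_mode`).
* **GC fractions are pseudocounted** ((G+C+1)/(unambiguous+2)) so that
  GC-free or all-ambiguous references cannot produce zero denominators in
  the relative-GC ratios.
* **Dinucleotide frequencies** exclude positions containing `N` from both
  numerator and denominator; a window with no unambiguous dinucleotide
  position reports all 16 as 0.
* **Group statistics** use sample sd (n−1; 0 for n<2) and the moment
  skewness g1 = m3/m2^1.5 (0 for n<3 or zero variance). Groups are pooled
  across organisms over members with an extracted window; ungrouped genes
  form singletons (sd = skew = 0).

### Folding backend

The default backend is an internal Nussinov-style dynamic program
maximizing total pair weight (GC=3, AU=2, GU=1) over nested structures
with hairpin loops of at least 3 unpaired nt, returning minus the optimal
weight. It is not a thermodynamic nearest-neighbor model: its value is an
energy *proxy* in arbitrary units. Because all features are standardized
per organism downstream, the unit cancels and only the ordering of
sequences by pairing potential matters. The `external` backend shells out
to ViennaRNA's `RNAfold` and returns kcal/mol behind the same contract
(deterministic, ≤ 0). The internal DP is verified in the test suite
against exhaustive enumeration of all admissible structures for random
sequences of length ≤ 12.

## Preprocessing

Standardization is fitted per organism (sample sd, n−1) and persisted
with the model; prediction-time tables are rescaled with the training
parameters. Features constant within an organism standardize to 0 and are
logged; an organism contributing one gene is an error. Correlation pruning
runs one greedy pass over the pooled standardized matrix in canonical
feature order: for each pair (i < j) with |r| > 0.55 the later feature is
dropped — deterministic, auditable (every drop is recorded with the
partner and r), and idempotent. Pooled rather than per-organism
correlation is used because the retained set is a single global list.

## Balancing

SMOTE interpolates between a minority row and one of its k nearest
minority neighbors (Euclidean, on the standardized pruned features) with
u ~ U(0,1); the base row cycles over the minority set for even coverage.
The reference configuration targets 5,000 positives and 12,500 sampled
negatives (ratio 2.5:1, 17,500 rows). A requested k larger than the
available n−1 neighbors (the reference k=300 against 9 originals) is
clamped, and both requested and effective k are recorded in the manifest —
output counts, not the oversampling multipliers, are the contract.

## Classifier

`sklearn.svm.SVC` with a degree-2 polynomial kernel; class weights 2:1
(positive:negative). Model selection: repeated stratified 10-fold CV
(default 30 repeats) over an 8×4 grid of kernel scales
γ ∈ {2⁻⁹..2⁻²} and costs C ∈ {0.25, 1, 4, 16} (32 combinations), scored
by mean accuracy with mean kappa and grid order as tie-breaks.

Platt calibration is fitted by Newton's method with backtracking on the
regularized likelihood with smoothed targets t⁺ = (N⁺+1)/(N⁺+2),
t⁻ = 1/(N⁻+2), to gradient norm < 1e−8 (error on non-convergence after
200 iterations). The decision threshold is posterior 0.5.

**CV on the balanced set.** By default, cross-validation is performed on
the post-SMOTE balanced set. Synthetic positives interpolated from
originals that land in different folds leak information across the split,
so these CV scores are optimistic; they are retained as the default for
fidelity to the established protocol. `rebalance_within_folds=True`
balances inside each training fold and scores on untouched held-out
originals instead.

The empirical FDR is 100 × (positive calls on the negative-control
windows)/(positive calls on the UTR windows), both screens over the same
gene universe.

## Enrichment and ranking

One-sided (over-representation) Fisher exact tests via the hypergeometric
survival function; a two-sided test would not match the reported
direction of the analysis. BH correction defaults to the family of tested
groups (those with ≥ 1 positive call); `family="all"` enlarges the family
to every group with members in the universe. The universe is all genes
with an analyzable window.

The ranking score multiplies the *complement* of the posterior by the
group's BH-adjusted enrichment p: confident predictions in conserved
groups get the lowest scores, and "lower is better" is coherent.
Variants (posterior instead of complement; raw instead of adjusted p) are
exposed as flags. Genes without an enriched group use group p = 1; only
SVM-positive genes are ranked. Term enrichment is a flat gene→terms map
(no ontology DAG propagation or semantic summarization).

## Network analysis

Density = 2E/(n(n−1)) on the undirected simple graph. Interaction input
is a STRING-style TSV; edges below `min_score` (default 400) are dropped,
duplicates keep the max score, self-loops are removed. Edges are
unweighted in density and Louvain; the confidence score is only a load
threshold.

The null model samples m genes uniformly without replacement from the
full protein-coding gene list — genes absent from the interaction data
enter as isolated nodes and dilute density, which is the intended
behavior of sampling genes rather than network nodes. Default 10,000
replicates (configurable upward; the inference contract is independent of
the count). Replicates are Box-Cox transformed (λ by profile MLE via
`scipy.stats.boxcox`); zero densities are certain in sparse nulls, so a
shift c is applied first: c = 0 if min > 0, else −min plus half the
smallest positive excess (1e−6 fallback). The p-value is the upper-tail
normal probability of the transformed observation under the transformed
null's mean/sd. Calibration (approximate uniformity of p under the null)
is checked in the acceptance suite with a KS test; the normal
approximation requires the subgraph-density distribution to be reasonably
fine-grained, so the check uses sample sizes where the support is dense.

Louvain module detection uses `networkx.community.louvain_communities`
(resolution 1, seeded); modules are renumbered 1..k by decreasing size.
Size-1 modules have undefined density and are flagged excluded in the
module report, which otherwise gives per-module size, density, density p
at m = module size, and per-node degrees within the analyzed network.

## Synthetic study conditions

The generator emulates what the method assumes about real data:

* background composition A=T=0.30, G=C=0.20 (AT-rich fungal-like);
* positive upstream windows rewritten from A=0.45, T=0.25, G=C=0.15 —
  A-enrichment carries the compositional signal and the G/C depletion
  suppresses pairing so the folding proxy also separates classes;
* genes on both strands with random gaps (150–500 nt) and CDS lengths
  (300–1500 nt), orthologous groups assigned uniformly so they span
  organisms, positives concentrated in a small set of planted groups
  (default 5 of 400 at 80% within-group positive rate);
* 9 positives exposed as training labels regardless of the larger hidden
  truth — the order-10-positives regime.

Default size is 3 organisms × 2 chromosomes × 1,000 genes (6,000 genes,
~7 Mb), chosen so the complete end-to-end estimation runs in seconds on
one CPU; the end-to-end checks use a balanced set of 1,000/2,500 (ratio
kept at 2.5:1), while the reference 5,000/12,500 configuration is
exercised where it is cheap. What passing these tests shows is that the
estimation chain recovers a planted signal of realistic shape under the
stated imbalance; it does not show that real fungal IRESs are this
separable — the planted effect is stronger and cleaner than biology, the
generator has no codon structure, no introns, no shared ancestry within
groups beyond the label, and no correlation between network topology and
the planted groups.

## Known limitations

* The internal folding proxy ignores stacking thermodynamics; rankings
  can disagree with `RNAfold` for sequences of similar pairing content.
* CV-on-balanced-set scores overstate generalization (see above).
* BH-corrected group p-values depend on the family-size convention; both
  conventions are implemented and reported explicitly.
* With very few originals, SMOTE explores only the convex hull of the
  observed positives; the classifier cannot extrapolate beyond it.
* The network null treats the gene universe as exchangeable; degree-
  preserving nulls are out of scope.
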