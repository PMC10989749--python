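# Methods

`markerflow` re-implements a complete marker-gene (16S-style amplicon)
community-analysis workflow as a tested Python library with a thin CLI:
read classification, copy-number-corrected taxonomic profiles,
predicted gene-family (KO) and pathway profiles with NSTI, alpha/beta
diversity with permutation statistics, biomarker ranking, co-occurrence
networks, and a deterministic parallel orchestrator that renders a
static HTML viewer. This note records the models, the defaults that
matter, and the design choices made where the design was genuinely
open.

## Read classification

Reads are assigned to reference taxa by cosine similarity of k-mer
count vectors (default k = 8), computed for the read and its reverse
complement against each leaf's representative sequence; the best hit is
accepted when the similarity clears `min_identity` (default 0.97). This
is a deliberately simple, alignment-free matcher: it stands where a
production pipeline would run a full aligner such as vsearch, and an
import path for precomputed `read<TAB>leaf<TAB>identity` assignments is
provided so external aligners can be dropped in. Two consequences are
worth knowing:

- k-mer cosine is much stricter than alignment identity. One
  substitution in a 200 bp read destroys up to k of its ~193 k-mers, so
  a read with a single error scores ≈ 0.96 — below the 0.97 cutoff.
  At a 0.5% per-base error rate only ~37% of reads are classified.
  Classification is therefore precise rather than sensitive: among
  classified reads the correct-assignment rate exceeds 95% on 16-taxon
  references, and profiles built from the classified subset are
  unbiased because errors hit taxa independently of identity.
- Ties (identical best similarity) are resolved by splitting the read's
  count equally across the tied leaves, recording the deepest taxonomic
  rank they share. This keeps the taxonomy honest: the split count is
  exact at the shared rank and agnostic below it.

ASV denoising and chimera removal are exposed only as a no-op hook
(`denoise_reads`); they are upstream concerns of sequencing-error
modelling this package does not implement.

## Profiles and copy-number correction

Per-sample classified counts `c_i` are corrected by each taxon's marker
gene copy number `k_i` and normalised:

    a_i = (c_i / k_i) / Σ_j (c_j / k_j)

so abundances reflect organisms rather than gene copies. Correction is
scale-invariant in the counts, and setting all copy numbers to 1
recovers plain relative counts. Profiles collapse to any of the seven
ranks by summing leaves over their lineage prefix; a leaf whose label
at the target rank is empty pools into `Unclassified_<deepest
non-empty parent>`.

## Functional prediction and NSTI

A sample's KO profile is the linear push-through of its corrected taxon
weights `w_i = c_i / k_i` through the reference KO-content matrix,

    KO_k ∝ Σ_i w_i · n_ik ,

renormalised to sum 1 (`n_ik` = gene-count of KO k in taxon i; integer
counts, not presence/absence, so prediction magnitude is meaningful).
Pathway profiles aggregate KOs through a fixed three-level hierarchy;
a KO with several hierarchy paths splits its abundance equally across
them, and KOs absent from the hierarchy pool under `Unannotated`.

NSTI is the abundance-weighted mean of each taxon's distance to its
nearest sequenced relative, Σ_i a_i d_i. The weighted-mean form (rather
than an unweighted sum over taxa) is used because it is the definition
that makes the index comparable across samples with different richness;
a pure sample's NSTI equals its taxon's distance, and the index is
bounded by the largest reference distance.

## Alpha diversity

Shannon H = −Σ p_i ln p_i (natural log), Gini–Simpson D = 1 − Σ p_i²,
and bias-corrected Chao1 = S_obs + F1(F1−1)/(2(F2+1)). Chao1 demands
integer sampling counts and is computed from raw classified-read counts
(tie splits rounded), not from copy-number-corrected abundances — the
estimator reasons about singletons and doubletons of a sampling
process, which corrected abundances are not.

Associations with discrete metadata use the two-sided
Mann–Whitney/Wilcoxon rank-sum test (exact enumeration of all rank
splits when both groups have ≤ 8 samples, else the normal approximation
with tie and continuity correction) or Kruskal–Wallis for > 2 groups;
numeric metadata get an ordinary least-squares fit with the two-sided
t-test on the slope. Samples with missing values are dropped per test,
never globally.

## Beta diversity

The taxonomic distance is a phylogeny-aware mass-matching recursion on
the reference tree, run post-order: at each node the two samples'
incoming abundance masses are matched (the minimum is credited to
similarity S), and each residual climbs to the parent attenuated by
exp(−branch length); unmatched mass at the root is discarded and the
distance is 1 − S. Identical profiles give 0; profiles on disjoint,
infinitely distant clades give 1. The exponential attenuation and the
root-discard rule are this package's declared constants — the published
algorithm family it follows does not pin them down — and the test suite
asserts the properties (symmetry, range, identity of indiscernibles,
monotonicity in clade distance) rather than published constants. The
unweighted variant replaces abundances by 1/n over present taxa.

The functional distance runs the same recursion on the 4-level pathway
hierarchy (root → level-1 → level-2 → level-3 → KO) with a fixed
attenuation of 0.5 per edge, since hierarchy edges carry no lengths:
two KOs sharing a level-3 parent are at distance 0.5, two KOs sharing
only the root at 1 − 0.5⁴ = 0.9375.

PCoA is classical scaling (Gower-centred −½ J D² J, eigendecomposition,
coordinates scaled by √λ over positive eigenvalues); PCA is the SVD of
the column-centred table. Both fix axis signs by making the
largest-magnitude loading positive, and on Euclidean distance matrices
the two agree to numerical precision (classical-scaling duality, tested
to 1e-8).

PERMANOVA uses the standard pseudo-F partition of squared distances;
ANOSIM uses R = (mean between-group rank − mean within-group rank) /
(M/2), M = N(N−1)/2, with mid-ranks on ties. The Mantel-style numeric
association regresses pairwise distance on |Δx|. All permutation
p-values use the add-one convention (b+1)/(m+1) with 999 permutations
by default and an explicit seed; under exchangeable labels each test's
type-I error at α = 0.05 calibrates to the nominal rate (verified at
[0.03, 0.07] over 500 null cohorts).

## Biomarkers

Features are first screened by the rank-sum test (after a 10%
prevalence filter that stabilises rank statistics on sparse taxa) with
Benjamini–Hochberg correction at q ≤ 0.05, then ranked by a bagged
decision-tree ensemble (500 trees, √p features per split). Importance
is Breiman-style out-of-bag permutation importance — the mean decrease
in per-tree OOB accuracy when a feature is permuted — and the reported
model error is the ensemble OOB vote error. Numeric variables use a
Spearman screen with the same BH control, ranked by |ρ|.

The screen-then-rank order, the prevalence cutoff and the q-threshold
are this package's choices; the screen's per-feature type-I error and
the BH-kept fraction are both verified by null simulation.

## Co-occurrence networks

Edges join feature pairs with |Spearman ρ| ≥ 0.6 and BH q ≤ 0.05
(t-approximation p-values) after a 20% prevalence filter; constant
features are dropped before correlating (zero rank variance). Density
is 2E/(V(V−1)) over all nodes (isolated nodes retained); diameter and
radius are max/min BFS eccentricity on the largest connected component
(so they are finite); centralization is Freeman's degree centralization
Σ(d_max − d_i)/((V−1)(V−2)), 0 for V < 3. A path on 4 nodes gives
density 0.5, diameter 3, radius 2; a 4-node star has centralization 1;
a 4-cycle has 0.

## Synthetic data

The generator emulates a two-group 16S study at desk scale:

- **Reference pack**: random bifurcating tree by successive random pair
  joins, branch lengths ~ Exponential(mean 0.1); 7-rank taxonomy
  derived from tree clades (so sister leaves share low ranks); copy
  numbers ~ uniform integers 1–10; 30 KOs over a 2/4/8-label
  three-level hierarchy with Poisson(2) gene counts; NSTI distances ~
  Exponential(mean 0.03); 200 bp representative sequences evolved down
  the tree with per-site substitution probability 1 − exp(−branch
  length).
- **Cohort**: baseline proportions ~ symmetric Dirichlet(0.5) (sparse,
  a few dominant taxa — the familiar shape of real communities); group
  B multiplies effect taxa by their fold change and renormalises;
  counts ~ Multinomial. Default 20 samples per group at 500 reads per
  sample: large enough for stable rank tests, small enough that the
  full pipeline runs in seconds. The metadata's numeric covariate is
  independent by design so numeric-association nulls are testable.
- **Reads**: each read copies its taxon's representative with i.i.d.
  substitutions; files are written in the exact manifest/metadata
  dialects the readers parse, and read ids carry the true taxon for
  downstream accuracy checks.

What this does **not** emulate: chimeras, length variation, quality
scores, overdispersion beyond multinomial sampling, phylogenetically
correlated trait evolution of KO content, or realistic rRNA secondary
structure. Passing tests therefore certify the statistical machinery
and the pipeline plumbing, not performance on real sequencing data.

### Recovery experiment design

The planted-signal experiment puts a fold-change-8 effect on five
mid-abundance taxa (baseline ranks 6–10, read from a same-seed pilot
draw). Rare taxa make undetectable plants (nothing to recover at 500
reads/sample); planting in the dominant taxa is equally uninformative
because compositional closure then turns every unplanted taxon into a
mirror biomarker and importance spreads over dozens of
perfectly-separating features. With five exchangeable plants at one
common fold change no single plant is "strongest" by design, so the
headline check is that the best-ranked planted taxon sits in the
Random-Forest top 3 — the attribution question the experiment can
meaningfully pin down.

## Pipeline and determinism

Stages run as tasks on an acyclic dependency graph with dynamic
dispatch to a bounded thread pool: per-sample profiling and function
prediction parallelise at sample grain, pairwise distances at pair
grain, statistics at analysis grain. Every reduction iterates in
manifest order and every stochastic step derives its seed from the
pipeline seed plus a stable task name, so all result files are
byte-identical for any thread count and re-runs reproduce bit-for-bit.
A broken sample is quarantined (logged, dropped from downstream
stages); a failed stage cancels only its dependents. `logs/`,
`summary.txt` and `script.sh` record run provenance (timestamps, the
requested thread count) and are the only outputs allowed to differ
between otherwise identical runs.

Problem sizes throughout the test-suite and the acceptance script (16–50
taxa, 30–60 samples, a few hundred reads per sample, 199–999
permutations) are the package's chosen desk-scale study conditions.

## Known limitations

- The k-mer matcher is not an aligner: no gaps, no partial-window
  scoring, and recall drops steeply with read error (see above).
- Tree-distance attenuation constants are declared, not fitted; only
  their qualitative properties are contractual.
- Chao1 on tie-split (rounded) counts is approximate when many reads
  tie across references.
- The HTML viewer is static; interactive drill-down charts are out of
  scope.
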