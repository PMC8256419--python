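# Methods

## The problem

Quantitative phosphoproteomics measures thousands of phosphorylation sites,
but functional annotation (GO biological process terms, KEGG pathways) is
attached to *genes*, not to sites. Two sites on the same protein can be
regulated in opposite directions and serve different functions; gene-centric
enrichment cannot see this. This package associates *regulation clusters* of
phosphosites with candidate functions by diffusing a random walker over a
three-layer heterogeneous network and ranking function terms by their
steady-state visiting probability.

## Network model

Nodes come in three layers — sites R, proteins P, function terms F — and the
network is the symmetric binary block matrix

    A = | A_RR  A_RP  0    |
        | A_PR  A_PP  A_PF |
        | 0     A_FP  A_FF |

- **A_RR** connects sites in the same regulation cluster whose quantitative
  profiles have squared Pearson correlation r² ≥ 0.99 (inclusive; a flag
  switches to plain r). Cluster co-membership is required, so the site layer
  encodes the clustering.
- **A_PP** is the interaction subgraph induced on the phosphorylated
  proteins plus their direct interactors, from a STRING-style edge list
  filtered at channel score > 0.4 (strict). Edges among included
  interactors are kept, preserving module structure; data proteins without
  interactions stay as isolated nodes.
- **A_RP** links each site to its single host protein (one edge per site).
- **A_PF** is built in two steps: Louvain modules of the protein layer are
  tested for term enrichment (upper-tail hypergeometric, BH within module,
  q < 0.05), and each retained term is linked to the module proteins
  actually annotated to it (a flag switches to the all-members variant).
  In GO mode, terms annotated (after child→ancestor propagation) to more
  than 5% of universe genes are dropped as over-broad, and of any pair with
  Wang similarity > 0.9 the higher-frequency term is dropped as redundant.
- **A_FF** connects terms with pairwise similarity strictly > 0.7 — Wang
  semantic similarity on the ontology in GO mode (is_a factor 0.8, part_of
  0.6, only these relations traversed), or the overlap coefficient
  |A∩B|/min(|A|,|B|) of annotation gene sets in KEGG mode (Jaccard
  available).

## Random walk with restart

The transition matrix M allocates, per node, probability mass λ to
cross-layer moves and 1−λ to intra-layer moves, each uniform over the
corresponding neighbors. Protein nodes adjacent to both the site and the
function layer split the cross-layer mass λ/2 per side (a degree-
proportional split is available). A node missing one kind of edge
reallocates that mass to the other kind; fully isolated nodes keep all-zero
rows. Every row with at least one edge sums to 1 within 1e-12.

The walk iterates

    p_{s+1} = (1 − r) Mᵀ p_s + r p_0

to an L1 fixed point (tolerance 1e-10, cap 10 000 iterations; with r = 0.7
convergence takes ~20 iterations since the residual contracts by 1−r per
step). The initial vector p_0 places mass 1 uniformly on the seed sites
(the sites of one regulation cluster), η_P uniformly on proteins and η_F on
functions, then normalizes; non-seed sites start at exactly 0. Defaults
λ = 0.7, r = 0.7, η_P = 0.7, η_F = 0.3. Since the iteration is linear in
p_0, the 1/(1+η_P+η_F) normalization cannot change any ranking.

Per seed cluster, function nodes are ranked by steady-state probability
(ties broken lexicographically by term ID; integer ranks). Terms ranked at
the same integer position for *every* cluster carry no cluster-specific
signal and are removed (skipped when only one cluster exists); the top
⌈top_fraction × n_remaining⌉ terms are retained, top_fraction = 0.05 by
default (0.01/0.10/0.15 are the standard alternatives).

## Preprocessing

Input ratio tables are filtered to *regulated* sites: at most one missing
ratio and at least one ratio strictly above 2 or strictly below 0.5.
Remaining missing values are treated as left-censored: per condition, a
normal distribution is fitted to the observed log2 ratios and draws are
taken from its truncation above the 0.01 quantile of those observed values,
then back-transformed. Observed cells are never altered. Optional quantile
normalization forces all condition columns onto the common rank-mean
distribution. Profiles are clustered with fuzzy C-means (fuzzifier 2.0,
tolerance 1e-6, max 1000 iterations, hard label = argmax membership) or
k-means (25 restarts); the cluster number can be chosen by mean silhouette
width or by the elbow rule, formalized as the k maximizing the second
difference of the within-cluster sum of squares.

## Permutation significance

The control asks whether a term's standing for a given seed cluster could
arise from topology alone. Each permutation draws an independent node-label
permutation per layer and applies it consistently to the intra-layer and
bipartite blocks: the permuted network is isomorphic to the original (all
subnetworks and bipartite edges maintained, degree multisets preserved),
but which sites seed a cluster — and which term occupies which position —
is random. A label-shuffle that left the bipartite blocks *positionally*
fixed was evaluated and rejected: it preserves the seed → host-protein →
term path, every permuted network reproduces the observed top ranks, and
the control has no power.

The add-one empirical p for a (cluster, term) pair is

    p = (1 + #{permutations with null probability ≥ observed}) / (n_perm + 1)

computed on the *continuous* steady-state probability rather than on the
integer rank. Within any single network the two order terms identically,
but across networks integer ranks collide whenever the function layer is
small relative to n_perm, which makes a rank-count p conservative (measured
false-flag rate ~0.3% at nominal 5% on random networks) and bounds it below
by (1 + n_perm/|F|)/(n_perm + 1). The probability statistic is tie-free and
exactly uniform under the exchangeable null (measured 4.4–6.1% at nominal
4.95% across seeds). Null *ranks* are still recorded per term, with a
Gaussian KDE (Silverman bandwidth) available for reporting. BH-adjusted
q-values across terms within each cluster are reported; note that under a
label-exchangeable null the bulk of empirical p-values is uniform by
construction, so the smallest attainable q is about |F|/(n_perm+1) — the
add-one p is the primary significance measure. When observed ranks exist
for two or more clusters a two-sided Mann–Whitney U of the observed ranks
against the pooled null ranks is additionally reported per term (a single
observed rank against n_perm nulls is degenerate, hence the restriction).

## ORA baseline

Per cluster, the host proteins are tested against the annotation library
with the same upper-tail hypergeometric core, BH across all tested terms,
keeping q < 0.05. This is the gene-centric comparison point: it sees
protein lists, not regulation patterns.

## Synthetic studies and what they show

`generate_planted_study` emulates a SILAC time-course experiment with known
ground truth: each cluster follows one of five temporal archetypes (early
transient, sustained, late, decreasing, cycling; fixed Gaussian/exponential
shapes of amplitude ±2 on the log2 scale over 8 time points) plus Gaussian
noise (default SD 0.25 log2 units); 10% of sites get one left-censored
missing cell. Each cluster's 30 sites sit on 15 dedicated host proteins
forming a near-clique (edge probability 0.95) interaction module annotated
to that cluster's distinctive term. 350 background proteins are wired as
direct interactors of the phosphoproteins — as a STRING first-neighborhood
pull would be — and host 12 dense decoy modules of 8 proteins, each
annotated to a decoy term; decoy terms sit in sibling pairs at ontology
depth 4 so some pairs clear the 0.7 function-similarity threshold. Module
internal degree (~13) deliberately dominates the per-host tether load
(~7.8): if the two are comparable, modularity optimization resolves
star-shaped satellite communities instead of the planted modules and the
ground truth is not recoverable even in principle. Planted annotation
frequency (15/395 ≈ 3.8%) stays below the 5% broad-term cutoff.

`generate_validation_like_dataset` mirrors the shape of a canonical
MAPK/ERK-style benchmark: 19 sites on 8 proteins in 5 archetype clusters.
`random_multilayer` produces structureless networks whose distribution is
invariant under within-layer relabeling — the exchangeable null used for
calibration checks.

What passing tests show: the solver is correct (matches the direct linear
solve to 1e-8), the construction rules are implemented as specified, the
planted cluster→function signal is recovered and detected by the
permutation control, and the null calibration is exact. What they do not
show: performance on real data with peptide-level ambiguity, incomplete
and biased interaction/annotation databases, correlated noise across
conditions, or clusters without dense module support — none of which the
generator emulates.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (3 clusters × 30 sites,
  ~400-protein layer, 15-term function layer; 50 recovery runs; 10–20
  permutation repeats at n_perm = 100) were chosen to make every stochastic
  property measurable with comfortable margins at desk scale.
- One global seed derives all stage seeds via SHA-256 of "seed:stage", so
  any stage is reproducible in isolation and two runs with the same config
  are byte-identical.
- Louvain module numbering is canonicalized by each module's smallest
  member; cluster labels are renumbered by first appearance; ranking ties
  break lexicographically — all to keep outputs order-independent.
- The weighted ranking comparison is the symmetric hyperbolically weighted
  Kendall tau (additive pair weight 1/r_i + 1/r_j on 1-based ranks,
  averaged over both rankings), computed by explicit pair enumeration and
  cross-checked against an independent implementation in the tests.
- Degenerate inputs: empty filtered tables are legal; constant profiles
  correlate with nothing (warned, no edges); a cluster with no sites in the
  network is an error; isolated nodes keep zero transition rows and simply
  absorb no mass.

## Known limitations

- Binary edges only: interaction confidence and membership strength are
  thresholded away, as in the original design.
- The λ/2 cross-layer split for proteins is one of several defensible
  three-layer generalizations (degree-proportional is provided); published
  variants may differ in degree-zero fallbacks.
- KEGG mode lacks the frequency/redundancy filter (no DAG).
- The permutation control's BH q-values are structurally conservative (see
  above); use the add-one empirical p for detection decisions.
- No identifier mapping is bundled; quant, PPI and GMT inputs must share a
  namespace.
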