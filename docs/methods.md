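# Methods

## Model

The input is a curated set of chemical–protein associations: rows of the
form (chemical, protein, interaction phrase, negation flag).  All
non-negated interaction kinds (expression changes, binding, agonism, …) are
treated identically; negated rows ("does not affect") are parsed but never
enter any index or downstream computation.  Duplicate (chemical, protein)
pairs collapse to one record; if duplicates disagree on negation the pair
is treated as negated, the conservative reading of contradictory curation.

Writing P(c) for the target set of chemical c, n_c = |P(c)|, and C(p) for
the chemical set of protein p, the protein–protein association network
(P-PAN) has an edge for every unordered protein pair sharing at least one
chemical, carrying two scores:

* **wscore** = Σ over shared chemicals of 1/n_c.  The weights are
  "inversely proportional" to the chemical's target count; the
  proportionality constant is 1, which only fixes the global scale — every
  ranking and every fraction-based threshold is invariant to it.  Chemicals
  with n_c = 1 create no pair and contribute nothing.  The score conserves
  mass exactly: a chemical with n_c targets spreads C(n_c, 2) · (1/n_c) =
  (n_c − 1)/2 units over its pairs, so Σ_edges wscore = Σ_{n_c ≥ 2}
  (n_c − 1)/2.  This identity is asserted on randomly generated worlds.

* **hscore** = −log₁₀ P(X ≥ k), X ~ Hypergeom(N, K, n) with N the number of
  distinct chemicals in the filtered table (configurable), K = |C(p₁)|,
  n = |C(p₂)|, k the shared count.  The test asks whether two proteins
  share more chemicals than expected given how chemically active each is;
  it is symmetric in the pair.  When the tail underflows to zero the score
  is capped at −log₁₀ of the smallest positive double (≈ 323.3) and the cap
  is logged.

Both tails are computed with `scipy.stats.hypergeom.sf`; the test suite
checks them against exact rational-arithmetic enumeration for every margin
configuration with N ≤ 12 (tolerance 1e-12).

## Calibration and the high-confidence network

Edges are ranked by a score (wscore by default) and, for each fraction f of
the ranking, the top ⌈f·|E|⌉ edges are intersected with a reference
protein–protein interaction set.  Ties at the boundary score are always
included — deterministic, and it makes the top-f networks nested in f.  We
report overlap counts, the percentage of the full reference, and the
percentage of the *recoverable* reference (edges whose endpoints both occur
in the network), since the two denominators answer different questions.

The no-signal baseline permutes node labels uniformly: topology, degree
multiset and score multiset are untouched, only identities move.  Under a
uniform relabeling each specific pair of network proteins is an edge with
probability exactly |E|/C(P, 2), so the expected baseline overlap is
|ref ∩ P²| · |E| / C(P, 2); the observed mean over 50 permutations is
required to sit within three binomial standard errors of it.  The baseline
curve reported alongside a calibration curve is the mean over a configurable
number of permutations (default 10 in the pipeline, 50 in the acceptance
checks).

The default operating point keeps the top 8 % of edges by wscore, with
5 %, 12.5 % and 17 % exposed as presets for robustness scans.  Proteins
left without a retained edge are dropped.

## Markov clustering

MCL is implemented directly on the wscore-weighted adjacency matrix
(dense float64; the intended scale is 10²–10⁴ proteins):

1. add self-loops — per node, its maximum incident edge weight (a common
   stabilisation of attractors; constant value configurable);
2. column-normalise to a stochastic matrix;
3. iterate: raise to the matrix power e (expansion, default 2), raise
   elementwise to r (inflation, default 2.0), renormalise, zero entries
   below the prune threshold (default 1e-5), renormalise again (a column
   emptied by pruning gets its self-loop restored);
4. stop when the largest entry change drops below 1e-6 or after 200
   iterations (non-convergence returns the last iterate with a warning
   flag and `converged=False`).

Column stochasticity is asserted at every step (1e-9).  Clusters are read
from attractor rows (positive diagonal mass); attractor supports that share
nodes are merged by union–find, and any node outside every support becomes
a singleton, so the output is always a strict partition.  Expansion and
inflation cannot move probability across disconnected components, so
components are never merged.  Clusters below `min_size` (default 5) are
moved to an unassigned pool.  The granularity setting of the original mcl
binary ("scheme 7") has no portable definition; inflation is the
corresponding exposed knob here.

The cluster-level network connects every cluster pair joined by at least
one inter-cluster edge, weighted by the arithmetic mean of those edges'
wscores.

## Enrichment and chemical–disease mining

For a cluster of n annotatable proteins in a background of N, a term with K
annotated background proteins and k annotated cluster members gets the
upper-tail hypergeometric p-value P(X ≥ k).  By default the universe is
restricted to proteins carrying at least one annotation of the tested kind
(in both N and n): proteins that could never be counted for any term should
not dilute the test.  The full-background variant is available.

Bonferroni correction multiplies by m, the number of terms tested in that
cluster (terms with ≥ 1 annotated cluster member), capped at 1; the family
is per-cluster because reporting is per-cluster.  Significance is called at
corrected p ≤ 0.05.  GO annotations are pre-filtered to experimentally
supported or traceable evidence codes {IDA, IMP, IPI, IGI, TAS}; disease
annotations to a minimum confidence score of 60 (inclusive — a "minimum of
60" passes 60 itself).  No ontology up-propagation is performed: terms are
flat labels.

Chemical mining treats each chemical's target set as a term, with the
high-confidence network proteins as background and the full cluster as n;
chemicals with no target in the cluster are excluded (k = 0 carries no
information).  For every reported chemical and every disease present in the
cluster, the overlap table counts the disease-annotated cluster members the
chemical targets — the association is undirected, so whether the chemical
causes or protects against the disease is left to interpretation.

The disease-score cutoff itself can be calibrated against a second,
unscored annotation source: sweeping a cutoff over the scored source, the
count of shared (protein, disease) pairs stays flat while only unshared
noise is removed and drops once genuine annotations are cut.  The suggested
cutoff is the first grid point whose one-step overlap loss exceeds an elbow
criterion (default 5 % of all shared pairs).

## Neighbor-protein target prediction

Given a chemical's known targets present in the network (the input set):

1. the inputs and their mutual edges form the seed;
2. each first-order neighbour is kept when its **inclusion ratio** — the
   fraction of its network edges touching the input set — is ≥ 0.1
   (inclusive by default; a strict-comparison flag is provided);
3. all network edges among retained proteins are added.

Every sub-network protein v is then scored with the statistic t(v) = summed
wscore of v's edges into the input set, against a null of R random input
sets of the same cardinality drawn uniformly from the network's proteins
(R = 10⁴ by default; degree-proportional sampling is available as a guard
against hub bias).  Then:

* **cpscore(v)** = (t_obs(v) − mean_null(v)) / sd_null(v), a z-score; NaN
  and ranked last when the null is degenerate (sd 0);
* **empirical p(v)** = (1 + #{null ≥ obs}) / (R′ + 1), with a pseudocount
  so the smallest attainable p is 1/(R + 1);
* **cscore** = the same z-score construction applied to Σ t(v) over the
  non-input sub-network members, with its own empirical p.

One statistical subtlety: a candidate protein is never a member of its own
input set, but an unconditional null sometimes draws sets containing it,
and such sets have one fewer potential neighbour — a small systematic
downward bias of the null.  Each protein's null is therefore conditioned on
the draws that do not contain it (R′ ≤ R of them).  With this conditioning,
querying the scorer with a random input set yields exactly uniform
empirical p-values for a randomly chosen candidate, which the acceptance
checks verify with a Kolmogorov–Smirnov test.  On sparse networks the
statistic has an atom at zero (candidates with no edge to any input), which
makes p-values conservative rather than uniform; the uniformity check is
therefore run on the dense unthresholded projection.

`score_complex(None, …)` scans the entire network instead of a pull-down —
the right candidate set for unbiased evaluation, since restricting to
pulled-down neighbours conditions on connectivity to the observed inputs.

Predictions are evaluated as recall = |pred ∩ ref|/|ref| and precision =
|pred ∩ ref|/|pred| against an independent chemical–protein catalogue;
precision is reported as undefined when nothing was predicted.

## Synthetic worlds

The generator emulates the statistical structure the method assumes, not
any particular database snapshot:

* M = 6 modules of m = 20 proteins (the intended working scale for tests);
* q = 8 module chemicals per module, each hitting its module's proteins
  independently with probability h = 0.5 plus Poisson(ρ·m) out-of-module
  targets at ρ = 0.02 — dense within-module shared-chemical structure with
  a little leakage;
* b = 10 promiscuous background chemicals with 60 uniform targets each —
  these blanket the network with weak pairs (n_c = 60 caps any
  background-only edge at wscore b/60) and exercise exactly the case the
  1/n_c weighting exists to suppress;
* disease labels = module identity at 90 % coverage with 5 % flipped to a
  random other module, scores uniform on [60, 100], plus sub-cutoff noise
  entries the score filter must remove; GO-like labels analogous, with
  electronically-inferred (IEA) noise entries the evidence filter must
  remove;
* a reference interactome containing each within-module pair with
  probability 0.3 and each other pair with probability 0.005 — high enough
  signal to calibrate against, far from a clean answer key;
* 5 % spurious negated rows on non-target pairs.

Everything is drawn from named distributions under one seeded generator;
identical seeds give byte-identical worlds.  What the generator does *not*
emulate: heavy-tailed target-count distributions of real chemicals,
overlapping protein complexes (modules are disjoint), correlated curation
errors, and dose dependence.  Passing tests therefore demonstrate that the
machinery recovers the structure it is designed for, not that any
particular real-world association is correct.

## Evaluation designs and problem sizes

* Conservation identity: 100 random worlds with dimensions drawn from
  modest ranges (2–5 modules of 4–10 proteins), absolute tolerance 1e-9.
* Projection: exact comparison against an O(P²) double loop on worlds of
  ≤ 50 proteins.
* Module recovery: 20 default worlds, projected, thresholded at 8 %,
  clustered at inflation 2.0; adjusted Rand index computed between the
  cluster partition and the planted modules over the proteins assigned to
  clusters (thresholding legitimately drops weakly connected proteins, and
  the unassigned pool is not a cluster claim).  Success is ARI ≥ 0.9;
  18 of 20 worlds must succeed.
* Enrichment null: 200 random-annotation trials (100-protein background,
  one 20-protein cluster, 30 terms annotated independently at 10 %); the
  fraction of trials with any Bonferroni-significant term must stay ≤ 0.05.
  Discreteness of the hypergeometric makes the realised rate far lower.
* Mining recovery: per world, every planted disease must see one of its own
  module's chemicals ranked first in its best-enriched cluster; 18 of 20
  worlds.
* Held-out target recovery: in one default world, every module chemical
  with ≥ 5 targets (typically ~48 of them) has 30 % of its targets held
  out; cpscores over all non-input network proteins are pooled across the
  queries and a single AUROC (held-out vs non-target) is computed at
  R = 1000.  A single-chemical AUROC with 3–4 positives has a sampling
  standard error of several points; pooling measures the same recovery
  property with adequate n.  The intrinsic ceiling is below 1: after a
  chemical's own pairs are removed, its held-out targets are statistically
  exchangeable with the other members of its module, so the score can place
  the module at the top but cannot single them out within it.
* Null p-value honesty: 100 independent random-input queries against the
  dense projection, one randomly chosen candidate p-value per query
  (p-values within one query share the null draws and are correlated;
  one-per-query restores the independence a KS test assumes).
* Determinism: the full pipeline (synthetic world, calibration with 5
  permutations, clustering, enrichment, mining, one prediction at R = 300)
  rerun into a fresh directory must reproduce every file byte for byte.

## Known limitations

* The dense-matrix MCL is O(n³) per iteration; beyond ~5 000 proteins a
  sparse implementation would be needed.
* cpscore/cscore are z-scores against a uniform random-set null; degree
  structure is only addressed by the optional degree-matched sampler.
* Bonferroni is deliberately conservative; with thousands of terms per
  cluster a false-discovery-rate procedure would retain more power.
* The hypergeometric universe N (distinct chemicals in the table) is a
  modelling choice; other universes (e.g. all catalogued chemicals) rescale
  hscores and are supported through the `universe_size` argument.
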