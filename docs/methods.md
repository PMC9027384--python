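# Methods

## Input model

The analysis operates on a gene × time matrix of log2 fold changes relative
to a pre-perturbation reference; time zero is the perturbation and sampling
times are decimal hours. Validation requires unique gene identifiers,
strictly increasing times and complete profiles (genes with missing values
are dropped with a warning by default, because both the clustering and the
per-timepoint t-tests assume complete profiles; a strict `error` policy is
available). No re-referencing or array normalisation is performed — those
belong upstream of this package.

Regulatory background knowledge is a table of (regulator, sigma factor,
target gene, effect) interactions in the style of a RegulonDB export.
Composite regulators (e.g. FlhDC) are kept verbatim; an optional alias map
can merge naming variants such as CRP/CRP-cAMP (off by default — we do not
second-guess the input nomenclature). A gene's *regulatory signature* is its
set of (TF, SF, mode) combinations; activation and repression by the same
TF/SF pair are distinct units throughout.

## Differential expression and scaling

A gene is differentially expressed when max over time of |log2FC| ≥ 1.5 —
the comparison is inclusive, so a profile that exactly reaches the threshold
counts. Before clustering, each DEG profile is divided by its own maximum
absolute value. This unit max-abs scaling preserves signs and the position
of the extremum while removing amplitude, so clusters reflect the *shape*
of the response; it is idempotent and configurable (z-scoring would also
remove the baseline level, which for ratio data is already the reference —
max-abs is the milder and default choice).

## Constrained k-means and model selection

Clustering is COP-kmeans: Lloyd's algorithm in Euclidean space where
must-link pairs are first closed transitively into blocks, and each block is
assigned as a unit to the centroid nearest its member mean. With must-links
only the problem is always feasible; cannot-links are supported via greedy
feasible assignment with seeded re-initialisations and a hard error if they
cannot be satisfied.

Must-links are derived from the background knowledge as follows: DEGs whose
signatures are identical *and non-empty* are linked in a spanning chain in
gene-id order (a group of m genes contributes m − 1 links, keeping the
constraint count linear). Genes without known regulation carry no evidence
of co-regulation and generate no constraints. This is the package's own
construction — background-knowledge clustering literature specifies how
constraints are *used*, not how regulon tables become constraints — and it
is deliberately conservative: only exact agreement of the full signature
links genes. A `max_pairs` cap adds groups smallest-first, so the largest
groups are the ones truncated if the cap binds.

Initialisation is k-means++ with the best of `n_init = 10` runs by
within-cluster sum of squares (plain random seeding is available as a flag,
but it reliably lands in poor local optima on profile data: in our
experiments its mean silhouette at the true k was 0.37 against 0.76 for the
true partition, which makes the k selection below collapse onto the trivial
down/up bipartition). Empty clusters are re-seeded from the block farthest
from its centre, deterministically.

The cluster number is chosen by running `repeats_per_k` seeded restarts for
every k in `k_range` (default 2–30, which brackets the cluster counts
reported for pulse-response compendia), recording mean ± sd of the mean
silhouette index, and taking the k with the largest mean; ties break toward
the smaller k (parsimony). The returned partition is the best-silhouette run
at the chosen k. The silhouette uses Euclidean distance with the standard
conventions: singleton-cluster points score 0, as do exact duplicates with
a = b = 0. It is computed in-package from an explicit pairwise-distance
matrix so the conventions are under our control and the value agrees with a
brute-force O(n²) recomputation to 1e−12.

Reported cluster labels are canonicalised by ascending mean scaled profile
over the first third of the time course, so down-regulated clusters come
first; this ordering is cosmetic.

## Over-representation analysis

For each cluster and unit (GO category or TF/SF combination) with at least
one member DEG in the cluster, the right-tail Fisher's exact p is the exact
hypergeometric upper tail — no normal approximation. Three counts
parameterise the test (cluster size among DEGs, unit members in the cluster,
unit size in the universe); the universe closes the table. The default
universe is the annotated genes (network ∪ GO) intersected with the matrix;
`universe="array"` forces all matrix genes. Only over-representation is
tested, because the scientific question is whether a unit is *enriched*.

Holm–Bonferroni correction is applied per stage: all GO tests form one
family, all TF/SF tests another. Tests with zero overlap are not emitted and
do not count toward the family size m (they carry p = 1 and can only make
the correction more conservative for everything else; m = number of emitted
tests is the documented convention here). A unit is *selected* in a cluster
when n_hit ≥ `min_genes` (default 9) and corrected p < `alpha_enrich`
(default 0.0025); combinations selected in at least one cluster form the
important set. GO-stage results export in the two-column term/p format that
the REVIGO web service accepts; the service itself is never called.

## Co-regulation levels

Each DEG is mapped to the intersection of its signature with the important
set; genes with an empty intersection are excluded, and genes sharing the
same exact subset form a group at level = |subset|. Groups keep their genes
even when too small to test (< 2 members), but are then marked untestable
and can never be decisive.

A group's direction is the sign of its mean log2FC over the whole time
course. The group Fisher test asks whether the group is enriched in DEGs
shifted in the group's own direction, over the full matrix universe — the
2×2 layout (group membership × direction-matched-DEG membership) is this
package's reconstruction of a "significant impact on controlled genes"
test and is documented as such. Degenerate margins give p = 1 with a
warning. Per sampling time, a pooled-variance two-sample t-test compares the
group's log2FC against all other genes of the matrix, one-sided in the
group's direction (down → lower tail, up → upper tail). Pooled rather than
Welch is the default reading of a plain "two sample t-test"; Welch is a
one-line change via scipy and deliberately not a second code path. Zero
pooled variance at a time point is flagged, carries p = NaN and is excluded
from the correction family.

Both p-value families — group Fisher tests, and all (group × time) t-tests
— are Holm-corrected *within each level*. A group is decisive iff its
corrected Fisher p and its best corrected timepoint p are both below
`alpha_level` (default 0.05). The heat-map export writes signed
−log10 p_adj, negative for down-regulated groups.

## Synthetic studies

The generator plants a complete ground truth: 7 differential-expression
archetypes (immediate-down-then-recover, immediate-down-persistent,
delayed-down-persistent, delayed-up-transient, delayed-up-persistent,
delayed-up-then-recover, immediate-up-persistent) plus one flat background
cluster; 1200 genes with 150 per archetype by default; 10 sampling times
from 0.5 to 25 h. Archetypes are anchor-value profiles linearly interpolated
onto the time grid — they mimic empirically observed pulse-response shapes
without asserting kinetics — with all anchors inside ±3 log2FC and peak
amplitudes of 2–2.5, comfortably above the 1.5 DEG threshold at the default
noise sd of 0.2. Noise is additive iid Gaussian on the log2 scale, the
standard error model for log-ratio data.

Six planted TF/SF combinations each control 18–40 genes concentrated in one
target cluster; 10% of each regulon "leaks" to background genes, modelling
regulon members that do not respond to the perturbation. Six planted GO
categories follow the same scheme. Twenty decoy combinations are small
(3-gene) regulons concentrated in one random cluster each: real regulons
produce co-expressed targets — that premise is exactly why regulon tables
are usable as must-link knowledge — so decoys are wired like miniature
regulons rather than as uniform cross-cluster noise, which would contradict
the method's own model and simply sabotage the constraints. Decoys stay far
below the 9-gene selection floor, so they probe the selection rule without
being selectable. All randomness derives from the truth seed through
separate streams for expression and network, making fixture files
byte-identical across runs.

What the generator does *not* emulate: probe-level intensities and dye
effects, gene-length or GC biases, correlated noise between neighbouring
time points, regulon overlap structure of a real genome-scale network, and
GO term nesting. Passing the recovery experiments therefore shows that the
pipeline's logic is correct under its own model assumptions, not that real
arrays will yield clusters this clean.

## Study conditions used by the recovery experiments

The planted-recovery experiments (tests and `scripts/acceptance.py`) search
k over 2–12 with 5 restarts per k — enough to bracket the 7 planted
clusters with headroom while keeping a full 20-repeat selection experiment
in the minutes range on one core. The wider search (k 2–30, 20 restarts)
remains the `Config` default for real data. The global-null
experiment for the level stage simulates iid N(0, 1) profiles: at the
default noise sd of 0.2 no gene ever crosses the DEG threshold and the null
would be vacuous, so the null uses unit variance to keep the DEG filter and
direction classification active.

## Numerical and degenerate-input conventions

- Fisher tails by exact summation (scipy hypergeometric survival function);
  count-invariant violations raise with the offending count named.
- Holm adjustment via the step-down running-maximum formula, capped at 1,
  returned in input order; p-values outside [0, 1] raise.
- Unit max-abs scaling of an all-zero profile raises (cannot scale).
- k = 1 clustering is allowed and trivial; silhouette for a single cluster
  raises (undefined).
- k exceeding the number of must-link blocks raises before iteration.
- All seeds derive from a single top-level seed through numpy SeedSequence
  spawning, so every stage is independently reproducible and recorded in the
  run manifest.

## Known limitations

- The constraint-derivation rule and the group-Fisher 2×2 layout are
  package design choices where the underlying methodology is commonly left
  unstated; both are isolated behind single functions and documented above.
- Silhouette-based selection is O(n²) per evaluation; for matrices beyond
  ~10⁴ DEGs a subsampled silhouette would be needed.
- The level analysis tests groups independently; cooperative effects between
  groups at different levels are displayed (heat-map rows) but not jointly
  modelled.
- GO annotation is taken as given — no ancestor propagation over the
  ontology graph.
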