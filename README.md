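# regclust

Regulation-aware constrained clustering and enrichment analysis of
time-course transcriptome responses.

When a steady-state microbial culture is hit with a sudden perturbation — the
canonical case being a glucose pulse on a carbon-limited chemostat — the
transcriptome reorganises over the following hours. `regclust` takes a gene
× time matrix of log2 fold changes (relative to the pre-perturbation
reference) together with transcription-factor/sigma-factor (TF/SF) regulatory
background knowledge, and answers three questions:

1. **Which response shapes exist?** Differentially expressed genes (DEGs,
   max over time of |log2FC| ≥ 1.5 by default) are scaled to unit maximum
   absolute value and partitioned by *constrained k-means*: genes with an
   identical, non-empty set of known (TF, SF, mode) regulators are chained
   with must-link constraints, so the background knowledge biases the
   partition toward co-regulated groups. The cluster number k is chosen by
   repeated computation of the mean silhouette index
   s(i) = (b(i) − a(i)) / max(a(i), b(i)) over a k range.
2. **Who controls each cluster?** For every cluster and every *unit* — a GO
   biological-process category or a (TF, SF, mode) combination — a one-sided
   Fisher's exact test scores over-representation: with N universe genes, K
   unit genes, a cluster of n DEGs and x of them in the unit,
   p = P(X ≥ x), X ~ Hypergeometric(N, K, n). Raw p-values are corrected
   per stage with Holm–Bonferroni; a unit is *selected* when it has ≥ 9
   member DEGs in a cluster at corrected p < 0.0025. Combinations selected
   anywhere form the *important* set.
3. **How do the important regulators cooperate over time?** DEGs are
   regrouped by the exact subset of important combinations controlling them;
   a subset of cardinality L sits at co-regulation *Level L*. Each group is
   scored by a direction-aware Fisher test (is the group enriched in DEGs
   shifted in its own direction?) and, per sampling time, by a one-sided
   pooled-variance two-sample t-test of the group versus all other genes,
   both Holm-corrected within each level. A group is *decisive* when both
   corrected p-values fall below 0.05. The per-timepoint results export as
   a signed −log10 p heat-map (negative = down-regulation).

A fully deterministic synthetic-study generator (planted profile archetypes,
planted regulons, planted GO categories, decoys, Gaussian noise) makes every
stage testable without any external download.

## Worked example

```python
import regclust as rc

truth = rc.make_truth()                        # synthetic study, seed 42
matrix = rc.simulate_expression(truth)         # 1200 genes x 10 time points
degs = rc.filter_degs(matrix, threshold=1.5)
scaled = rc.scale_profiles(matrix, degs)

interactions, go_map = rc.simulate_network(truth)
signatures = rc.build_signatures(interactions, matrix.gene_ids)
constraints = rc.derive_mustlinks(signatures, degs.gene_ids)

cfg = rc.Config(k_range=(2, 12), repeats_per_k=5, seed=1)
result = rc.select_k(scaled, constraints, cfg)

combo_index = rc.build_combination_index(signatures)
records = rc.enrich(result.assignments, combo_index, matrix.gene_ids, cfg)
important = rc.select_important(records)
groups, tests = rc.run_level_analysis(
    degs.gene_ids, important, signatures, matrix, cfg
)
```

Output of the run above:

```
1050 of 1200 genes differentially expressed
157 must-link constraints
selected k = 7, mean silhouette = 0.759
6 important TF/SF combinations:
   ArcA/RpoD(-)  CRP-cAMP/RpoD(+)  CRP-cAMP/RpoS(+)
   FNR/RpoD(-)   FlhDC/RpoF(+)     GadE/RpoS(+)
Level 1  CRP-cAMP/RpoD(+)  n=36  down  fisher_p_adj=1.12e-15  decisive=True
Level 1  CRP-cAMP/RpoS(+)  n=23  down  fisher_p_adj=5.57e-10  decisive=True
...
```

Reading: all 1050 genes carrying a planted response archetype pass the DEG
filter; the silhouette trace peaks at the 7 planted differential-expression
clusters; exactly the 6 planted regulator combinations are selected as
important (no decoy passes the ≥ 9 genes / p < 0.0025 rule); each Level-1
group is decisive — e.g. the 36 genes activated by CRP-cAMP/RpoD alone are
down-shifted far beyond what chance or the remaining genes allow.

The same analysis runs from the shell:

```sh
regclust simulate --outdir fixtures --seed 42
regclust run-all --expression fixtures/expression.tsv \
    --network fixtures/network.tsv --go fixtures/go.tsv \
    --universe array --k-min 2 --k-max 12 --repeats 5 --seed 1 --outdir out
```

`out/` then holds cluster assignments, the silhouette trace, both enrichment
tables, the REVIGO-ready GO export, level-group memberships, the
per-timepoint significance heat-map and a reproducibility manifest.

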