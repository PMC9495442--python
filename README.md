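# rhizofun

Analytics for rhizosphere abundant/rare microbial subcommunities and
their link to ecosystem multifunctionality, productivity and function
trade-offs.

Soil amplicon studies routinely discard the long tail of low-abundance
taxa, yet that "rare biosphere" may carry most of a community's
functional signal. `rhizofun` provides, as one tested pipeline, the
statistical machinery needed to ask which abundance fraction of a
rhizosphere microbiome best predicts system-level function:

* **Subcommunity partitioning** — locally abundant/rare OTUs by
  within-sample relative abundance (0.1% / 0.01% thresholds), regionally
  abundant/rare by mean abundance across samples (0.01% / 0.001%), plus
  richness/Shannon/Simpson diversity profiles per subcommunity.
* **Multifunctionality** — averaging-approach indices over z-scored
  functions: C/N/P-cycling multifunctionality (CCMF, NCMF, PCMF) and
  average ecosystem multifunctionality (AEMF); per-sample
  **trade-off intensity** d = |x − y| / √2, the distance of a
  standardized function pair from the 1:1 line, with a stability
  analysis over the number of aggregated pairs.
* **Group statistics** — normality/homoscedasticity-gated test choice
  (t/ANOVA vs rank tests), partial eta-squared from the two-way
  plant × system ANOVA, and ANOSIM with permutation p-values.
* **Co-occurrence networks** — per group and subcommunity level, edges
  where |Pearson r| > 0.8 and BH-adjusted p < 0.001, summarised as
  edges / vertices / positive edges.
* **Selection-effect screen** — the headline analysis: per
  (organism × level × feature kind × response) cell, features passing
  both a Spearman screen against the response and a Kruskal–Wallis
  screen across groups are intersected and the intersection is scored by
  a Mantel test (Spearman correlation of Euclidean distance matrices,
  one-sided permutation p). The Mantel r of significant cells ranks the
  subcommunities: the larger the r, the stronger the inferred selection
  effect.
* **Synthetic studies** — a generator with planted taxon–function
  associations (a shared latent driver, group effects, conditional
  blooms) so every stage is testable by parameter recovery without the
  original field data.

## Worked example

Simulate a study in which ten conditionally rare taxa (β = 1.5) drive
aboveground productivity, then ask the screen which subcommunity
carries the signal:

```python
import rhizofun as rf

study = rf.simulate_study(rf.recovery_scenario("locally_rare", seed=11))

mf = rf.multifunctionality_indices(study.functions)
print(mf.head(3).round(3))
#        CCMF   NCMF   PCMF   AEMF
# MZ_1 -0.819  0.156 -0.463 -0.274
# MZ_2  0.209  0.403  0.425  0.316
# MZ_3 -0.005 -0.253 -0.352 -0.315

res = rf.run_screen(
    {"bacteria": study.otu}, study.functions, study.design,
    responses=("ANPP",), anpp=study.anpp,
    n_permutations=999, seed=0,
)
print(res.top_cells["ANPP"])
# {'organism': 'bacteria', 'level': 'locally_rare', 'kind': 'species',
#  'mantel_r': 0.3633420374671408, 'mantel_p': 0.003}
```

The per-sample multifunctionality indices are unitless z-score means
(0 ≈ average sample). The screen's ranked table for this run reads:

```
           level      kind  n_intersection  mantel_r  mantel_p
    locally_rare   species               4  0.363342     0.003
 regionally_rare   species               2  0.337016     0.005
           whole   species               3  0.310264     0.005
```

i.e. the features selected from the locally rare subcommunity correlate
with productivity distances more strongly (Mantel r = 0.36, p = 0.003)
than any other subcommunity view — the planted truth recovered.

The same stages are available from a shell via the `rhizofun` CLI
(`simulate`, `partition`, `diversity`, `multifunc`, `tradeoff`,
`network`, `stats`, `screen`, `report`), each writing TSV tables and a
JSON summary to `--out-dir`.

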