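# cosegmap

Co-segregating markers and the inflation of high-density genetic maps in
doubled-haploid (DH) populations.

High-throughput SNP assays place far more markers on a linkage map than a
mapping population can resolve: in typical wheat DH maps around 85% of
markers show zero recombination with at least one other marker and stack
at a shared position (*co-segregating markers*, or bins). `cosegmap` is a
toolkit for studying what that excess does to a map. It

* simulates DH biparental genotype matrices with known truth (marker
  positions, co-segregation clusters, scoring errors, missing calls),
* builds linkage maps from scratch — pairwise recombination fractions,
  exact-binomial linkage grouping, minimum-spanning-tree + local-search
  marker ordering, Haldane/Kosambi distances, double-recombinant
  correction,
* constructs **skeleton maps** (one *delegate* marker per co-segregation
  cluster) and rebuilds *sequential maps* after adding co-segregating
  markers back, one at a time or in sampled proportions,
* quantifies the **inflation factor** of every rebuilt map and the
  collinearity of its marker order with the skeleton, and
* predicts inflation from the co-segregation proportion with a suite of
  regression learners (LR, GLM, POLY2/3, KNN, SVM, CART, RF) under 80/20
  holdout and 10-fold × 5 cross-validation.

It is aimed at people building or evaluating high-density linkage maps —
and at developers of mapping software who want a reproducible testbed for
the map-expansion artefact.

## The quantities at the core

For two markers in a DH population the recombination fraction is
estimated as the discordant-call fraction over lines observed at both
markers, `r̂ = n_discordant / n_informative`, and converted to map
distance with Haldane, `d = −50·ln(1 − 2r)`, or Kosambi,
`d = 25·ln((1+2r)/(1−2r))` (cM). Marker ordering minimizes the sum of
adjacent recombination fractions (SARF) — a travelling-salesman-type
objective — via a deterministic MST heuristic with 2-opt/Or-opt
refinement. Each rebuilt ("sequential") map is scored by its inflation
factor relative to the skeleton,

```
IF = ((L_seq − L_sket) / L_sket) · 100   [percent]
```

and by the absolute Spearman correlation of the shared markers' order.

The mechanism that makes IF positive is scoring error: a per-call miscall
rate ε makes two markers at the *same* locus discordant with probability
2ε(1−ε), which a mapping function converts into spurious length — about
2 cM per marker pair at ε = 1%.

## Worked example

Simulate two 60 cM linkage groups (13 loci each, 85% co-segregating
markers, n = 200 DH lines, 1% miscalls, 2% missing), build skeletons,
sample 10–80% of the co-segregating markers back (5 replicates per
level), and fit the learners:

```
cosegmap run-all --config example.yaml --out demo --log-level WARNING
```

with `example.yaml` produced by:

```python
from cosegmap import RunConfig, SimConfig, ExperimentDesign

pos = [5.0 * k for k in range(13)]
RunConfig(
    sim=SimConfig(n_lines=200, n_lg=2, lg_length_cM=60.0,
                  locus_positions=[pos, pos], coseg_proportion=0.85,
                  miscall_rate=0.01, missing_rate=0.02, seed=1),
    mapping_function="haldane",
    cluster_source="truth",     # clusters = true co-located markers
    correct_doubles=False,      # keep the raw error mechanism visible
    design=ExperimentDesign(levels=(10, 20, 30, 40, 50, 60, 70, 80),
                            replicates=5, master_seed=1),
    seed=1,
).to_yaml("example.yaml")
```

Output (abridged):

```
 proportion_pct  n_maps   mean_IF    sd_IF  mean_rho
           10.0      10 13.276868 4.750544  1.000000
           20.0      10 27.073182 4.535601  1.000000
           40.0      10 53.129861 4.953616  1.000000
           80.0      10 98.620459 8.135333  1.000000

model        design     rmse  accuracy
   LR holdout_80_20 7.917536  0.957842
  GLM holdout_80_20 7.917536  0.957842
  KNN holdout_80_20 8.316044  0.954503
   RF holdout_80_20 8.724981  0.948587
```

Reading it: every added co-located marker carries ~2 expected discordant
calls (n=200, ε=1%), i.e. ~2 cM of spurious Haldane length, so the mean
inflation factor climbs almost linearly with the proportion of
co-segregating markers added back — from ~13% at the 10% level to ~99% at
the 80% level — while the marker order stays essentially collinear with
the skeleton (mean |ρ| ≈ 1). All learners score within a few percent of
plain linear regression, the signature of an underlying linear
IF–proportion relation. (Real curated data show the same pattern at much
smaller amplitude, because most scoring errors are removed during
curation; see `docs/methods.md`.)

The `simulate`, `build-map`, `skeleton`, `expand`, `predict` and `report`
subcommands expose the individual stages; every run writes its resolved
configuration and a manifest next to its outputs, and all randomness
flows from the single master seed.

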