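# Methods

## Population and meiosis model

A doubled-haploid (DH) biparental population is fully homozygous; each
line carries one of the two parental alleles (A/B) at every locus, with
1:1 expected segregation. The simulator draws, per line and linkage group
(LG), one gamete: crossover count ~ Poisson(L/100) for an LG of true
length L cM, crossover positions uniform on the LG, starting parental
allele Bernoulli(1/2). There is no crossover interference, so the process
is exactly the model underlying the Haldane mapping function; this is the
simplest meiosis model consistent with converting recombination fractions
back to distances downstream. All markers assigned to a locus inherit
that locus's allele before noise.

Noise is applied per call, independently: a symmetric A↔B flip with
probability `miscall_rate` (ε), then masking to missing with probability
`missing_rate`. Both placements are recorded in the `TruthTable`, along
with each marker's true position and cluster, and the realized crossover
counts, so parameter recovery is testable against ground truth.

Locus placement defaults to "LG ends anchored, interior uniform", so the
outermost markers span the configured length and an error-free skeleton
estimates L itself. Explicit per-LG `locus_positions` override this when
controlled spacing matters. Co-segregation is configured as the fraction
of markers that are extra copies at existing loci; the realized marker
count per LG is `round(n_unique_loci / (1 − coseg_proportion))`, extras
assigned to loci uniformly at random.

### What the generator does and does not emulate

It reproduces the *structure* of a curated high-density DH data set —
tens-to-hundreds of markers per LG, ~85% co-segregation, 1:1 segregation,
<10% missing per marker — with errors that are independent and symmetric.
Real genotyping error is neither: it concentrates in poorly clustering
assays, correlates within markers, and coexists with segregation
distortion and heterozygous miscalls, none of which are modelled.
Passing tests therefore demonstrate the mechanics of map inflation and
the correctness of the pipeline's bookkeeping, not the magnitude of
inflation to be expected from any particular real data set. In
particular, simulated IF values at ε = 1% (tens of percent) are much
larger than published wheat values (4–17%), because in real studies most
scoring errors are removed during curation and correction; the residual
error rate of curated data is unknown and ε is deliberately left a free
parameter.

## Estimation and map construction

* **Recombination fraction.** `r̂ = discordant / informative` over lines
  non-missing at both markers; values above 0.5 are clamped to 0.5 (and
  kept raw in the record). Pairs with fewer than `min_informative = 20`
  shared lines are flagged uninformative and treated as unlinked — a
  variance-control cutoff.
* **Independence test.** Exact two-sided binomial tail of the discordant
  count under Binomial(n, 1/2). For the symmetric binomial this equals
  twice the smaller one-sided tail, capped at 1; it is deterministic and
  matches DH sampling exactly.
* **Grouping.** Edges join pairs with p < 1e-10 *and* map distance
  ≤ 15 cM; LGs are connected components. Singletons are reported as
  unplaced, never silently dropped.
* **Mapping functions.** Haldane and Kosambi; Kosambi is the package
  default (the convention of the mapping-software family this pipeline
  mirrors), Haldane is used wherever simulated truth is compared, since
  the simulator is interference-free. r is clamped at 0.4999 before
  conversion because Haldane diverges at 0.5.
* **Ordering.** Complete graph weighted by r̂ (uninformative pairs weigh
  0.5); deterministic Prim MST with ties broken by (weight, incident
  marker index, vertex index). If the MST is a Hamiltonian path it is
  returned directly — a spanning path that is an MST is the minimum-SARF
  path. Otherwise initial paths are taken by depth-first traversal from
  both endpoints of the weighted tree diameter plus greedy
  nearest-neighbour construction from the same endpoints, each refined by
  alternating first-improvement 2-opt (segment reversal) and Or-opt
  (relocation of segments of length ≤ 3) sweeps to a local optimum; the
  best SARF wins, with a lexicographic tie-break. The multi-start
  refinement exists because a single 2-opt descent measurably misses the
  exhaustive optimum on a few percent of small noisy instances; with it,
  the order matches brute force on 1,000/1,000 random ≤ 7-marker
  instances under study-like conditions. Orientation is canonical: the
  lexicographically smaller terminal marker comes first.
* **Ordering resolution limits.** Exact order recovery is bounded by the
  sample, not the algorithm: two markers 1 cM apart have a ~14% chance of
  zero sampled recombinants at n = 200 (any order ties), and even at 5 cM
  spacing ~2% of instances contain an adjacent swap whose SARF exactly
  equals the true order's. Order-recovery tests therefore assert recovery
  up to sample-indistinguishability (returned SARF ≤ true order's SARF,
  |Spearman| vs truth ≥ 0.999).
* **Map assembly.** Positions are cumulative sums of adjacent-pair
  distances, starting at 0; an uninformative adjacent pair is an error
  naming the pair.
* **Double-recombinant correction.** For each line, a non-terminal marker
  whose nearest non-missing flanks within 10 cM (each side) agree with
  each other but not with the focal call has its call replaced by the
  flanking genotype. One pass in map order; decisions are taken on the
  input calls and applied simultaneously, so the outcome is independent
  of scan direction. Terminal markers are never modified and missing
  calls never imputed. A genuine double crossover within a few cM is
  vanishingly rare in a DH line, so such calls are treated as scoring
  errors.

## Clusters, delegates, skeleton

A co-segregation cluster is a connected component of the "zero estimated
recombination" graph: pairs with no discordant calls among ≥ 20
pairwise-complete observations. Position, not byte-identity, is the
criterion, so markers differing only at missing calls cluster together.
The delegate of a cluster maximizes PIC (`1 − p² − q²` over non-missing
calls), then minimizes missing fraction, then is drawn uniformly at
random (seeded). The skeleton map orders and maps the delegates only;
its length `L_sket` is the reference for all inflation factors.
`n_coseg = markers − clusters` per LG.

**Cluster source for simulation studies.** With ε > 0 the strict r̂ = 0
rule cannot recover true co-location (two same-locus markers at ε = 1%,
n = 200 carry ~4 expected discordant calls) — which is precisely the
unlinking effect under study. Detection-based clustering is therefore the
default for loaded (real) data, where curation has already removed most
errors, while the inflation experiments on simulated data take their
clusters from the simulator's ground truth (`clusters_from_truth`),
keeping the delegate-selection rule on the observed calls. Running the
experiments on *corrected* + detected clusters instead inverts the
effect: the SARF-minimizing reorder routes through the least-noisy
cluster members and rebuilt maps come out slightly *shorter*, a pipeline
behaviour worth knowing but not the mechanism of interest. Cluster
membership is computed once per LG and never re-detected downstream.

## Inflation experiments

* **Sequential (one at a time).** A seeded permutation of the LG's
  non-delegate markers; for k = 1..n_coseg the map is fully re-ordered
  and rebuilt on delegates + first k markers — one record per k. Full
  re-ordering (rather than insertion into a frozen order) keeps every map
  the product of the same algorithm.
* **Sampled proportions.** Default design: levels 10–80% in steps of 10,
  50 replicates per level; LGs whose own co-segregation proportion is
  below the top level fall back to levels 10–60% with 20 replicates, and
  any remaining infeasible level is skipped with a log entry. The sample
  size at level p is round-half-up(p/100 × n_coseg), drawn without
  replacement. Rebuilt maps contain the delegates plus the sample only.
* **Scores.** `IF = ((L_seq − L_sket)/L_sket)·100`, kept as-is when
  negative; order collinearity is |Spearman| over the delegates' ranks in
  both maps (average ranks on ties; undefined below 3 shared markers).
* **Seeding.** Every record's RNG derives from
  (master seed, CRC32(lg id), level, replicate), so any single map is
  reproducible in isolation and reruns are bit-identical.
* **Summaries.** Mean, sample SD (ddof = 1) and count of IF per level,
  per LG × level, and per LG.

## Prediction

The sampled-proportion records form the learning set: x = proportion
level (percent, continuous), y = IF (percent), one row per map;
sequential-experiment records are excluded (their "proportion" is a
by-product of k, not a design level). IF, not raw length, is the
response: it is the scale-free quantity the experiments vary.

Learners (all scored on held-out data, sharing the same seeded
partitions): LR (OLS); GLM (Gaussian family, identity link, fitted by
IRLS — a distinct estimation route asserted in tests to agree with OLS to
1e-9); POLY2/POLY3 (OLS on polynomial expansions); KNN (Euclidean on
standardized x, neighbourhood size selected from {5, 9, 17, 33} by
internal 5-fold CV — the predictor is discrete with many tied neighbours
per level, so a fixed small k would average an arbitrary subset of the
ties and inflate RMSE); SVM (RBF support-vector regression, C = 1,
γ = "scale", ε-tube 0.1, on standardized x and y so the defaults are
scale-free); CART (regression tree, cost-complexity pruning α chosen by
internal 5-fold CV over the pruning path); RF (500 bootstrap trees).
Partition designs: a seeded 80/20 holdout, and 10-fold CV with 5
replicates scored per fold and averaged over the 50 fold-evaluations.
RMSE is in IF percentage points; accuracy is the Pearson correlation of
predicted vs observed held-out values (undefined and flagged when the
held-out response is constant).

## Numerical and design choices

* Segregation filter: 1-df χ² of the non-missing A/B counts against 1:1,
  default α = 0.05; monomorphic markers and markers with ≥ 10% missing
  calls are dropped; the per-marker disposition log makes curation losses
  auditable; an all-filtered matrix is reported with a warning, never
  silently returned.
* All tie-breaks (MST edges, delegate pools, 2-opt scan order) are
  deterministic by marker identifier or position index.
* Genotype files use the MST-mapping-tool text dialect (key-value header,
  one row per marker, calls A/B/U/-, case-insensitive); written files
  carry line identifiers in a comment so round-trips are exact. Maps,
  cluster reports, records and summaries are TSV.
* Test problem sizes: the zero-noise genome check uses 14 LGs of 7 loci
  (10 cM spacing, n = 177, ~47 markers/LG); monotonicity uses one LG of
  13 loci (5 cM spacing, n = 200, ε = 1%, levels 10–80 × 20 replicates);
  skeleton recovery uses 100 replicates of a 21-locus 100 cM LG; ordering
  optimality uses 1,000 simulated 4–7-marker instances against exhaustive
  enumeration. These sizes exercise every code path at per-LG marker
  counts in the tens — the same order as real skeleton maps — while the
  machinery itself has no size-specific behaviour.

## Known limitations

* The per-call error model is the textbook mechanism, not a calibrated
  error profile; simulated IF magnitudes exceed curated-data values (see
  above).
* Only DH (A/B/U) populations: no F2/outbred designs, no heterozygote
  calls, no segregation distortion, no sex-specific maps.
* Ordering is pairwise/heuristic, not multipoint maximum likelihood;
  within the resolution of the sample it matches exhaustive SARF
  minimization, but SARF itself is a surrogate objective.
* Double-recombinant correction runs exactly one pass; iterating it would
  progressively erase genuine tight double crossovers along with errors.
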