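# Methods

`pedlion` estimates the state of genetic diversity of a small captive
population from its studbook alone — no molecular data.  This note records
the models implemented, the conventions and defaults chosen where the
literature leaves room, and the known limits of what the synthetic tests
demonstrate.

## Pedigree model and conventions

A studbook row records an animal, its sire and dam, sex, birth date,
location and whether it belongs to the *reference population* (the living,
analysed subset).  Animals with both parents unrecorded are **founders**,
assumed mutually unrelated and non-inbred.  Two further conventions keep
every downstream quantity well defined:

* an animal with exactly one recorded parent receives a unique **phantom
  founder** in the empty slot (phantoms are never shared, so no spurious
  relatedness is created);
* a parent identifier that never occurs as a row is materialised as a
  founder record with a warning — it is a named, recorded ancestor, so it
  counts as *known* for completeness, whereas phantoms count as unknown.

Validation is permissive by default (sex-role conflicts and birth-date
reversals become warnings) because historical studbooks are known to be
internally inconsistent; strict mode upgrades them to errors.  Year-only
birth dates resolve to July 1, the midpoint convention.

## Completeness

Four per-animal measures: generations to the furthest known ancestor;
fully traced generations (all 2^g slots known); equivalent complete
generations `t = Σ (1/2)^n` over all known ancestors (per path); and the
pedigree completeness index at depth d, the harmonic mean
`PCI = 2·Cp·Cm/(Cp+Cm)` of the per-parental-line mean proportions of known
ancestors over generations 1..d.  Default depth d = 5, the horizon usually
reported for studbooks; the harmonic mean sends a fully unknown line to 0.
`PCI = 1` at depth d exactly when the pedigree is fully traced to d, a
property the tests exercise on random pedigrees.

## Relationship machinery

The numerator relationship matrix **A** is built by the tabular recursion
over a topological order (`a_xy = (a_sy + a_dy)/2`, `a_xx = 1 + a_sd/2`,
missing parents contributing zero).  Inbreeding is `F_i = a_ii − 1`,
co-ancestry (kinship) `c_ij = a_ij/2` — exactly the inbreeding of a
prospective offspring of i and j — and average relatedness
`AR_i = (1/2n) Σ_j a_ij` over the analysis set.  The test suite checks the
tabular values against an exhaustive Wright path-counting oracle (sum of
`(1/2)^(n1+n2+1)(1+F_A)` over node-disjoint ancestor path pairs) on
hundreds of random pedigrees; values are exact dyadic rationals computed in
double precision and rounded only for reporting.

## Rates of inbreeding and effective size

Two estimators of realised effective population size are provided, both
computed on the reference population:

* **individual increase in inbreeding**: `ΔF_i = 1 − (1 − F_i)^(1/(t_i − 1))`
  with `t_i` the equivalent complete generations; `N̄e = 1/(2·mean ΔF)`.
  Animals with `t ≤ 1` have no defined rate and are excluded from the mean
  (the count of animals used is reported — silent imputation would bias Ne);
* **pairwise increase in co-ancestry**:
  `Δc_jk = 1 − (1 − c_jk)^(2/(g_j + g_k))` over all unordered reference
  pairs, `N̄ec = 1/(2·mean Δc)`; pairs of founders (mean generation 0) are
  excluded.

The generation-mean rate `(F̄_t − F̄_{t−1})/(1 − F̄_{t−1})` is exposed
separately because published studbook analyses print one form or the other
without always saying which.  In idealised-population simulations
(constant N, random union of gametes, equal sex numbers) both estimators
recover N = 20 within a few percent of the replicate mean, and the realised
generation rate matches Wright's `1/(2N)`.

## Probability of gene origin

Founder contributions `q_k` come from gene-flow recursion (half of each
parent's vector), averaged over the reference; they sum to one by
construction.  Derived parameters:

* effective number of founders `fe = 1/Σ q_k²`;
* effective number of ancestors `fa = 1/Σ p_j²` with marginal contributions
  `p_j` from greedy selection: each round picks the ancestor (founder or
  not) explaining the largest share of the reference gene pool whose
  lineage avoids every previously selected ancestor; ties break by
  topological order for determinism.  `n50` is the number of leading
  ancestors jointly explaining half the pool.
* founder genome equivalents: deterministically `fg = 1/(2·f̄)` with `f̄`
  the mean co-ancestry over all reference pairs including self pairs
  (default), or by Monte-Carlo gene dropping, `fg = 1/Σ (q_j²/r_j)` with
  `r_j` the mean fraction of founder j's two unique alleles surviving in
  the reference (default 10,000 replicates, seeded, bit-reproducible).

Retained diversity `GD = 1 − 1/(2fg)` and `GD* = 1 − 1/(2fe)` partition the
loss into a founder-imbalance share (`1 − GD*`) and a drift/bottleneck
share (`GD* − GD`).

Two caveats, both verified empirically and deliberately left visible:

* the ordering `fa ≤ fe ≤ f` is guaranteed only for *proper* reference
  populations (no reference animal an ancestor of another, or the
  generation-structured references studbooks actually have).  On adversarial
  references containing an animal together with its own descendants the
  greedy first pick can self-credit enough weight to break the ordering;
  the package reports what the algorithm yields rather than clamping.
* the retention-based gene-drop `fg` and the co-ancestry `fg` are different
  statistics.  They coincide when every founder allele is retained
  (reference = founders) and for a single non-inbred reference animal; for
  inbred references the retention form tracks allele survival only, not
  frequency equalisation, and sits above the co-ancestry form.  Both are
  reported so the discrepancy is auditable.

## Generation intervals

Mean parental age at offspring birth (365.25-day years) along the four
pathways father–son, father–daughter, mother–son, mother–daughter, in two
modes: all offspring, or only offspring that themselves reproduced.  Pairs
with missing dates, unsexed offspring or negative ages are excluded and
counted, never imputed or clamped — validation owns the data errors.

## Subpopulation structure

Groups are holding locations (countries).  Mean pairwise co-ancestries
`f_ij` include self-co-ancestries `(1+F)/2` within groups, so singleton
groups are well defined.  Differentiation uses the Nei-minimum-distance
form on co-ancestries, `FST_ij = (f̄_within − f_ij)/(1 − f̄_within)` with
`f̄_within = (f_ii + f_jj)/2`, clamped to [0, 1]; the estimator name is
recorded in the output metadata since several pedigree FST variants exist.
The FST matrix feeds an average-linkage (UPGMA) dendrogram exported as
Newick (scipy hierarchical clustering; ultrametric node heights are half
the merge distances).  Individual substructure comes from the
eigen-decomposition of the double-centered relationship matrix — centering
the similarity rather than standardising columns, so that coordinates
(eigenvectors scaled by √eigenvalue) embed genetic distance and the
component variance fractions sum to one.

## Mating plans

Candidates are partitioned by average relatedness: AR < 4% (rare ancestry,
preferred breeders), 4–12.5% inclusive (usable supplements), > 12.5%
(over-represented).  Pair recommendation is a greedy minimum-kinship sweep
over male × female pairs with a kinship ceiling (default 0.0625, the
first-cousin level), at most one use per animal by default, and an
optional same-location preference; an exhaustive minimum-total-kinship
matcher is available for candidate sets up to 10×10.  The predicted
offspring F of a recommended pair is the pair's kinship, exactly.  The
greedy matcher is the default because no optimiser is prescribed by
practice and its decisions are transparent; tests confirm it reaches the
exhaustive optimum on small instances.

## Synthetic studbooks

The simulator breeds discrete generations from unrelated founders and
records ground truth (per-animal F from an internal relationship matrix,
exact founder contributions, per-generation mean F and realised Ne) before
any censoring.  Modes: an idealised population of constant size N with
uniform random parent choice and equal sex numbers (expected
ΔF = 1/(2N)); or demographic mode with monogamous couples per policy —
`random`, `full_sib_bias` (a quarter of the couples carry all litters,
inflating sibships and downstream inbreeding), or `min_kinship` (couples
paired by lowest current kinship).  Litter sizes are Poisson; birth dates
follow a generation clock with mean parental age 6.5 years (a realistic
large-felid value) plus Gaussian noise; locations are inherited from the
dam with a transfer probability.  Censoring deletes parent links
independently with a per-generation probability (indexed by the animal's
own generation), emulating the steep completeness decay of real studbooks;
one integer seed determines everything.

A study-shaped preset produces exactly 454 animals with a 98-animal
reference population over at most 7 ancestor generations, a dozen
locations, and reference-population completeness above 70% at generation 1
falling to near zero by generation 5.  It reproduces the *shape* of a real
studbook analysis — not any particular population's numbers, which depend
on an unpublished pedigree.

What the synthetic tests do not show: real studbooks have overlapping
generations, non-random mate choice across institutions, and correlated
(not independent-Bernoulli) record gaps; estimator behaviour under those
regimes is exercised only qualitatively by the preset.

## Problem sizes and numerics

Default analyses hold the full relationship matrix in memory (O(n²); a few
MB at studbook scale) and compute it once per report.  Gene dropping is
vectorised over replicates and chunked at 20,000 replicates per block.
Marginal-contribution selection stops when the best remaining contribution
falls below 1e−9.  Acceptance-style checks use 50 replicates of the N = 20
idealised population and the 454-animal preset, which keep the whole suite
in seconds on one core.
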