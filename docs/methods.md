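# Methods

## Phenotype calling

A growth assay is called from two endpoints: lactate concentration in the
spent medium and a pH-indicator colour change. POSITIVE requires lactate
> 10 mM *and* a colour change; lactate < 5 mM is NEGATIVE; everything else is
INDETERMINATE. OD600 drift is deliberately excluded from the call: small OD
increases (~0.2 units) occur without any carbohydrate degradation, so optical
density alone is not evidence of growth. INDETERMINATE is a first-class call
value even though well-behaved assays rarely produce it; downstream matrix
operations accept only binary panels, so indeterminate calls must be resolved
(or excluded) explicitly rather than silently coerced.

Percentages are integer round-half-up of `100·count/n`, computed in exact
integer arithmetic (`(200c + n) // (2n)`); this reproduces every printed
percentage of the packaged panel, including the half-way case 8/41 → 20 %.
Group means report both the raw and the half-up-rounded value; the rounded
value is the comparison surface because survey prose reports rounded means.

## The packaged panel and gene-state fixtures

The packaged `table1` fixture is a 41-strain × 18-sugar binary growth panel
with lineage labels (branch A: 29 strains, B: 11, C: 1). Negatives are stored
as blank cells, mirroring how such tables are printed (only the 1s are
marked); the parser treats blank as NEGATIVE. Per-sugar gene
functionality-state fixtures encode the four-state code ABSENT / PSEUDOGENE /
SINGULAR / INTACT. Cells that are not individually documented default to
INTACT (or ABSENT for strain-specific isoforms such as `araD1` and
`mfs9C23`), and every such assumption is listed in a sidecar
`*_stated.json` / `table1_assumed.json` file so the reconstruction is
auditable. Statistics computed from the panel's marginals (totals,
percentages, bins, group means) do not depend on the assumed cells.

## Functionality policy

Gene states map to a functional flag through a total policy with per-gene
overrides. The default treats only INTACT as functional. SINGULAR
(strain-specific protein variant) is non-functional by default — the
conservative reading, supported by cases like a PTS permease IIC-subunit
variant found exactly in the phenotype-negative strains — but real data are
not uniform (some singular variants lie outside the catalytic site and are
tolerated), hence the per-gene override mechanism rather than a global
constant.

## Gene-trait matching

For each (gene, sugar) pair the strains shared by the two matrices are
cross-classified into a 2×2 table. The primary statistic is the two-sided
Fisher exact test by the point-probability method: the p-value sums the
hypergeometric probabilities of all tables (with the observed margins) no
more probable than the observed one. It is computed in exact integer/rational
arithmetic, so tied tables are classified exactly and the only rounding is
the final float conversion; the test suite verifies agreement to 1e-12 with
an independent enumeration oracle over every table with n ≤ 30 and
cross-checks scipy. Tables with no variation (gene constant or phenotype
constant) are reported with p = 1 and a `degenerate` flag, never dropped.
FDR control is Benjamini–Hochberg within each sugar (via statsmodels), making
screens rankable without pretending the sugars are one family. A `perfect`
flag marks tables where functionality separates the phenotype exactly in
either direction.

### Lineage-aware permutation test

Lineages differ systematically in versatility, so any gene that tracks branch
membership correlates with many phenotypes spuriously. The guard shuffles
phenotype labels only within lineage groups (default: the panel's branch
labels) and recomputes |log odds ratio| (Haldane +0.5 for zero cells);
p = (1 + #{permuted ≥ observed}) / (1 + n_perm). A statistic explained purely
by between-group structure is invariant under these shuffles and gets p ≈ 1.
Groups with fewer than two strains cannot be shuffled and are left fixed.
The permutation p is discrete and therefore mildly conservative in small
panels (at ~40 strains the realized level at α = 0.05 is nearer 0.03);
calibration is verified at a 100-strain panel, where the empirical type-I
error over 1000 within-group-null simulations falls within 0.05 ± 0.02 at
199 permutations.

## Pathway logic

A pathway model is a monotone OR-of-AND rule over isoform groups:
`positive ⇔ ∨_routes ∧_groups ∨_genes functional(gene)`. An empty route list
predicts all-negative; a route with no groups is always satisfied. Evaluation
reports, per strain, the satisfied routes and — for each unsatisfied route —
the first blocking isoform group, which is the useful diagnostic when reading
discordances. Upgrading any gene state toward functional can never flip a
prediction positive→negative (monotonicity; property-tested).

### Rule inference

`infer_rules` enumerates every monotone DNF within explicit bounds
(`max_routes`, `max_groups_per_route`, `max_group_size`, plus the
always-false empty rule and the always-true empty route), scores each against
the observed phenotype column, and returns all rules achieving maximal
concordance, filtered to *minimal* ones. Minimality means every single
deletion — a route, an isoform group, or one gene occurrence — strictly
decreases training accuracy. Group deletion is included (not just literal and
route deletion) because it is the permissive direction of the lattice: without
it, a rule padded with an always-satisfied group would count as minimal, and
the all-positive panel would not have the always-true rule as its unique
minimal solution. Strain membership is bit-packed into Python integers, so a
rule evaluation is a few bitwise operations and a popcount; the search is
exhaustive and deterministic, guarded at 10⁷ rule evaluations. Equally
scoring minimal rules are all reported (ordered by literal count, then
lexicographically) — ambiguity is surfaced, never resolved silently. When the
best accuracy does not beat the majority class, the result carries a
`low_confidence` flag.

## Stoichiometry

Route vectors are yields in mol product per mol substrate over (lactate,
acetate, ethanol, mannitol, CO2). Registration checks carbon balance of every
vector against the substrate's six carbons to 1e-9 — the mannitol-sink
dismutation (3 fructose → 1 lactate + 1 acetate + 2 mannitol + 1 CO2, stored
per mol) closes exactly. Mixtures are convex combinations. Fitting minimizes
the Euclidean residual over the route simplex by grid search at resolution
0.001 (supported for ≤ 3 routes — exhaustive and deterministic at this size);
ties break toward the highest homolactic fraction. Unmeasured products are
masked out of the residual rather than assumed zero (HPLC setups often do not
quantify ethanol), CO2 is computed but never fitted, and "less than x"
readings are treated as upper bounds contributing residual only when the
prediction exceeds them. `classify_mode` labels a profile homolactic-dominant
iff lactate strictly exceeds acetate + ethanol + mannitol.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — a
clonal, tree-structured population in which functions are lost predominantly
by point disruption rather than gene loss:

- **Tree**: pure-birth Yule with rate 1.0 (time units arbitrary), default 60
  tips. The simplest model producing a clonal nested lineage structure.
- **Gene states**: each gene evolves independently down the tree under a
  continuous-time Markov chain on {ABSENT ⇄ INTACT → PSEUDOGENE → ABSENT}
  with default rates gain 0.3, loss 0.15, pseudogenization 0.35 and root
  distribution (A 0.05, I 0.95, P 0). With a Yule-60 tree (root-to-tip depth
  ≈ 3–4 time units) these rates leave each gene functional in roughly half
  the tips with strong phylogenetic correlation — variable enough to witness
  rule literals, clustered enough to exercise the lineage confounding the
  permutation test guards against. Under pseudogenization × depth ≥ 1,
  almost every replicate contains phenotype loss without gene loss, the
  regime the four-state code exists for. SINGULAR is applied afterwards as an
  annotation on intact tips (default probability 0.02 per cell), since it is
  an annotation-level category, not an evolutionary state.
- **Phenotypes**: rule output, then independent flips with probability
  ε < 0.5; every flip is recorded, and per-branch event logs allow exact
  replay of tip states.

Everything derives from a single seed via spawned substreams; identical
configs give byte-identical outputs.

What the generator does *not* emulate: horizontal transfer and recombination
(gene histories are strictly tree-shaped), correlated evolution between genes
of one operon, annotation error in state assignment, and assay noise
structure beyond symmetric flips. Passing recovery benchmarks therefore shows
the inference machinery is sound under the assumed generating process, not
that real panels satisfy those assumptions.

### Recovery benchmark

`benchmark_recovery` repeats simulate → infer over seeds. A replicate is
*identifiable* when the true rule is minimal on the realized dataset (the
data witness every literal). On identifiable noiseless replicates the
exhaustive search provably recovers the true rule (it attains accuracy 1 and
is minimal), and the benchmark confirms ≥ 95 % exact recovery at 60 tips with
12 candidate genes and true rule (g1 ∧ g2) ∨ g3; with 5 % flip noise the true
rule attains the maximal concordance found in ≥ 80 % of replicates. Decoy
genes pick up spurious perfect-association flags in ≤ 5 % of replicates.

## Numerical and design choices

- Exact integer arithmetic wherever a printed integer is reproduced
  (percentages, Fisher tails); floats only at interfaces.
- Half-up rounding throughout (never banker's rounding), matching how survey
  tables print.
- Deterministic orderings everywhere results are sets: rules by literal count
  then lexicographic genes; screens by (q, p, gene); ties in flux fitting by
  highest homolactic fraction.
- Problem sizes in the shipped checks (100-replicate benchmarks, 1000-sim
  calibration at 199 permutations, n ≤ 30 Fisher sweep) were chosen so the
  whole suite completes in about a minute while Monte-Carlo error stays well
  inside the asserted bands.

## Known limitations

- Rule inference is exhaustive, not heuristic: it is intended for a handful
  of candidate genes per sugar (the bounds guard refuses searches beyond 10⁷
  rule evaluations). It does not scale to GWAS-style candidate sets.
- The permutation guard conditions on a fixed grouping; it does not model
  finer phylogenetic structure within groups.
- The flux-split fitter assumes yields are per mol substrate and routes are
  linearly mixed; it does not do redox/ATP bookkeeping or biomass yield.
- The packaged gene-state fixtures encode only documented states; cells
  defaulted to INTACT make packaged rules err on the side of predicting
  growth, which is visible (and intended) in the concordance reports of
  `carbotrait reproduce`.
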