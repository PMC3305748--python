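# Methods

## Model and procedure

The pipeline treats a gene expression cohort as a complete weighted graph:
vertices are genes, edge weights are `|PCC|` of the two genes' expression
profiles across samples. Taking the absolute value treats strong negative
co-expression as connectivity, which matters because anti-correlated
members of one regulatory program belong in one module. Weights are clipped
to `[0, 1]`; the diagonal is zero; the graph is stored dense, which is
comfortable to a few thousand genes on a laptop (the implementation warns
above 5,000).

Mining proceeds by greedy expansion from heavy seed edges. The expansion
threshold `(1 − 1/(2λ(|C|+t))) · d(C)` couples admission to the current
density: early on (small `|C|`) the factor is lenient, and it tightens
toward `d(C)` as the set grows, so late additions must nearly match the
set's average connectivity. The printed form of this expression in the
literature this algorithm descends from is typographically ambiguous; the
parenthesization above is the one consistent with the stated dependence on
λ, t, |C| and density, and it is isolated in a single function
(`miner._threshold_factor`) so an alternative reading is a one-line change.

The "edge-covering" property — every edge with weight ≥ γ·max is inside at
least one pre-filter sub-network — follows from the seed loop: an eligible
edge either seeds its own expansion or was already covered. The property is
exercised on random graphs in the test suite.

### Determinism choices

All tie-breaks are fixed so identical inputs give identical outputs:

- seed edges sort by (−weight, gene_a, gene_b) with endpoints in
  lexicographic order;
- expansion ties go to the earliest vertex in the network's vertex order
  (`argmax` takes the first maximum);
- β-merging scans pairs in list order, merges the first qualifying pair and
  restarts; at β ≈ 1 (the default 0.99999) only (near-)identical sets
  merge, so scan order is immaterial and the pass is idempotent;
- K-means restarts keep the earliest replicate on objective ties, and
  labels are canonicalized so sample 0 carries label 0;
- every stochastic stage derives its seed from one master seed plus a
  stage/sub-network label (CRC32 into a `SeedSequence`), so a re-run of a
  single stage reproduces the full run's behaviour.

The size filter (≥ 10 genes by default) is applied after β-merging. The
β-merge needs the network at hand to recompute a union's density, hence
`beta_merge(subs, beta, net)`.

## Survival screen

Patients are bipartitioned with K-means under the correlation distance
`1 − PCC` between per-patient feature vectors (the sub-network's genes).
sklearn's K-means is Euclidean-only, so the clustering is implemented
directly: rows are centred and scaled to unit norm, centroids are means of
member rows re-standardized, and the best of `replicates` (default 100)
random 2-point initializations wins by total within-cluster distance. An
emptied cluster is re-seeded at the worst-fitting sample so both groups
stay non-empty, which the downstream test requires. Samples whose feature
vector has zero variance make the distance undefined and raise an error.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(`KaplanMeierFitter`, `statistics.logrank_test`); ties use the standard
hypergeometric variance on the pooled risk set. The package wraps them with
the contracts the pipeline needs (non-empty groups, at least one event,
finite non-negative times) and the tests check the statistic against an
independently coded observed-minus-expected/variance oracle.

## Randomized thresholds

Overlapping sub-networks make the family of log-rank tests strongly
dependent, so significance is calibrated against the dataset itself: for
each size bin, random gene lists (independent Bernoulli inclusion at rate
N/|universe|, giving expected size N exactly) are run through the identical
screen, and the cutoff is the `⌈0.05·n⌉`-th smallest of the `n_random`
(default 1000) null p-values — for 1000 values, the 50th order statistic,
with no interpolation. Lists that come out with fewer than two genes are
redrawn, since correlation-distance features need at least two coordinates;
list size is independent of survival, so the null p-value distribution is
unaffected. Selection uses a strict inequality; sizes map to bins by
zeroing all but the leading decimal digit (28 → 20, 250 → 200), and a size
whose bin was never computed raises an error rather than extrapolating.

A property worth knowing when reading threshold tables: the *value* of a
cutoff is a conditional quantile — all random tests share the dataset's one
survival realization and one realized gene pool — so it fluctuates between
datasets (and drops sharply when the dataset contains real prognostic
structure that random lists can pick up). What is stable is the selection
rate it induces on fresh random lists from the same dataset, which stays at
the nominal 5%; the test suite checks both behaviours.

Cluster merging of significant sub-networks is formalized as connected
components of the graph joining pairs with overlap ratio > 0.5, computed
among the original sets (not against growing unions): this is
order-independent and reproduces transitive chains. Representative
tie-breaks: lowest p, then smaller gene set, then lexicographic id.

## Synthetic data generator

The generator emulates a genes × samples cohort with planted co-expression
modules and matched right-censored survival:

- **Expression.** Module gene `g` is `a_g · f + ε`, with one latent factor
  `f ~ N(0,1)` per sample per module and unit noise. The loading magnitude
  is inverted from the requested pairwise correlation
  (`|PCC| = a²/(a²+1)`), and loadings alternate in sign: a same-sign module
  would shift all genes together, which per-sample centring removes, making
  the module invisible to correlation distance between patients; real
  modules have heterogeneous loadings, and the alternation keeps `|PCC|` at
  target while making the factor's high/low patient groups genuinely
  bimodal in correlation distance. Background genes are independent
  `N(0,1)`.
- **Survival.** Each module splits samples at its factor's median; a
  sample's death hazard is the baseline (default 1/500 per day, median
  survival ≈ 1 year, a glioblastoma-like scale) times the product of module
  hazard ratios for its high groups. Times are exponential; censoring is an
  independent exponential clock whose rate is solved (Brent) so the
  expected censored fraction matches the request (default 30%).
- **Defaults** are the package's reference study conditions: 200 patients,
  one 15-gene module at |PCC| 0.85 with hazard ratio 3, 500 background
  genes.

What the generator does *not* emulate: probe-level artifacts, platform
normalization effects, correlated background (all non-module genes are
independent), non-proportional hazards, and informative censoring. Passing
tests on this generator therefore demonstrate the machinery — recovery of
planted dense modules and their survival effects at realistic effect sizes
— not robustness to those real-data complications.

## Numerical and degenerate-input choices

- Zero-variance genes are dropped before network construction (correlation
  undefined; any imputed weight would be arbitrary), with a warning.
- Expression input must be complete; missing values are rejected, not
  imputed.
- `|PCC|` values are clipped into `[0, 1]` against floating-point overshoot.
- The optional edge-weight floor in network construction is a memory
  optimization only, default off; any positive floor makes mining
  approximate and is documented as such.
- Densities recomputed from members agree with stored values to 1e-12; the
  expansion loop compares contribute against the threshold with plain
  floating-point `≥`, which the independent trace oracle reproduces.

## Problem sizes used by the test suite

The suite runs desk-scale versions of every check: random graphs up to 50
vertices for the edge-cover property, ≤10 vertices against the brute-force
expansion trace, 200-patient cohorts with 200 random tests per bin for
threshold calibration, and ten seeds of the 515-gene reference condition
for end-to-end planted-module recovery. These sizes were chosen so the
whole suite runs in a few minutes on one CPU while keeping every
statistical check at the stated tolerances.

## Known limitations

- The miner is quadratic in gene count through the dense weight matrix and
  the seed-edge scan; genome-scale (>10k genes) runs want a sparser design.
- K-means with correlation distance can converge to a local optimum;
  100 restarts make this rare but not impossible, and the screen's p-values
  inherit that residual randomness (controlled by the master seed).
- Thresholds for size bins larger than any mined sub-network are not
  computed, and sizes above the largest computed bin raise an error rather
  than extrapolate.
- The log-rank test is asymptotic; with very small or very unbalanced
  groups its χ² approximation weakens.
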