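# Methods

This note documents the models, conventions, and numerical choices behind
`slscan`, in the spirit of a statistical-software methods appendix.

## Constraint-based model and solvers

A metabolic model is a stoichiometric matrix *S* (metabolites × reactions)
with flux bounds *l*, *u*, an objective vector *c* (biomass), and one GPR
boolean rule per reaction. FBA solves max *c*ᵀ*x* subject to *Sx* = 0,
*l* ≤ *x* ≤ *u*. The L1-minimal (parsimonious) flux problem minimises
Σ|*v*| with the objective pinned to a target value, via the standard split
*x* = *p* − *q*, *p*, *q* ≥ 0.

All LPs and MILPs use HiGHS through `scipy.optimize.linprog` /
`scipy.optimize.milp`: single-threaded and deterministic, so repeated runs
give identical flux vectors. Choices:

* **Objective pinning** is relaxed to ± `1e-6 · max(1, |target|)`; exact
  equality is numerically brittle. A pin that is infeasible while the
  unpinned network is feasible raises a dedicated error.
* **Flux-support tolerance** is 1e-6 (three orders above solver
  feasibility): reactions with |flux| above it define the KO-gene list.
* **Knockouts** close reaction bounds to [0, 0] rather than deleting
  columns, keeping model dimensions stable across simulations. Unknown
  gene ids in a knockout set are inert. Negative post-knockout objectives
  (solver noise) are clipped to 0 before forming the KO/WT ratio, and
  ratios are capped at 1.

## Context-specific extraction (iMAT)

Expression is aggregated to reactions with AND → min, OR → max (the COBRA
convention). Genes missing from a profile are ignored inside a rule; a
rule whose genes are all missing, or a reaction without a GPR, is
*unmapped* and always classified *moderate* — never rewarded nor penalised
by the MILP. Classification uses value ≥ UB → high, ≤ LB → low (ties go to
the stronger class).

The iMAT MILP maximises (#high reactions with |flux| ≥ ε) + (#low
reactions with zero flux) with ε = 0.1 flux units, zero MIP gap. The
extracted model keeps the core set (which must contain biomass) plus every
reaction with nonzero MILP flux; orphan metabolites are pruned.

The threshold grid search iterates a fixed, ordered quantile grid computed
over the *mapped reaction-expression values*: (LB, UB) ∈ {(q25, q75),
(q25, q90), (q10, q75), (q10, q90), (q50, q75)}. "First suitable" means
the first pair whose extracted model has FBA objective > 1e-6. Both the
quantile basis and the order are declared conventions of this package; an
explicit grid can always be supplied.

Model QC reports blocked reactions (per-reaction max/min LPs), the biomass
optimum, and structural problems. Functionality tasks ask whether a target
metabolite can be produced at ≥ 1e-4 flux **from the task's inputs only**:
existing exchange reactions are closed, importers for the inputs and a
demand for the target are opened, and the demand is maximised. The random
benchmark draws size-matched reaction subsets that always retain all
exchange reactions and the biomass reaction — without this, almost every
random model fails trivially and the better-than-99%-of-random success
rule would be vacuous.

## The SL scan

* **Drivers**: metabolic genes (present in the KO-score universe) with ≥ 1
  damaging mutation in ≥ 2 cell lines. For MAF input a variant is damaging
  if its deleterious flag is true, else if its classification is nonsense,
  frameshift, splice-site, nonstop, or de-novo out-of-frame start; the
  rule is recorded in the matrix provenance.
* **Test**: Student's pooled two-sample t-test, two-sided; t > 0 means the
  knockout hurts mutated lines less. The choice of pooled over Welch and
  two-sided over one-sided is a declared convention. Self-pairs
  (driver = KO gene) stay in the family to keep the row-count contract
  simple; in practice they are filtered by the mean rule.
* **Filter**: driver/KO pairs whose mutated-group mean KO score exceeds
  0.95 get p = 1 without testing and remain in the BH family.
* **Noise**: every observation receives uniform noise in [1e-12, 1e-11),
  drawn from a generator seeded per (scan seed, driver, KO gene) via
  CRC-32, so results are independent of iteration order and reproducible
  bit-for-bit. The noise exists solely to make zero-variance groups
  testable; for means separated by ≥ 1e-3 it moves p-values by < 1e-4
  relative.
* **Skips**: pairs where either stratum has < 2 lines are skipped and
  logged, not assigned p = 1 — a one-observation t-test is undefined —
  and excluded from the BH family. FDR is adjusted within one scan
  (one cancer type), never pooled across scans.

Screen scans (CRISPR / shRNA / PRISM) use the same test without filter or
noise — experimental scores carry natural variance — with pairwise NaN
dropping. Concordance restricts both result tables to the pairs tested in
both, and the enrichment p is the inclusive upper tail P(X ≥ overlap) of
the hypergeometric with population = universe, successes = screen hits,
draws = method hits, summed exactly in log space. The inclusive tail is
the variant that reproduces the published per-cancer concordance p-values
to printed precision.

## Gene-set enrichment

Partner genes are ranked by descending |t|, ties broken by larger raw
score then gene id; the driver is appended with the mean partner t. The
enrichment score is the weighted-KS running-sum maximum deviation (hit
increments ∝ |score|, weight exponent 1; uniform miss decrements).
Significance uses gene-label permutations with the add-one estimator
(count + 1)/(n_perm + 1), which is a valid permutation p and near-uniform
under the null. Sample permutation is impossible from a ranked list.
Default n_perm = 1000, minimum overlap 2. Process frequency counts drivers
with p ≤ α per set (nominal by default; BH within driver optional).

## Synthetic data

The planted-SL generator emulates the pipeline's input formats around the
5-reaction parallel toy network: the driver (g2) gates a backup route for
the partner's (g1) reaction. In mutated lines the whole backup route —
driver plus its downstream isozymes — is transcriptionally silenced
(low ≈ 1 vs high ≈ 10 log2 expression, jitter ± 0.1, far from the (2, 5)
thresholds), and a damaging MAF record is written for the driver; context
extraction then drops the route and the partner becomes conditionally
essential. Default conditions: 20 cell lines, half mutated. The null
generator keeps the same expression heterogeneity but draws mutation
labels Bernoulli(0.5) independently of it.

What these fixtures do *not* emulate: DepMap's scale (hundreds of lines,
~1674 metabolic genes), mutation spectra, expression covariance, or
culture-medium effects. Passing the recovery and calibration suites shows
the statistical machinery is correct and calibrated under the planted
mechanism, not that genome-scale predictions are accurate. Cohort-scale
counts reported for real screens are therefore out of this package's test
scope; the acceptance layer replaces them with the synthetic suites and
with desk-scale recomputation of the published concordance enrichment
p-values from their contingency counts.

Problem sizes used by the default suites: 100 planted replicates and 20
null replicates at 20 cell lines each, 50 random ≤ 10-reaction networks
for the LP cross-check, exhaustive enumeration oracles on ≤ 10-reaction
toys, and hypergeometric brute-force checks up to universe 500 — chosen so
the whole suite documents the method on commodity hardware in about a
minute.

## Known limitations

* Only metabolic genes are considered; SL pairs outside metabolism are
  invisible by construction.
* The iMAT extraction may have degenerate optima; HiGHS determinism fixes
  the returned one, but it is one of possibly several optimal
  sub-networks.
* Mass balance is checked structurally, not from chemical formulas
  (formula fields are optional in the supported inputs).
* shRNA matrices are consumed as ATARiS scores in CSV; RDS files must be
  converted upstream. PRISM compounds require a user-supplied
  compound → target map.
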