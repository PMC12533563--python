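# Methods

## Model and assumptions

The package works in the standard expected-utility framing of threshold
analysis.  A patient is described by two numbers: the pre-test probability
of disease *p* (population prevalence or an individualized risk estimate —
the package is agnostic and models no covariates) and the cost-benefit
trade-off of treatment ρ = l/(l+b) ∈ (0,1).  Treating a diseased patient
yields utility *b* > 0, treating a healthy one costs *l* > 0; with no test
available, treatment is indicated iff p ≥ ρ.

All internal computation is carried out in units of *b*: the two VI
branches and every INB expression depend on (b, l) only through
r = ρ/(1−ρ) = l/b, and on a test's cost and harm only through
l_Dx/b.  Absolute currency enters only at the configuration layer (two of
the three packaged panels supply ratios only).  ρ = 0 and ρ = 1 are
rejected as degenerate (the formulas divide by ρ or 1−ρ).

Tests are binary, with known (Se, Sp), and their results are assumed
conditionally independent given disease status.  No correlation parameter
is exposed; correlated panels are out of scope.  Tests with Se + Sp ≤ 1
are accepted with a logged warning rather than rejected — the framework
remains well defined for them, and property tests exercise that region.

## Aggregation rules and expected testing loss

Composite operating points are exact products (AND/OR) or
Poisson-binomial majority tails, all order-invariant.  The majority rule
is implemented for any odd panel size by dynamic programming over the
count of positive results, not by symbolic expansion: test *k* is
administered while neither the positives nor the negatives have reached a
strict majority of the full panel, which for three tests means the first
two always run and the third only on a split.  Early stopping never
changes the final vote, so the composite point stays order-invariant
while the expected testing loss

    E[loss](p) = Σ_k (l_Dx,k / b) · P(test k administered | p)

is order-dependent and linear in p.  A brute-force oracle
(`outcome_enumeration_oracle`) replays the stopping rule on all 2^n
outcome vectors and is used throughout the test suite to pin the closed
forms and the DP to 1e-10; it is limited to n ≤ 12.

## Threshold solving

Within each VI branch, every protocol's INB is linear in p (and, at fixed
p, linear in r), so thresholds and pairwise transitions are roots of
linear equations — no iterative solver sits in the main path.  Roots are
filtered by branch validity: the lower (test) threshold must fall in
[0, ρ), the upper (test-treatment) threshold in [ρ, 1].  Thresholds in ρ
are solved in the transformed variable r and mapped back.  Thresholds
falling outside the unit interval are reported as absent rather than
clamped, so "always test" / "never test" regimes are explicit.  Since
INB(0) ≤ 0 and INB(1) ≤ 0 always hold while the branch lines join at
p = ρ, a protocol has a testing interval iff INB(ρ) > 0; degenerate
geometries (a branch positive up to its edge) truncate to the branch
segment.

For two *single* tests the INB difference is the same linear function of
p on both branches, so their transition point is branch-free and matches
the classical closed form.  For general protocols the difference depends
on the branch (the composite operating points differ); the solver
collects per-branch roots and prefers the one at which the INB is
positive, i.e. the transition actually inside the testing region.

## Protocol enumeration and selection

For a panel of n ≤ 6 tests the protocol set comprises all single tests,
all ordered sequences of ≥ 2 distinct tests under AND and under OR, and
all ordered odd-length ≥ 3 sequences under majority (three tests → 33
protocols).  The optimal action at (p, ρ) is the INB-argmax over that
set, defaulting to "no test, no treat" (p < ρ) or "treat without testing"
(p ≥ ρ) when no protocol achieves positive INB.  Exact INB ties break
toward fewer tests, then the lower expected testing loss, then the
lexicographically smaller protocol id — fewer tests dominate on
unmodeled patient burden.  The decision map rasterizes this argmax on a
uniform grid over the open unit square; the default 501 × 501 resolution
resolves the narrow regions that appear in the prostate panel (the
conjunctive-triple sliver near p > 0.3, ρ > 0.65) at modest cost, and
the map evaluation is vectorized per protocol (two linear branches
broadcast over the grid), so the full prostate map takes well under a
second.  Tests exercise smaller grids (9–21 points per axis), which is
sufficient to check agreement with the scalar selector cell by cell.

## ROC frontier

Distinct operating points are grouped at an absolute tolerance of 1e-9 on
both coordinates of the full-precision values: order permutations of the
same test set and rule coincide exactly in floating point, which is what
the "distinct pairs" counts refer to.  The frontier is the upper convex
hull in (1−Sp, Se) space anchored at (0,0) and (1,1), built by monotone
chain; a point is flagged efficient when its sensitivity reaches the hull
envelope at its false-positive rate within 1e-9, so collinear points on a
hull edge are retained (weak dominance kept).  Whether weakly dominated
collinear points should count as efficient is a convention; retaining
them is this package's documented choice.

## Case-study fixtures

The three packaged panels carry published parameters with per-parameter
provenance notes:

- **prostate** — FT (0.91/0.40), hK2 (0.51/0.78), TRUS (0.84/0.34) from
  Vickers et al. (2013); losses as ratios to b of 0.01/0.01/0.1, anchored
  on b = 10 × l_TRUS; reference ρ = 0.26 (the cohort's biopsy positivity).
- **colorectal** — FIT (0.733/0.964, USD 19), MTsDNA (0.933/0.898,
  USD 649), colonoscopy (0.887/0.796, USD 1400 plus a perforation-derived
  6e-4 QALY harm); λ = 100 000/QALY, b = λ·1.5 − 75 000 = USD 75 000.
- **cad** — ETT (0.68/0.77, USD 100), SE (0.867/0.807, USD 340), MPS
  (0.806/0.747, USD 819; dominated by SE on all axes), CCTA (0.937/0.847,
  USD 394) from Min et al. (2017); l = USD 55 000, b = USD 105 000, with
  threshold analyses calibrated at b/l = 1.9 exactly (ρ = 1/2.9), the
  value that places the ETT test threshold at the 15% guideline floor.

Component values (costs, harms, b) are treated as primary wherever a
published summary ratio disagrees with them: the colonoscopy ratio
1460/75 000 = 1.947e-2 vs a printed 1.97e-2, and the CCTA cost ratio
394/105 000 = 3.75e-3 vs a printed 9.57e-4 (a suspected copy of the ETT
row).  Both versions reproduce the case studies' headline thresholds at
the printed precision.  Two further published numbers disagree with the
closed-form majority specificity (prostate 0.55 printed vs 0.50 computed;
colorectal 0.98 printed vs 0.97 computed); the implementation follows the
formula, whose value the enumeration oracle confirms.

## Synthetic panels

`random_panel(n, seed)` draws Se, Sp ~ U(0.5, 1) and l_Dx/b ~ U(0, 0.05):
informative but imperfect tests with losses spanning the packaged panels'
range (2.5e-4 to 0.1).  These panels drive the oracle-equivalence,
order-invariance, monotonicity and threshold-consistency property tests.
They emulate *parameter* diversity only — independent binary tests with
exactly known operating points.  They do not emulate correlated results,
spectrum bias (Se/Sp varying with the tested population), or sampling
uncertainty in Se/Sp, so green property tests certify the algebra and the
implementation, not robustness of a clinical recommendation to those
real-data features.

## Numerical choices

- Grouping tolerance for distinct operating points: 1e-9 absolute;
  frontier membership: 1e-9 on the hull envelope.
- Oracle agreement asserted at 1e-10 (closed forms vs enumeration) and
  1e-12 for the n = 3 majority closed form.
- Threshold/transition roots: exact linear algebra per branch; INB at a
  reported threshold vanishes to < 1e-10 in units of b.
- Rounding to published precision (2 decimals for operating points and
  thresholds, 3 for probabilities and ratios, nearest percent for the
  CAD thresholds) happens only in reporting; all internal math is double
  precision.

## Known limitations

Mixed AND/OR expression trees, correlated tests, continuous-marker cutoff
optimization, confidence intervals on thresholds, and elicitation of λ or
QALY weights are out of scope.  Decision-region boundaries are raster
cells, not analytic curves.  Panels above six tests are rejected rather
than sampled (protocol count grows factorially).
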