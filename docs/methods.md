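# Methods

## Model

A protein's binding profile over a designed nucleosome library is modelled
as linear in the installed modifications plus all pairwise products,

    Y = β₀ + Σⱼ βⱼ Lⱼ + Σ_{j<k} Θ_{jk} Lⱼ Lₖ + ε,     L ∈ {0,1}^{n×q},

with Gaussian noise ε.  Θ is stored symmetric with zero diagonal and is
reported *single-count*: a pair's whole contribution to a fitted value is
Θ_{jk}·Lⱼ·Lₖ.  Diagonal products are never generated — for binary
predictors L² = L, so they would alias the main effects; a q-modification
design therefore has q + q(q−1)/2 coefficients (78 at q = 12).

Strong hierarchy (Θ_{jk} ≠ 0 ⇒ βⱼ ≠ 0 and βₖ ≠ 0) is imposed through the
standard convex relaxation: β is split into nonnegative parts β⁺, β⁻ and
each row of Θ obeys ‖Θⱼ‖₁ ≤ β⁺ⱼ + β⁻ⱼ, with objective
½‖y − ŷ‖² + λΣ(β⁺+β⁻) + (λ/2)‖Θ‖₁.  The relaxation does not force
symmetry; because the problem is convex and symmetric under Θ ↦ Θᵀ,
symmetrizing any solution cannot increase the objective, so the solver
symmetrizes on output and the reported Θ is exactly symmetric.

## Solver

A monotone FISTA iteration, JIT-compiled with numba.  The gradient step is
dense linear algebra on the centered design; the proximal step separates
across rows of Θ and is solved exactly up to a 100-step bisection on the
Lagrange multiplier of the ℓ₁-cap constraint.  If an accelerated candidate
would increase the objective, a plain proximal-gradient step (guaranteed
descent at step 1/‖A‖²) is taken instead, so the objective trace is
non-increasing by construction (`debug=True` retains it).

* Predictors are column-centered, **not scaled** — all features are binary
  and on a common scale, and unscaled fits keep coefficients in response
  units (SILAC log-ratios).  The intercept absorbs the centering.
* Convergence: relative objective change < 1e−7 or 5000 iterations;
  non-convergence raises (with the last objective), never returns silently.
* Coefficients below 1e−8 in magnitude are reported as exact zeros; the
  active set and hierarchy enforcement use this threshold.
* Penalty path: 20 log-spaced values from λ_max (the smallest penalty with
  an all-zero solution, max over centered columns of |xᵀỹ|) down to
  0.01·λ_max, warm-started.  Tests certify the solver's objective against
  an independent scipy `trust-constr` solve of the identical QP (worst
  relative gap ~1e−9 on small instances).

## Stability selection

Complementary-pairs stability selection: B = 50 pairs of disjoint
half-samples of size ⌊n/2⌋ (odd leftover index dropped per pair,
uniformly).  On each half-sample the path is walked from large to small λ
accumulating feature entry order on *hierarchy-enforced* active sets — an
interaction cannot be selected in a half-sample without both parents
active in that same fit — and the walk stops at the first grid point where
the cumulative entered count reaches k = 12 (ties at a grid point are all
kept; if fewer than k ever enter, all entered features are returned).
π̂(j) is the selection frequency over the 2B = 100 half-samples; the stable
set is {j : π̂(j) ≥ 0.5}.  Degenerate half-samples (e.g. constant response)
count as selecting nothing; more than 10% failures abort the protein.

### Selector saturation (a known regime)

The first-k selector *always* spends its budget: with a sparse truth
(3 features) each half-sample still returns ~k features, and because the
hierarchy cap makes pair columns expensive, the surplus concentrates on
the ~q noise **main** effects rather than spreading over the q(q−1)/2
pairs.  Their selection probabilities then straddle the 0.5 threshold in
both replicates.  Consequences, measured at the default study conditions
(below): the planted features are *contained* in the refit intersection in
~95% of runs, but the intersection is rarely *exactly* the planted set,
and borderline mains often differ between replicates (status
"inconsistent").  The guard the workflow actually provides is on
**interactions** — hierarchy, stability and the replicate intersection
together keep interaction false positives near zero (mean 0.44 per run
versus 2.82 for cross-validated penalty selection at 50 paired seeds) —
not on weak main effects.  Analyses that need exact support recovery
should lower k toward the expected model size.

## Replicate-consistency workflow

Per protein: (1) drop rows where the replicates disagree in sign — exact
zeros agree with anything (a zero log-ratio contradicts neither
replicate), rows missing in either replicate are dropped, and fewer than 8
surviving rows means no model; (2) run CPSS independently per replicate
(per-protein, per-replicate RNG streams derived by hashing, so adding
proteins never shifts other proteins' draws; a `shared_subsamples` option
reuses one set of draws for both replicates); require the stable sets
equal ("fully consistent") or nested; (3) refit by OLS with intercept on
the intersection of the two sets over the retained rows, response =
arithmetic mean of the replicates.  Adjusted R² = 1 − (1−R²)(nᵢ−1)/(nᵢ−d−1)
gates the reported models at 0.2; an intercept-only refit has adjusted R²
defined as 0.  A mains-only refit on the same intersection provides the
additive-versus-interaction variance decomposition.  Rank-deficient refit
designs drop the protein with a logged reason.

## Interaction modes

Six direction codes from the signs of (βⱼ, βₖ, Θ): same-sign mains with a
same-sign interaction are synergy (`b+b+b`, `r+r+r`); same-sign mains with
an opposing interaction are antagonism (`b+b+r`, `r+r+b`); opposed mains
are conflict, dominated by binding (`b+r+b`) or repulsion (`b+r+r`), with
the pair re-ordered binder-first so the code is unique.  Classification
uses the refit (unpenalised) coefficients, not the shrunken path
coefficients.  Complex-level analysis averages per-protein π̂ of
interaction pairs over user-supplied complex memberships and keeps edges
with mean π̂ > 0.2.

## Synthetic data

The generator emulates a screened nucleosome-library design and label-swap
replicate profiles.  Defaults (the package's study conditions):

| parameter | default | meaning |
|---|---|---|
| n, q | 33, 12 | experiments × modifications |
| design | blocky | two 3-column co-occurrence blocks |
| block_on_p / coupling / background | 0.4 / 0.6 / 0.15 | latent block state; P(column on given block on) ≈ 0.6; independent background |
| main effects | +1.5, +1.0 | response units (log-ratio) |
| interaction | +1.0 | between the two true mains (hierarchy by construction) |
| σ | 0.25 | replicate noise sd |
| ρ_signflip, miss_rate | 0, 0 | optional reverse-replicate corruption / dropout |

Block columns share a latent per-experiment state that raises joint
occurrence (within-block correlation ~0.25 on average) without making
columns near-identical; draws with any pairwise column correlation ≥ 0.95,
duplicate, all-zero or all-one columns are rejected and redrawn (up to
1000 times), because near-collinear columns belong to the *unscreened*
library that the collinearity screen exists to remove.  Effect magnitudes
default to the values above (configurable; random draws from ±[0.5, 1.5]
when unspecified) and σ = 0.25 makes the default recovery problem neither
trivial nor hopeless.  What the generator does **not** emulate: mass-spec
intensity distributions, peptide-level missingness structure, and the many
weak-but-real main effects of the biological data — so passing recovery
tests demonstrate correctness of the machinery, not field performance on
real screens.

The CPSS-versus-cross-validation comparison runs both selectors on the
same simulated response: CPSS as above; the competitor picks λ by 10-fold
CV over the same grid and takes the hierarchy-enforced active set of the
full-data fit at the CV-optimal λ.  Scoring is against the planted truth
on interaction features (false-positive count, true-positive rate).

## Genome-track validation

bedGraph/BED coordinates are 0-based half-open throughout.  Bins are fixed
width (default 1000 bp), gap-free from position 0 per chromosome; the
terminal remainder bin is dropped rather than shortened.  A bin's value
per track is the coverage-weighted mean of overlapping intervals; bins
with zero coverage in any track, or overlapping a blacklist interval by
≥ 1 bp, are removed.  Only chromosomes present in every track are binned.
The product column a·b of two tracks serves as the interaction proxy.
Peak contrasts report in/out-of-peak means, their difference, the
rank-biserial effect size and a Mann-Whitney p-value.  Partial
correlations come from the inverse of the pairwise Kendall tau-b matrix
(tau-b because methylation fractions and fold changes are heavily tied;
scipy's O(m log m) implementation), partial[u,v] = −Ω_uv/√(Ω_uu Ω_vv);
a near-singular tau matrix (condition number > 1e12) is ridge-inflated on
the diagonal in logged, escalating steps up to 1e−2, beyond which it is an
error.  Note the tau-based partial is only approximately zero under
conditional independence (the rank transform is nonlinear), so null checks
use moderate couplings.  bigWig is not parsed — convert to bedGraph
upstream.

## Problem sizes and determinism

Default test and acceptance runs use the study conditions above: 20
pipeline seeds for recovery, 50 paired seeds for the CPSS/CV comparison,
small (n ≤ 15, q ≤ 4) instances for oracle certification, and toy
single-chromosome genomes for binning — sizes chosen so the whole suite
certifies every stage in a few minutes on one CPU.  All randomness flows
through explicit seeds; pipeline tables are byte-identical across reruns
with the same seed.

## Known limitations

* Exact support recovery is not the selector's operating point at k = 12
  with very sparse truths (see *Selector saturation*).
* Weak-hierarchy mode, three-way interactions and non-Gaussian losses are
  out of scope.
* The CPSS error-control constants of the theoretical literature are not
  computed; π_thr is a plain threshold.
* Agreement with the original R implementation of the hierarchy solver is
  at the level of the shared convex objective (certified against a generic
  solver), not iterate-for-iterate.
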