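# Methods

## Model and assumptions

The tissue is a chain of K cell compartments downstream of a stem-cell pool
(compartment 0). The stem pool has constant size N₀ and divides
asymmetrically at rate r₀ per cell per year, so it exports a constant flux
φ = influx_factor·r₀·N₀ of cells into compartment 1 (influx_factor defaults
to 1, one exported cell per stem division; setting it to 2ε₀ represents a
symmetrically differentiating stem pool). A dividing cell in compartment k
differentiates (two daughters into k+1) with probability εₖ, dies with
probability dₖ, and self-renews otherwise. The model deliberately contains
no feedback, no spatial structure and no interaction between clones: the
mean dynamics are a *linear* cascade, and distinct clones evolve
independently and superpose additively. Stem-pool dynamics (e.g. a Moran
process among the N₀ stem cells) are out of scope; N₀ is a constant.

Writing γₖ = 2(εₖ+dₖ)−1 (per-division net loss), bₖ = γₖrₖ and
aₖ = 2εₖ₋₁rₖ₋₁:

* γₖ > 0 in every compartment is the homeostatic regime: a unique
  equilibrium N\*₁ = φ/b₁, N\*ₖ = aₖN\*ₖ₋₁/bₖ exists and all transients
  decay;
* γ = 0 in a compartment makes it self-sustaining (a clone there keeps its
  founder count and feeds downstream compartments like a private stem
  pool);
* γ < 0 makes the compartment a net producer even without influx: counts
  downstream of it diverge exponentially.

Time is measured in years, with r₀ = 1/year fixing the scale; day-level
outputs use 365 days/year.

## Closed forms and numerics

Because the cascade matrix is lower-bidiagonal with distinct eigenvalues
−bⱼ in the generic case, every solution is a hypoexponential sum
N_inf + Σⱼ Aⱼ e^(−bⱼt) whose amplitudes are products of inflow
coefficients divided by products of rate differences (partial fractions).
Numerical choices:

* Amplitudes are stored as (sign, log magnitude) pairs; a compartment-31
  amplitude can exceed 10⁵⁰ while the sum at small t is ~10⁻²⁰, so naive
  products overflow and naive sums cancel catastrophically.
* Evaluation runs in floating point and monitors cancellation (the ratio of
  the signed sum to the sum of magnitudes). When more than 6 decimal digits
  cancel, the point is re-evaluated in 100-digit arithmetic (mpmath) with
  amplitudes rebuilt exactly from the rate coefficients; 6 digits keeps the
  fast path's error comfortably below the 10⁻⁸ relative agreement the
  oracle tests demand, since ~14 digits survive the log/exp round trip.
* Decay rates closer than 10⁻⁹·max(b) (relative) are treated as confluent:
  the closed form would need t·e^(−bt) terms, so the solution object is
  flagged and transparently evaluated through the ODE integrator instead.
* The ODE oracle integrates the cascade with LSODA at rtol 10⁻¹⁰ /
  atol 10⁻¹² (tighter when used as a test oracle), with the exact constant
  Jacobian supplied; round-off negatives within 10·atol are clamped to
  zero. A matrix-exponential evaluation would be an equally valid exact
  path for this constant-coefficient linear system.
* Trajectory maxima are located from the sign pattern of the analytic
  derivative on a geometric grid followed by bracketed root-finding;
  threshold crossings are bracketed from the maximum outward. No value is
  ever read off a plotting grid, so day-level numbers are
  grid-artifact-free.

## Extinction times

"Extinction" of a deterministic clone in compartment k means its *average*
count dropping below a threshold of one cell (exposed as a parameter). Two
estimators are provided: root-finding on the full exponential sum (exact),
and the slowest-mode approximation τ = ln(A_min/threshold)/b_min using only
the slowest-decaying term. The approximation is accurate when the slowest
mode already dominates at the crossing, i.e. when (b₂nd−b_min)·τ ≫ 1.
On the default hematopoiesis family (rate ratio 1.26) this is a *slowly*
attained limit: for a single founder cell the asymptotic estimate exceeds
the exact crossing by ~58% two compartments below the origin, shrinking to
~5% seven compartments down. With a 50-cell founder (or, equivalently, in
any setting where ln A_min is large) the two agree within 5% already at
k = c+2; the validation suite uses that mean-field regime and a unit test
asserts the monotone improvement with k−c for the single-founder case.

Empirical extinction times from the simulator score the moment the
compartment-k count reaches zero with no clone cells remaining upstream
(recolonization impossible) — the stochastic counterpart of washout. For a
single founder the *mean* stochastic extinction time sits systematically
~20% below the deterministic mean-crossing, because the late-time average
count is carried by rare large realizations; the two converge (within 15%,
measured ≤6%) for founder clones of ~50 cells, which is the regime in which
a mean-based extinction time is a faithful summary. This is a real
limitation of mean-based extinction estimates for single-cell clones, not
an artifact.

## Stochastic simulator

A standard Gillespie loop over the first K_sim compartments: total
propensity r₀N₀ (stem events, optional) + Σ rₖnₖ, exponential waiting
times, event compartment chosen proportional to propensity, outcome drawn
from (εₖ, dₖ, 1−εₖ−dₖ). Stem events add influx_factor (integer) cells to
compartment 1 and leave the stem pool untouched. Cells differentiating out
of compartment K_sim are tallied as overflow, not tracked — simulating all
31 compartments at physiological cell numbers (≫10⁹ cells) is neither
feasible nor needed, since the deterministic solutions are exact means.
One simulated time unit is N₀ stem events ≈ 1 year at r₀ = 1/year (asserted
to Poisson accuracy in the tests). Per-realization RNG streams derive from
(master seed, run index) via numpy's SeedSequence spawning, so ensembles
are reproducible and order-independent. Relative fluctuations in the first
compartments are of order one for single-founder clones and shrink with
compartment number; ensemble summaries report per-point mean, SD and
realization count.

## PIG-A worked analysis

The healthy hierarchy uses the standard human hematopoiesis estimates
(N₀ = 400, r₀ = 1/yr, ε = 0.85, d = 0, rₖ = 1.26ᵏ, K = 31; compartment 31
= circulating cells, equilibrium ≈ 1.6·10¹¹ cells). PIG-A-mutant cells are
nearly neutral: they keep the healthy rates and d = 0 but differentiate
with a slightly lower probability ε = 0.765, the value at which a
single-founder clone from an early-progenitor compartment transiently
reaches the 10–60 per-million frequencies observed by flow cytometry
(a fully neutral ε = 0.85 clone would peak ~25× lower, far below the
7.5-per-million detection limit from any plausible origin).

Frequencies are reported as 10⁶ · (mutant count)/(healthy equilibrium
count) in the reference compartment. The *extinction time for an
observation level L* follows the convention: elapsed time from the clone's
down-crossing of L on its decaying branch (the moment a sample would
measure L) to its final down-crossing of the detection limit (7.5 per
million). Measuring from the rising branch instead would make the
average-level time exceed the maximum-level time, contradicting the
observed ordering; with the decaying-branch convention a single origin-10
parameter set yields ~211 days for L = 51 and ~96 days for L = 21
simultaneously. The origin scan labels origins whose peak stays below the
detection limit "undetectable", scores each (level, persistence)
observation independently (observations come from different individuals)
by the absolute log-ratio between predicted remaining-detectability time
and observed persistence, and ranks origins by their best-explained
observation; with the in vivo levels (51 and 21 per million, persistence
192 and 174 days) the compatible window is the contiguous early-progenitor
band around compartments 9–11, with origin 10 ranked first.

## Synthetic data and what the tests show

All test inputs are generated programmatically: a 4-compartment toy
hierarchy with hand-checkable coefficients (ε = 0.85, d = 0, rates
1.26^(k−1), N₀ = 5), random valid models with rejection-sampled
well-separated decay rates (pairwise relative gaps > 10⁻³) for oracle
equivalence, and seeded Gillespie ensembles. These emulate the model's own
universe — they cannot validate the biological parameter estimates, the
neutrality of PIG-A mutants, or the absence of feedback/selection in real
hematopoiesis. What passing tests do establish: the closed forms solve the
stated equations (10⁻⁸ agreement with independent integration), the
simulator's means are the deterministic solutions (3·SE agreement at 1000
realizations), the regime taxonomy (washout / fixed point / divergence)
behaves as derived, and the PIG-A pipeline reproduces its reference
predictions (230 and 100 days within 10%) under the stated convention.

## Problem sizes

Default validation scales were chosen to keep the whole suite in tens of
seconds on one core: 100 random models × 50 time points for oracle
equivalence, 1000 realizations for mean-field consistency on the
4-compartment toy model, 300 realizations per point for empirical
extinction times, ensembles capped at K_sim ≤ 8. Larger runs only tighten
the statistical bands; the deterministic comparisons are scale-free.
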