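# Methods

## Setting

A confirmatory comparative diagnostic accuracy trial evaluates an
experimental index test against an established comparator, with the
reference standard defining the true disease status. Sensitivity (Se, the
probability of a positive result in diseased participants) and specificity
(Sp, the probability of a negative result in non-diseased participants)
are co-primary endpoints: the trial succeeds only if superiority of the
experimental test is shown on *both*. Formally the global null is the
union of the two endpoint nulls,

    H0_global = {Se_E = Se_C} ∪ {Sp_E = Sp_C},

and it is rejected by the Intersection-Union rule only when both endpoint
nulls are rejected. Because each endpoint is tested at its own two-sided
level α, no multiplicity adjustment is needed, and under independence of
the diseased and non-diseased strata the overall power is the product of
the endpoint powers, Power_Se · Power_Sp.

Two designs are supported. In the *paired* design every participant
receives both index tests and the reference standard; in the *unpaired*
design participants are randomized 1:1 to one index test plus the
reference standard. Paired data introduce dependence between the tests,
parametrized by the discordance proportions ψ_D and ψ_ND — the probability
that the two tests disagree within the diseased and non-diseased stratum.
Given the marginal accuracies p_C, p_E of a stratum, ψ is constrained to

    |p_C − p_E| ≤ ψ ≤ p_C + p_E − 2 p_C p_E,

the lower edge corresponding to maximal (positive) dependence and the
upper edge to independence. Equivalently the dependence can be stated as
the joint success probability (TPPR among diseased, TNNR among
non-diseased), related by ψ = p_E + p_C − 2 · joint.

## Sample-size calculation

Per-status requirements come from standard asymptotic kernels:

* paired: the Miettinen-type formula
  n = (z_{1−α/2} ψ + z_{1−β} √(ψ² − ¼ (p_C − p_E)² (3 + ψ)))² / (ψ (p_C − p_E)²),
  applied with (Se_C, Se_E, ψ_D) for the diseased group and
  (Sp_C, Sp_E, ψ_ND) for the non-diseased group;
* unpaired: the two-independent-proportions formula
  n = (z_{1−α/2} √V₀ + z_{1−β} √V_A)² / (p_C − p_E)² per arm, with the
  alternative variance V_A = p_C(1−p_C) + p_E(1−p_E) and the null variance
  V₀ = 2 p̄(1−p̄) at the pooled proportion p̄ = (p_C + p_E)/2. Pooling
  under the null is the standard two-proportion convention; other
  variance choices exist, and this is the one the package fixes.

Prevalence scaling turns per-status requirements into endpoint-specific
totals, N_Se = n_D/π and N_Sp = n_ND/(1−π).

**Rounding.** Per-status sizes are kept unrounded through the prevalence
division; only the final total is rounded up. This order reproduces the
example study's printed numbers exactly (73.46 diseased → 73.46/0.47 = 156.3 →
157), whereas ceiling the per-status size first would not (74/0.47 =
157.4 → 158). Displayed per-status values are ceilings of the raw
requirements.

**Conventional method.** Each endpoint is sized at a fixed per-endpoint
power (default 0.9 each) and the larger total is recruited. The
non-binding endpoint is then overpowered, increasingly so the farther the
prevalence is from the point where N_Se = N_Sp.

**Optimal method.** The overall power is split between the endpoints so
that the unrounded totals coincide, subject to
(1−β_Se)(1−β_Sp) = Power_overall. Eliminating β_Sp = 1 −
Power_overall/(1−β_Se) leaves a one-dimensional root-finding problem in
power_se on the feasible interval (Power_overall, 1); the gap
N_Se − N_Sp is strictly increasing there, and no closed form exists.
The solver uses bisection on power_se with bracket offset 1e−9 and
tolerance 1e−10 — chosen over derivative-based methods because the normal
quantiles diverge at the interval's edges while bisection remains
bracketed.

**Boundary (one-sided domination).** When one endpoint's total exceeds
the other's on the entire feasible interval — e.g. a very small prevalence
making the diseased-group requirement dominant even with near-unit power
on the other endpoint — the equalization has no interior solution. The
constrained optimum is then the boundary split: the binding endpoint
receives exactly the overall target power and the other endpoint is
effectively overpowered at the resulting total. The solver clamps to this
boundary rather than failing; the re-estimation step of the worked
example already sits numerically at it (power_se ≈ 0.800007). The
pre-rounding equality |N_Se − N_Sp| < 1 therefore holds for interior
solutions only.

**Minimal paired size.** The paired total is monotone increasing in both
discordance proportions, so evaluating the optimal method at
ψ_min = |p_C − p_E| (both strata) gives a lower bound over all admissible
dependence structures. This minimal size doubles as the initial sample
size and the interim-analysis size of the paired adaptive design.

## Analysis

Superiority is concluded from two-sided confidence intervals for the
difference of proportions, one per endpoint, each at level 1−α; the
global decision requires both lower bounds above zero.

* Unpaired: score interval for the difference of two independent
  proportions. The interval inverts the score statistic with variance
  evaluated at the restricted MLE under p₁ − p₂ = δ, computed from the
  closed-form solution of the constrained cubic likelihood equation. The
  small-sample N/(N−1) variance inflation is available as an option
  (`bias_correction`), off by default; the literature uses both variants
  and the source does not pin one down.
* Paired: Tango's asymptotic score interval for the difference of matched
  proportions, profiling the nuisance discordant-cell probability at the
  positive root of the constrained quadratic.

Both inversions use bisection on δ (tolerance 1e−8, bracketed at [−1, 1]),
are range preserving, remain proper intervals at boundary counts (for
all-concordant paired data the endpoints reduce to ±z²/(n+z²)), and apply
the same inversion at x = 0 or x = n with no ad-hoc substitutions. Score
intervals are preferred over Wald for coverage closer to nominal; a Wald
interval is provided for reference only.

## Blinded re-estimation

Planning requires nuisance parameters — the prevalence π and, in the
paired design, ψ_D and ψ_ND — that are typically uncertain. The adaptive
design re-estimates them at a blinded interim:

1. initial size: paired — the minimal sample size; unpaired — the optimal
   size at the assumed parameters;
2. interim timing: paired — the full initial size; unpaired — half the
   initial per-arm size, rounded up at odd halves;
3. blinded estimation: π̂ = n_D/n (binomial MLE) and, paired,
   ψ̂ = (n₁₀ + n₀₁)/n within each stratum (multinomial MLE). These depend
   only on disease status and the concordance pattern, never on which
   test was correct, so the effect estimates stay hidden;
4. re-computation: the optimal size with nuisance parameters replaced by
   estimates and accuracy assumptions kept at their planning values; the
   recruitment target never drops below the interim size already
   observed (standard internal-pilot convention);
5. final analysis of *all* recruited participants with the fixed-design
   intervals at the unadjusted per-endpoint α. Because the adaptation is
   blinded, the type-I error rate is not inflated by construction.

Two corner cases are handled explicitly. An interim ψ̂ *below* the
minimum admissible for the assumed effect (where the sizing radicand
turns negative) is clamped up to that minimum with a warning. An interim
ψ̂ *above* the independence value implied by the assumed accuracies is
accepted as-is: the kernel remains well defined, and such estimates arise
routinely when the planning assumptions are wrong — rejecting them would
both bias the recorded estimates and misstate the design's operating
characteristics. Data generation, by contrast, enforces the full
admissibility interval, since joint cell probabilities must be
nonnegative.

## Simulation engine

Paired data: n_D ~ Bin(N, π_true); within each stratum the four
cross-classified outcomes are multinomial with cells implied by the
marginal accuracies and the joint success probability (both-correct
first). Unpaired data: independent binomial disease-status and
test-result draws per arm, with N participants per arm. Each scenario
uses a single seed from which per-run substreams are spawned
deterministically, so results are reproducible and independent of run
order; any reproducible generator suffices rather than a particular one.

A scenario couples true generating parameters with planning assumptions.
The packaged base scenario uses comparator accuracies 0.8/0.7, a planned
+0.1 improvement on both endpoints, true prevalence 0.2 assumed at 0.3,
and true discordance (0.11, 0.14) assumed at (0.18, 0.24) — deliberately
misspecified nuisance parameters, with variations of one parameter at a
time, 10,000 replicates per scenario at full scale. A scenario grid that
keeps a nominal ψ_true across effect sizes can undershoot the lower
admissibility bound at the largest effect; such values are lifted to the
bound on construction. Reported metrics: rejection rate (type-I error
under the null, power otherwise), the clairvoyant size N_true computed
from the true nuisance parameters with planning accuracies, the mean and
RMSE of the realized size, relative bias of the interim estimates, and
the Monte-Carlo half-width 1.96·√(p(1−p)/runs). Runs in which a disease
stratum comes up empty are re-drawn and counted; run-level failures are
counted and reported, never silently dropped.

What the generator does *not* emulate: verification bias (all
participants are verified by the reference standard), an imperfect
reference standard, clustered or multi-reader data, covariate-dependent
accuracy, and recruitment over time. Passing operating-characteristic
tests therefore speak to the statistical procedure under the stated
sampling model, not to robustness against those real-data features.

## Test and default scales

The packaged defaults mirror the study conditions (10,000 replicates per
scenario); the test suite and operating-characteristic checks run the
same engine at 2,000 replicates, the scale at which the substituted
figure-based properties are stated (Monte-Carlo half-width ≈ 0.018 for a
rate near 0.8). Full-scale runs remain available through ``n_runs`` and
the ``--runs`` CLI flag on a single CPU.

## Known limitations

* Only superiority hypotheses; non-inferiority and mixed hypotheses are
  an extension point.
* Sample-size formulas and the analysis intervals are asymptotic and not
  derived from one another (the sizing kernels match Wald-type
  asymptotics while the analysis uses score inversions); small-sample
  calibration differences are absorbed into the simulated operating
  characteristics rather than corrected analytically.
* The unpaired total from the equalization is per randomized arm (1:1
  allocation); because conventions differ on whether such totals are
  per arm or study-wide, the study-wide total 2N is reported alongside.
* No early stopping, no caps on the re-estimated size, no unblinded
  adaptation.
* Re-sizing on noisy interim estimates carries a concavity (Jensen)
  penalty: the power function is concave in the realized sample size near
  the target, so averaging over the spread of re-estimated sizes yields
  less power than sizing at the true parameters would, even though the
  mean size is nearly unbiased. The operating-characteristic tests
  quantify this; it grows when the interim diseased stratum is small
  (low prevalence, minimal interim size) and the true discordance is
  medium to large.
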