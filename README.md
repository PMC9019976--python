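# copriss

Optimal co-primary sample size and blinded sample-size re-estimation for
comparative diagnostic accuracy trials.

## The problem

A confirmatory diagnostic accuracy trial compares an experimental index
test against a comparator, with a reference standard defining disease
status. Sensitivity (Se) and specificity (Sp) are *co-primary* endpoints
combined by the Intersection-Union test: the global null

    H0 = {Se_E = Se_C} ∪ {Sp_E = Sp_C}

is rejected only if superiority is shown on both endpoints, so the
overall power is the product Power_Se · Power_Sp and no multiplicity
adjustment is needed. Diseased participants inform Se and non-diseased
participants inform Sp, so the endpoint-specific totals are
N_Se = n_D/π and N_Sp = n_ND/(1−π) with prevalence π. The conventional
recipe — size each endpoint at a fixed power and recruit
max(N_Se, N_Sp) — overpowers the non-binding endpoint. The *optimal*
calculation instead splits the overall power between the endpoints under
(1−β_Se)(1−β_Sp) = Power_overall so that the two totals coincide,
yielding the smallest N with the target overall power. In the paired
design (every participant gets both tests) the per-status kernels are
Miettinen-type formulas driven by the discordance proportions ψ_D, ψ_ND;
in the unpaired design, the classical two-independent-proportions
formula.

Because π and ψ are uncertain at planning, the package also implements a
*blinded* internal-pilot design: recruit to an interim (the minimal
paired sample size, or half the unpaired size), estimate the nuisance
parameters from disease status and test concordance only — never from
which test was right — re-compute the optimal size, and analyse all
participants at the unadjusted level with score-type intervals (Tango's
matched-pairs score interval in the paired design, the restricted-MLE
score interval for independent proportions in the unpaired design).
Blinding means the type-I error is not inflated. A Monte-Carlo engine
evaluates type-I error, power, sample-size distribution, and estimator
bias of fixed vs adaptive designs. See `docs/methods.md` for the full
model description.

Intended users: biostatisticians planning comparative accuracy studies
and methodologists examining adaptive diagnostic designs.

## Worked example

A paired study compares PET/CT against CT for pancreatic cancer:
Se 0.81 → 0.90, Sp 0.66 → 0.80, prevalence 0.47, per-endpoint two-sided
α = 0.05, overall target power 0.8, minimal discordance
ψ_D = 0.09, ψ_ND = 0.14.

```
copriss fixtures --outdir fixtures
copriss size --config fixtures/table1_example.yaml
```

prints (abridged):

```json
{
  "method": "optimal",
  "n_final": 133,
  "n_se_total_unrounded": 132.68000080919145,
  "n_sp_total_unrounded": 132.6800007276051,
  "split": {
    "power_se": 0.804460531543798,
    "power_sp": 0.9944552512287482
  }
}
```

The solver allocated power 0.804 to sensitivity and 0.994 to specificity
(product 0.8), making both endpoint totals equal at 132.68 → **133
participants** — versus 157 from the conventional calculation at 0.9
power per endpoint. This is also the internal pilot size of the adaptive
design. After the blinded interim re-estimates π̂ = 0.44, ψ̂_D = 0.11,
ψ̂_ND = 0.14,

```
copriss reestimate --config fixtures/table1_example.yaml \
                   --interim fixtures/table3_interim.json
```

reports `"n_final": 200` and `"recruitment_delta": 67`: the slightly
lower prevalence and higher discordance than planned require 67 more
participants. Final analysis of a count table:

```
copriss ci --design paired --counts counts.json --level 0.95
```

```json
{
  "sensitivity_difference": {"lower": 0.0105, "upper": 0.2507},
  "specificity_difference": {"lower": 0.0305, "upper": 0.2152},
  "superiority_shown": true
}
```

Both Tango interval lower bounds exceed zero, so the
Intersection-Union rule concludes superiority on both endpoints.
Operating characteristics of a scenario:

```
copriss simulate --scenario fixtures/table4_initial.yaml --runs 2000 --seed 1
```

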