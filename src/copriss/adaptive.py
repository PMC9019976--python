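"""Blinded sample-size re-estimation (internal pilot design).

Uncertain nuisance parameters - the disease prevalence and, in the paired
design, the discordance proportions - drive the sample size but are not
reliably known at the planning stage.  The adaptive design re-estimates
them at a blinded interim analysis and recalculates the optimal sample
size, in five phases:

1. compute the initial sample size (paired: the *minimal* size, obtained
   at the smallest admissible discordance; unpaired: the optimal size);
2. recruit up to the interim sample size (paired: the initial size itself;
   unpaired: half the initial size);
3. estimate the nuisance parameters from interim data, blinded;
4. recompute the optimal sample size with the estimates, keeping the
   planning assumptions about both tests' accuracies, and continue
   recruitment to the larger of the re-estimated and interim sizes;
5. analyse all recruited participants with the fixed-design score or
   Tango intervals and the Intersection-Union rule at the unadjusted
   per-endpoint level.

Blinding: the interim estimates are functions of the disease status and
the concordance pattern of the two tests only; they never use which test
was right.  Sensitivity and specificity of the experimental test are
therefore not revealed and the type-I error rate is not inflated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple, Union

import numpy as np

from .core_design import AccuracyParams, DesignSpec
from .intervals import (
    ConfidenceInterval,
    PairedCountTable,
    UnpairedCounts,
    iut_decision,
    score_ci_diff_independent,
    tango_ci_diff_paired,
)
from .sample_size import (
    PairedDependence,
    SampleSizeResult,
    minimal_sample_size_paired,
    optimal_sample_size,
    psi_min,
)

__all__ = [
    "InterimEstimates",
    "AdaptiveTrialRecord",
    "estimate_prevalence",
    "estimate_discordance",
    "interim_size",
    "reestimate_sample_size",
    "run_adaptive_trial",
]


@dataclass(frozen=True)
class InterimEstimates:
    """Blinded interim estimates of the nuisance parameters.

    Derived only from disease status and the tests' concordance pattern;
    ``psi_d_hat``/``psi_nd_hat`` are ``None`` in the unpaired design.
    """

    pi_hat: float
    n_interim: int
    psi_d_hat: Optional[float] = None
    psi_nd_hat: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("pi_hat", "psi_d_hat", "psi_nd_hat"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_interim < 1:
            raise ValueError("n_interim must be positive")


def estimate_prevalence(n_d: int, n: int) -> float:
    """Binomial ML estimate of the prevalence, ``n_d / n``."""
    if n < 1:
        raise ValueError("interim sample size must be at least 1")
    if not 0 <= n_d <= n:
        raise ValueError(f"need 0 <= n_d <= n, got n_d={n_d}, n={n}")
    return n_d / n


def estimate_discordance(table: PairedCountTable) -> Tuple[float, float]:
    """Multinomial ML estimates of the discordance proportions.

    Returns ``(psi_d_hat, psi_nd_hat)``, the observed fractions of
    discordant test-result pairs within the diseased and non-diseased
    stratum.  Blinded: discordance does not reveal which test was correct.
    """
    if table.n_diseased < 1:
        raise ValueError("cannot estimate discordance: diseased stratum is empty")
    if table.n_nondiseased < 1:
        raise ValueError("cannot estimate discordance: non-diseased stratum is empty")
    psi_d = (table.d10 + table.d01) / table.n_diseased
    psi_nd = (table.nd10 + table.nd01) / table.n_nondiseased
    return psi_d, psi_nd


def interim_estimates(table: PairedCountTable) -> InterimEstimates:
    """All blinded interim estimates from a paired count table."""
    psi_d, psi_nd = estimate_discordance(table)
    return InterimEstimates(
        pi_hat=estimate_prevalence(table.n_diseased, table.n_total),
        n_interim=table.n_total,
        psi_d_hat=psi_d,
        psi_nd_hat=psi_nd,
    )


def interim_size(spec: DesignSpec, initial: SampleSizeResult) -> int:
    """Sample size at which the blinded interim analysis takes place.

    Paired: the interim uses the full initial (minimal) sample size.
    Unpaired: half the initial per-arm size, rounded up.
    """
    if spec.design_kind == "paired":
        return initial.n_final
    return math.ceil(initial.n_final / 2)


def reestimate_sample_size(
    spec: DesignSpec,
    params_assumed: AccuracyParams,
    est: InterimEstimates,
) -> SampleSizeResult:
    """Optimal sample size with nuisance parameters replaced by estimates.

    The accuracy assumptions (both tests' sensitivity and specificity)
    stay at their planning values - only the prevalence and, in the paired
    design, the discordance proportions are updated.  An estimated
    discordance below the minimum admissible for the assumed accuracies is
    clamped up to that minimum (with a warning), since smaller values are
    incompatible with the planned effect.  The reported ``n_final`` never
    drops below the interim sample size already recruited.
    """
    params = replace(params_assumed, prevalence=est.pi_hat)
    if spec.design_kind == "paired":
        if est.psi_d_hat is None or est.psi_nd_hat is None:
            raise ValueError("paired re-estimation requires discordance estimates")
        dep = PairedDependence(
            psi_d=_clamp_psi("psi_d", est.psi_d_hat, params.se_c, params.se_e),
            psi_nd=_clamp_psi("psi_nd", est.psi_nd_hat, params.sp_c, params.sp_e),
        )
        result = optimal_sample_size(spec, params, dep)
    else:
        result = optimal_sample_size(spec, params)
    if result.n_final < est.n_interim:
        result = replace(result, n_final=est.n_interim)
    return result


def _clamp_psi(name: str, value: float, p_c: float, p_e: float) -> float:
    floor = psi_min(p_c, p_e)
    if value < floor:
        warnings.warn(
            f"interim {name} estimate {value:.4g} below the minimum {floor:.4g} "
            "admissible for the assumed accuracies; clamped",
            stacklevel=3,
        )
        return floor
    return value


@dataclass(frozen=True)
class AdaptiveTrialRecord:
    """Full record of one simulated adaptive trial."""

    design_kind: str
    n_initial: int
    n_interim: int
    estimates: InterimEstimates
    n_final: int
    counts: Union[PairedCountTable, UnpairedCounts]
    ci_se: ConfidenceInterval
    ci_sp: ConfidenceInterval
    reject: bool
    n_redraws: int


def analyze_paired(table: PairedCountTable, alpha: float) -> Tuple[ConfidenceInterval, ConfidenceInterval, bool]:
    """Tango intervals for both endpoint differences and the IUT decision."""
    level = 1.0 - alpha
    ci_se = tango_ci_diff_paired(table.d10, table.d01, table.n_diseased, level)
    # among non-diseased a positive result is an error, so the
    # experimental-favoring discordant cell is nd01 (comparator-only FP)
    ci_sp = tango_ci_diff_paired(table.nd01, table.nd10, table.n_nondiseased, level)
    return ci_se, ci_sp, iut_decision(ci_se, ci_sp)


def analyze_unpaired(counts: UnpairedCounts, alpha: float) -> Tuple[ConfidenceInterval, ConfidenceInterval, bool]:
    """Score intervals for both endpoint differences and the IUT decision."""
    level = 1.0 - alpha
    ci_se = score_ci_diff_independent(
        counts.tp_e, counts.n_d_e, counts.tp_c, counts.n_d_c, level
    )
    ci_sp = score_ci_diff_independent(
        counts.tn_e, counts.n_nd_e, counts.tn_c, counts.n_nd_c, level
    )
    return ci_se, ci_sp, iut_decision(ci_se, ci_sp)


def _draw_paired_nondegenerate(params_true, dep_true, n, rng, max_redraws=1000):
    """Sample a paired table, redrawing while a disease stratum is empty."""
    from .simulation import sample_paired_counts

    for attempt in range(max_redraws + 1):
        table = sample_paired_counts(params_true, dep_true, n, rng)
        if table.n_diseased >= 1 and table.n_nondiseased >= 1:
            return table, attempt
    raise RuntimeError(
        f"no non-degenerate paired sample in {max_redraws} redraws (n={n})"
    )


def _draw_unpaired_nondegenerate(params_true, n_per_arm, rng, max_redraws=1000):
    from .simulation import sample_unpaired_counts

    for attempt in range(max_redraws + 1):
        counts = sample_unpaired_counts(params_true, n_per_arm, rng)
        if min(counts.n_d_e, counts.n_d_c, counts.n_nd_e, counts.n_nd_c) >= 1:
            return counts, attempt
    raise RuntimeError(
        f"no non-degenerate unpaired sample in {max_redraws} redraws (n={n_per_arm})"
    )


def run_adaptive_trial(
    spec: DesignSpec,
    params_true: AccuracyParams,
    params_assumed: AccuracyParams,
    dep_true: Optional[PairedDependence],
    rng: np.random.Generator,
) -> AdaptiveTrialRecord:
    """Simulate one trial under the blinded adaptive design.

    Data are generated from ``params_true``/``dep_true``; all planning and
    re-estimation steps use ``params_assumed`` (with nuisance parameters
    replaced by their blinded interim estimates).  Interim participants are
    retained in the final analysis.  Deterministic given ``rng``'s state.
    """
    if spec.design_kind == "paired":
        if dep_true is None:
            raise ValueError("paired simulation requires the true dependence")
        initial = minimal_sample_size_paired(spec, params_assumed)
        n_interim = interim_size(spec, initial)
        table, redraws = _draw_paired_nondegenerate(params_true, dep_true, n_interim, rng)
        est = interim_estimates(table)
        re_sized = reestimate_sample_size(spec, params_assumed, est)
        n_final = re_sized.n_final
        if n_final > n_interim:
            from .simulation import sample_paired_counts

            table = table + sample_paired_counts(
                params_true, dep_true, n_final - n_interim, rng
            )
        ci_se, ci_sp, reject = analyze_paired(table, spec.alpha)
        counts: Union[PairedCountTable, UnpairedCounts] = table
    else:
        initial = optimal_sample_size(spec, params_assumed)
        n_interim = interim_size(spec, initial)
        interim_counts, redraws = _draw_unpaired_nondegenerate(
            params_true, n_interim, rng
        )
        n_d = interim_counts.n_d_e + interim_counts.n_d_c
        est = InterimEstimates(
            pi_hat=estimate_prevalence(n_d, 2 * n_interim),
            n_interim=n_interim,
        )
        re_sized = reestimate_sample_size(spec, params_assumed, est)
        n_final = re_sized.n_final
        counts = interim_counts
        if n_final > n_interim:
            from .simulation import sample_unpaired_counts

            extra = sample_unpaired_counts(params_true, n_final - n_interim, rng)
            counts = UnpairedCounts(
                *(getattr(interim_counts, f) + getattr(extra, f)
                  for f in ("tp_e", "n_d_e", "tn_e", "n_nd_e",
                            "tp_c", "n_d_c", "tn_c", "n_nd_c"))
            )
        ci_se, ci_sp, reject = analyze_unpaired(counts, spec.alpha)

    return AdaptiveTrialRecord(
        design_kind=spec.design_kind,
        n_initial=initial.n_final,
        n_interim=n_interim,
        estimates=est,
        n_final=n_final,
        counts=counts,
        ci_se=ci_se,
        ci_sp=ci_sp,
        reject=reject,
        n_redraws=redraws,
    )
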