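"""Sample-size calculations for comparative diagnostic accuracy trials.

Two index tests (experimental vs. comparator) are compared against a
reference standard on the co-primary endpoints sensitivity and specificity.
Diseased participants inform sensitivity, non-diseased participants
specificity, so per-status requirements are scaled by the prevalence ``pi``
(respectively ``1 - pi``) into endpoint-specific totals ``N_Se = n_D / pi``
and ``N_Sp = n_ND / (1 - pi)``.

Two planning strategies are provided:

* ``conventional`` - size each endpoint at a fixed per-endpoint power and
  recruit the maximum of the two totals.  Simple, but the non-binding
  endpoint is overpowered and the total exceeds what the target overall
  power requires.
* ``optimal`` - split the overall power between the endpoints so the two
  totals coincide (see :mod:`copriss.core_design`); the common total is
  the smallest sample achieving the target overall power.

Paired design kernels use the Miettinen-type formula driven by the
discordance proportions ``psi_D``/``psi_ND`` (probability the two index
tests disagree within a disease stratum); the unpaired design uses the
classical two-independent-proportions formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

from .core_design import (
    AccuracyParams,
    DesignSpec,
    PowerSplit,
    normal_quantile,
    solve_power_split,
)
from .exceptions import InvalidDependenceError, ZeroDifferenceError

__all__ = [
    "PairedDependence",
    "SampleSizeResult",
    "n_diseased_paired",
    "n_nondiseased_paired",
    "unpaired_variance",
    "n_diseased_unpaired",
    "n_nondiseased_unpaired",
    "conventional_sample_size",
    "optimal_sample_size",
    "minimal_sample_size_paired",
    "psi_bounds",
    "psi_min",
]

_BOUND_TOL = 1e-12


def psi_bounds(p_c: float, p_e: float) -> Tuple[float, float]:
    """Admissible interval for a discordance proportion.

    Given the two tests' marginal accuracies ``p_c``, ``p_e`` within a
    disease stratum, the probability that the tests disagree is bounded
    below by ``|p_c - p_e|`` (maximal dependence) and above by
    ``p_c + p_e - 2 p_c p_e`` (the value under independence is already the
    Frechet upper bound for nonnegatively dependent tests).
    """
    return abs(p_c - p_e), p_c + p_e - 2.0 * p_c * p_e


def psi_min(p_c: float, p_e: float) -> float:
    """Minimal possible discordance proportion, ``|p_c - p_e|``."""
    return abs(p_c - p_e)


@dataclass(frozen=True)
class PairedDependence:
    """Discordance proportions linking the two tests in a paired design.

    ``psi_d`` (``psi_nd``) is the probability that the experimental and
    comparator tests give different results for a diseased (non-diseased)
    participant.  Admissibility against specific marginal accuracies is
    checked by :func:`validate_against`, since the bounds depend on them.
    """

    psi_d: float
    psi_nd: float

    def __post_init__(self) -> None:
        for name in ("psi_d", "psi_nd"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def validate_against(self, params: AccuracyParams) -> None:
        """Check both proportions against their accuracy-implied bounds.

        Values below the lower bound ``|p_c - p_e|`` are errors: the sizing
        formula's radicand turns negative there.  Values above the
        independence value only indicate negative dependence relative to
        the *given* accuracies - the formula stays well defined (interim
        estimates routinely land there when planning assumptions are
        wrong), so this raises a warning, not an error.
        """
        for name, value, (p_c, p_e) in (
            ("psi_d", self.psi_d, (params.se_c, params.se_e)),
            ("psi_nd", self.psi_nd, (params.sp_c, params.sp_e)),
        ):
            lo, hi = psi_bounds(p_c, p_e)
            if value < lo - _BOUND_TOL:
                raise InvalidDependenceError(
                    f"{name} = {value} below the minimal discordance "
                    f"{lo:.6g} for accuracies ({p_c}, {p_e})"
                )
            if value > hi + _BOUND_TOL:
                warnings.warn(
                    f"{name} = {value} above the independence value {hi:.6g} "
                    f"for accuracies ({p_c}, {p_e}): negative dependence",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size calculation.

    ``n_diseased_raw`` / ``n_nondiseased_raw`` are the unrounded per-status
    requirements; ``n_se_total`` / ``n_sp_total`` the unrounded totals
    after prevalence scaling; ``n_final`` the integer recruitment target.
    For the unpaired design all sizes are *per randomized arm* (1:1
    allocation); ``n_both_arms`` then reports the study-wide total.
    """

    n_diseased_raw: float
    n_nondiseased_raw: float
    n_se_total: float
    n_sp_total: float
    n_final: int
    split: PowerSplit
    method: str
    design_kind: str

    @property
    def n_diseased(self) -> int:
        """Per-status display value (ceiling of the raw requirement)."""
        return math.ceil(self.n_diseased_raw - _BOUND_TOL)

    @property
    def n_nondiseased(self) -> int:
        return math.ceil(self.n_nondiseased_raw - _BOUND_TOL)

    @property
    def n_se(self) -> int:
        return math.ceil(self.n_se_total - _BOUND_TOL)

    @property
    def n_sp(self) -> int:
        return math.ceil(self.n_sp_total - _BOUND_TOL)

    @property
    def n_both_arms(self) -> Optional[int]:
        """Total across both arms (unpaired design only)."""
        if self.design_kind == "unpaired":
            return 2 * self.n_final
        return None


def _check_diff(name: str, p_c: float, p_e: float) -> float:
    diff = p_c - p_e
    if diff == 0.0:
        raise ZeroDifferenceError(
            f"superiority sizing on {name} requires different accuracies, "
            f"got {name}_c == {name}_e == {p_c}"
        )
    return diff


def _paired_kernel(
    name: str, p_c: float, p_e: float, psi: float, alpha: float, beta: float
) -> float:
    """Miettinen-type per-status requirement for one endpoint of a paired design."""
    diff = _check_diff(name, p_c, p_e)
    if psi <= 0.0:
        raise InvalidDependenceError(f"psi for {name} must be positive, got {psi}")
    radicand = psi * psi - 0.25 * diff * diff * (3.0 + psi)
    if radicand < 0.0:
        raise InvalidDependenceError(
            f"psi = {psi} too small for the {name} difference {abs(diff):.6g}: "
            "negative radicand in the paired sample-size formula"
        )
    z_a = normal_quantile(1.0 - alpha / 2.0)
    z_b = normal_quantile(1.0 - beta)
    numerator = (z_a * psi + z_b * math.sqrt(radicand)) ** 2
    return numerator / (psi * diff * diff)


def n_diseased_paired(
    se_c: float, se_e: float, psi_d: float, alpha: float, beta: float
) -> float:
    """Unrounded number of diseased participants, paired design.

    Implements ``(z_{1-a/2} psi_D + z_{1-b} sqrt(psi_D^2 -
    (Se_C - Se_E)^2 (3 + psi_D) / 4))^2 / (psi_D (Se_C - Se_E)^2)``.
    Symmetric in ``se_c``/``se_e``.
    """
    return _paired_kernel("sensitivity", se_c, se_e, psi_d, alpha, beta)


def n_nondiseased_paired(
    sp_c: float, sp_e: float, psi_nd: float, alpha: float, beta: float
) -> float:
    """Unrounded number of non-diseased participants, paired design."""
    return _paired_kernel("specificity", sp_c, sp_e, psi_nd, alpha, beta)


def unpaired_variance(p1: float, p2: float) -> float:
    """Variance kernel of a difference of independent proportions.

    ``p1 (1 - p1) + p2 (1 - p2)``; at most 0.5, zero only at degenerate
    proportions.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return p1 * (1.0 - p1) + p2 * (1.0 - p2)


def _unpaired_kernel(
    name: str, p_c: float, p_e: float, alpha: float, beta: float
) -> float:
    diff = _check_diff(name, p_c, p_e)
    # Null-hypothesis variance at the pooled proportion, alternative
    # variance at the assumed accuracies.
    pbar = 0.5 * (p_c + p_e)
    v0 = 2.0 * pbar * (1.0 - pbar)
    va = unpaired_variance(p_c, p_e)
    z_a = normal_quantile(1.0 - alpha / 2.0)
    z_b = normal_quantile(1.0 - beta)
    return (z_a * math.sqrt(v0) + z_b * math.sqrt(va)) ** 2 / (diff * diff)


def n_diseased_unpaired(se_c: float, se_e: float, alpha: float, beta: float) -> float:
    """Unrounded diseased participants *per arm*, unpaired design."""
    return _unpaired_kernel("sensitivity", se_c, se_e, alpha, beta)


def n_nondiseased_unpaired(sp_c: float, sp_e: float, alpha: float, beta: float) -> float:
    """Unrounded non-diseased participants *per arm*, unpaired design."""
    return _unpaired_kernel("specificity", sp_c, sp_e, alpha, beta)


def _kernels(spec: DesignSpec, params: AccuracyParams, dep: Optional[PairedDependence]):
    """Per-status requirement functions of beta for the active design."""
    if spec.design_kind == "paired":
        if dep is None:
            raise ValueError("paired design requires a PairedDependence")
        dep.validate_against(params)

        def k_se(beta: float) -> float:
            return n_diseased_paired(params.se_c, params.se_e, dep.psi_d, spec.alpha, beta)

        def k_sp(beta: float) -> float:
            return n_nondiseased_paired(
                params.sp_c, params.sp_e, dep.psi_nd, spec.alpha, beta
            )

    else:
        if dep is not None:
            raise ValueError("unpaired design takes no PairedDependence")

        def k_se(beta: float) -> float:
            return n_diseased_unpaired(params.se_c, params.se_e, spec.alpha, beta)

        def k_sp(beta: float) -> float:
            return n_nondiseased_unpaired(params.sp_c, params.sp_e, spec.alpha, beta)

    return k_se, k_sp


def _assemble(
    spec: DesignSpec,
    params: AccuracyParams,
    split: PowerSplit,
    n_d: float,
    n_nd: float,
    method: str,
) -> SampleSizeResult:
    pi = params.prevalence
    n_se_total = n_d / pi
    n_sp_total = n_nd / (1.0 - pi)
    # Rounding happens once, on the total: per-status sizes stay unrounded
    # through the prevalence scaling.
    n_final = math.ceil(max(n_se_total, n_sp_total) - _BOUND_TOL)
    return SampleSizeResult(
        n_diseased_raw=n_d,
        n_nondiseased_raw=n_nd,
        n_se_total=n_se_total,
        n_sp_total=n_sp_total,
        n_final=n_final,
        split=split,
        method=method,
        design_kind=spec.design_kind,
    )


def conventional_sample_size(
    spec: DesignSpec,
    params: AccuracyParams,
    dep: Optional[PairedDependence] = None,
    power_se: float = 0.9,
    power_sp: float = 0.9,
) -> SampleSizeResult:
    """Maximum-based sizing at fixed per-endpoint powers.

    Each endpoint is sized at its own power (default 0.9 each, for a
    theoretical overall power near 0.8), totals are obtained by prevalence
    scaling, and the final size is the ceiling of the larger total.
    """
    k_se, k_sp = _kernels(spec, params, dep)
    split = PowerSplit(beta_se=1.0 - power_se, beta_sp=1.0 - power_sp)
    return _assemble(spec, params, split, k_se(split.beta_se), k_sp(split.beta_sp), "conventional")


def optimal_sample_size(
    spec: DesignSpec,
    params: AccuracyParams,
    dep: Optional[PairedDependence] = None,
) -> SampleSizeResult:
    """Equalized sizing under the overall-power constraint.

    Solves for the power split at which the two unrounded endpoint totals
    coincide, then rounds the common total up once.
    """
    k_se, k_sp = _kernels(spec, params, dep)
    pi = params.prevalence

    split = solve_power_split(
        lambda beta_se: k_se(beta_se) / pi,
        lambda beta_sp: k_sp(beta_sp) / (1.0 - pi),
        spec.power_overall,
    )
    return _assemble(spec, params, split, k_se(split.beta_se), k_sp(split.beta_sp), "optimal")


def minimal_sample_size_paired(spec: DesignSpec, params: AccuracyParams) -> SampleSizeResult:
    """Optimal paired size at the minimal admissible discordance.

    Evaluates :func:`optimal_sample_size` at ``psi = |p_c - p_e|`` for both
    strata (maximal dependence between the tests).  Because the paired
    total is monotone increasing in both discordance proportions, this is
    a lower bound over all admissible dependence structures and serves as
    initial and interim sample size of the blinded adaptive design.
    """
    if spec.design_kind != "paired":
        raise ValueError("minimal sample size is defined for the paired design only")
    dep = PairedDependence(
        psi_d=psi_min(params.se_c, params.se_e),
        psi_nd=psi_min(params.sp_c, params.sp_e),
    )
    result = optimal_sample_size(spec, params, dep)
    return SampleSizeResult(
        n_diseased_raw=result.n_diseased_raw,
        n_nondiseased_raw=result.n_nondiseased_raw,
        n_se_total=result.n_se_total,
        n_sp_total=result.n_sp_total,
        n_final=result.n_final,
        split=result.split,
        method="minimal",
        design_kind=result.design_kind,
    )
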