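"""Shared design parameters and the optimal power split.

A comparative diagnostic accuracy trial has two co-primary endpoints,
sensitivity and specificity, combined through an Intersection-Union test:
the trial succeeds only if superiority is shown on *both* endpoints, so the
overall power is the product of the per-endpoint powers,

    Power_Se * Power_Sp = Power_overall.

Each endpoint implies its own total sample size once its power is fixed
(diseased participants scaled by the prevalence for sensitivity,
non-diseased scaled by 1 - prevalence for specificity).  The *optimal*
power split allocates the overall power between the endpoints so that the
two endpoint-specific totals coincide; the common value is then the
smallest total sample size that achieves the target overall power.  The
split has no closed form and is found here by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.stats import norm

from .exceptions import ConvergenceError, InfeasiblePowerError

__all__ = [
    "DesignSpec",
    "AccuracyParams",
    "PowerSplit",
    "normal_quantile",
    "complement_beta",
    "solve_power_split",
]

#: Offset keeping the bisection bracket strictly inside the feasible
#: interval; at its edges one endpoint's power tends to 1 and the normal
#: quantile diverges.
_BRACKET_EPS = 1e-9


def normal_quantile(p: float) -> float:
    """Standard-normal inverse CDF at ``p`` (e.g. ``z_{1-alpha/2}``).

    Raises
    ------
    ValueError
        If ``p`` is not strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    return float(norm.ppf(p))


def _check_probability(name: str, value: float, open_interval: bool = True) -> None:
    if open_interval:
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {value}")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class DesignSpec:
    """Trial-level design choices shared by both endpoints.

    Parameters
    ----------
    design_kind
        ``"paired"`` (every participant receives both index tests and the
        reference standard) or ``"unpaired"`` (random assignment to one
        index test).
    alpha
        Two-sided significance level applied *per endpoint*; the
        Intersection-Union structure needs no multiplicity adjustment.
    power_overall
        Target probability of rejecting both endpoint nulls.
    hypothesis
        Only ``"superiority"`` is supported.
    """

    design_kind: str
    alpha: float = 0.05
    power_overall: float = 0.8
    hypothesis: str = "superiority"

    def __post_init__(self) -> None:
        if self.design_kind not in ("paired", "unpaired"):
            raise ValueError(
                f"design_kind must be 'paired' or 'unpaired', got {self.design_kind!r}"
            )
        if self.hypothesis != "superiority":
            raise ValueError(
                f"only 'superiority' hypotheses are supported, got {self.hypothesis!r}"
            )
        _check_probability("alpha", self.alpha)
        _check_probability("power_overall", self.power_overall)


@dataclass(frozen=True)
class AccuracyParams:
    """Accuracy assumptions of a planned comparison.

    ``se_c``/``sp_c`` are the comparator test's sensitivity and specificity,
    ``se_e``/``sp_e`` the experimental test's, and ``prevalence`` the
    proportion of diseased individuals among all recruited.
    """

    se_c: float
    se_e: float
    sp_c: float
    sp_e: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("se_c", "se_e", "sp_c", "sp_e", "prevalence"):
            _check_probability(name, getattr(self, name))

    @property
    def se_diff(self) -> float:
        """Sensitivity difference experimental minus comparator."""
        return self.se_e - self.se_c

    @property
    def sp_diff(self) -> float:
        """Specificity difference experimental minus comparator."""
        return self.sp_e - self.sp_c


@dataclass(frozen=True)
class PowerSplit:
    """Per-endpoint type-II errors allocating the overall power."""

    beta_se: float
    beta_sp: float

    def __post_init__(self) -> None:
        _check_probability("beta_se", self.beta_se)
        _check_probability("beta_sp", self.beta_sp)

    @property
    def power_se(self) -> float:
        return 1.0 - self.beta_se

    @property
    def power_sp(self) -> float:
        return 1.0 - self.beta_sp

    @property
    def power_overall(self) -> float:
        """Product of the per-endpoint powers (Intersection-Union power)."""
        return self.power_se * self.power_sp


def complement_beta(beta_se: float, power_overall: float) -> float:
    """Type-II error on specificity implied by ``beta_se`` and the target.

    Solves ``(1 - beta_se) * (1 - beta_sp) = power_overall`` for
    ``beta_sp``.  Feasibility requires the sensitivity power ``1 - beta_se``
    to exceed the overall target, otherwise the specificity endpoint would
    need power above one.
    """
    _check_probability("beta_se", beta_se)
    _check_probability("power_overall", power_overall)
    power_se = 1.0 - beta_se
    if power_se <= power_overall:
        raise InfeasiblePowerError(
            f"power on sensitivity (1 - beta_se = {power_se}) must exceed the "
            f"overall power target {power_overall}"
        )
    return 1.0 - power_overall / power_se


def solve_power_split(
    n_se: Callable[[float], float],
    n_sp: Callable[[float], float],
    power_overall: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PowerSplit:
    """Find the power split equalizing the two endpoint-specific totals.

    Parameters
    ----------
    n_se, n_sp
        Unrounded endpoint-specific *total* sample sizes as functions of
        the endpoint's type-II error (``n_se(beta_se)``, ``n_sp(beta_sp)``);
        both must be strictly increasing in the endpoint's power and finite
        on the open feasible interval ``power_se in (power_overall, 1)``.
    power_overall
        Target overall power; fixes ``beta_sp`` given ``beta_se`` through
        :func:`complement_beta`.
    tol
        Bisection tolerance on ``power_se``.

    Returns
    -------
    PowerSplit
        The unique split where ``n_se == n_sp`` (before any rounding).

    Raises
    ------
    ConvergenceError
        If the gap ``n_se - n_sp`` does not change sign on the feasible
        interval, or bisection fails to reach ``tol`` within ``max_iter``
        iterations.  There is no analytic solution, so failures are
        reported rather than truncated.
    """
    _check_probability("power_overall", power_overall)

    def gap(power_se: float) -> float:
        beta_se = 1.0 - power_se
        beta_sp = complement_beta(beta_se, power_overall)
        return n_se(beta_se) - n_sp(beta_sp)

    lo = power_overall + _BRACKET_EPS
    hi = 1.0 - _BRACKET_EPS
    g_lo = gap(lo)
    g_hi = gap(hi)
    if g_lo == 0.0:
        root = lo
    elif g_hi == 0.0:
        root = hi
    elif g_lo > 0.0 and g_hi > 0.0:
        # The sensitivity total dominates over the whole feasible interval:
        # the totals never cross and the constrained optimum sits at the
        # boundary, power_se = power_overall with the specificity endpoint
        # effectively overpowered.  The final size is then the sensitivity
        # requirement alone (the maximum in the caller picks it up).
        root = lo
    elif g_lo < 0.0 and g_hi < 0.0:
        # Mirror case: specificity dominates everywhere.
        root = hi
    else:
        # gap is strictly increasing in power_se: raising the sensitivity
        # power inflates N_Se and, through the power product, deflates N_Sp.
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            g_mid = gap(mid)
            if g_mid == 0.0:
                lo = hi = mid
                break
            if (g_mid > 0.0) == (g_hi > 0.0):
                hi, g_hi = mid, g_mid
            else:
                lo, g_lo = mid, g_mid
            if hi - lo <= tol:
                break
        else:
            raise ConvergenceError(
                f"power-split bisection did not converge to {tol} within "
                f"{max_iter} iterations (bracket width {hi - lo:.3g})"
            )
        root = 0.5 * (lo + hi)

    beta_se = 1.0 - root
    beta_sp = complement_beta(beta_se, power_overall)
    if not math.isfinite(n_se(beta_se)) or not math.isfinite(n_sp(beta_sp)):
        raise ConvergenceError("endpoint totals non-finite at the solved split")
    return PowerSplit(beta_se=beta_se, beta_sp=beta_sp)
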