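"""Confidence intervals for differences of proportions and the IUT decision.

The trial's final analysis compares the two index tests on each endpoint
with a two-sided confidence interval for the difference of proportions:

* unpaired design - score interval for the difference of two independent
  proportions, with the variance evaluated at the restricted maximum
  likelihood estimates under the hypothesized difference
  (Farrington-Manning / Miettinen-Nurminen construction);
* paired design - Tango's asymptotic score interval for the difference of
  two matched proportions, profiling the nuisance discordance probability
  at its constrained MLE.

Score-type inversions are range preserving (endpoints stay in [-1, 1]) and
have coverage closer to nominal than Wald intervals, which is why they are
preferred here; a Wald interval is provided for reference.

Superiority on the co-primary endpoints is declared by the
Intersection-Union rule: both intervals must lie entirely above their
margins (zero for superiority).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_design import normal_quantile
from .exceptions import ConvergenceError

__all__ = [
    "ConfidenceInterval",
    "PairedCountTable",
    "UnpairedCounts",
    "wald_ci_diff_independent",
    "score_ci_diff_independent",
    "tango_ci_diff_paired",
    "iut_decision",
]

_EDGE = 1e-12  # keep inversions strictly inside the parameter space


@dataclass(frozen=True)
class ConfidenceInterval:
    """Two-sided interval ``[lower, upper]`` at confidence ``level``."""

    lower: float
    upper: float
    level: float
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class PairedCountTable:
    """Cross-classified results of a paired diagnostic study.

    Within each disease stratum the two index tests are cross-classified by
    their *positive* result indicator (experimental first, comparator
    second).  Among diseased participants a positive result is correct:
    ``d11`` both tests true positive, ``d10`` experimental-only true
    positive, ``d01`` comparator-only, ``d00`` both false negative.  Among
    non-diseased a positive result is incorrect: ``nd11`` both false
    positive, ``nd00`` both true negative, ``nd10``/``nd01`` single false
    positives of the experimental / comparator test.
    """

    d11: int
    d10: int
    d01: int
    d00: int
    nd11: int
    nd10: int
    nd01: int
    nd00: int

    def __post_init__(self) -> None:
        for name in ("d11", "d10", "d01", "d00", "nd11", "nd10", "nd01", "nd00"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"{name} must be a nonnegative integer, got {value}")

    @property
    def n_diseased(self) -> int:
        return self.d11 + self.d10 + self.d01 + self.d00

    @property
    def n_nondiseased(self) -> int:
        return self.nd11 + self.nd10 + self.nd01 + self.nd00

    @property
    def n_total(self) -> int:
        return self.n_diseased + self.n_nondiseased

    def __add__(self, other: "PairedCountTable") -> "PairedCountTable":
        return PairedCountTable(
            *(getattr(self, f) + getattr(other, f)
              for f in ("d11", "d10", "d01", "d00", "nd11", "nd10", "nd01", "nd00"))
        )

    def swap_tests(self) -> "PairedCountTable":
        """Table with the roles of the two index tests exchanged."""
        return PairedCountTable(
            d11=self.d11, d10=self.d01, d01=self.d10, d00=self.d00,
            nd11=self.nd11, nd10=self.nd01, nd01=self.nd10, nd00=self.nd00,
        )


@dataclass(frozen=True)
class UnpairedCounts:
    """Per-arm results of an unpaired diagnostic study.

    Each arm records the diseased participants tested (``n_d_*``) with
    their true positives (``tp_*``) and the non-diseased tested
    (``n_nd_*``) with their true negatives (``tn_*``).
    """

    tp_e: int
    n_d_e: int
    tn_e: int
    n_nd_e: int
    tp_c: int
    n_d_c: int
    tn_c: int
    n_nd_c: int

    def __post_init__(self) -> None:
        for x, n in (("tp_e", "n_d_e"), ("tn_e", "n_nd_e"),
                     ("tp_c", "n_d_c"), ("tn_c", "n_nd_c")):
            if getattr(self, x) < 0 or getattr(self, x) > getattr(self, n):
                raise ValueError(f"{x} must satisfy 0 <= {x} <= {n}")


def wald_ci_diff_independent(
    x1: int, n1: int, x2: int, n2: int, level: float = 0.95
) -> ConfidenceInterval:
    """Wald interval for ``p1 - p2`` from independent binomials.

    Provided for reference only: it is not range preserving and degenerates
    at boundary counts.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be at least 1")
    p1, p2 = x1 / n1, x2 / n2
    z = normal_quantile(0.5 + level / 2.0)
    half = z * math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    est = p1 - p2
    return ConfidenceInterval(est - half, est + half, level, method="wald")


def _fm_restricted_mle(p1_hat, p2_hat, n1, n2, delta):
    """Constrained MLEs of (p1, p2) under p1 - p2 = delta.

    Closed-form solution of the cubic likelihood equation
    (Farrington & Manning); vectorized over ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    theta = n2 / n1
    a = 1.0 + theta
    b = -(1.0 + theta + p1_hat + theta * p2_hat + delta * (theta + 2.0))
    c = delta * delta + delta * (2.0 * p1_hat + theta + 1.0) + p1_hat + theta * p2_hat
    d = -p1_hat * delta * (1.0 + delta)
    v = b**3 / (27.0 * a**3) - b * c / (6.0 * a**2) + d / (2.0 * a)
    disc = np.maximum(b * b / (9.0 * a * a) - c / (3.0 * a), 0.0)
    u = np.where(v >= 0.0, 1.0, -1.0) * np.sqrt(disc)
    u3 = u * u * u
    # u == 0 collapses the trigonometric term; the ratio value is then moot.
    ratio = np.divide(v, u3, out=np.ones_like(v + u3), where=u3 != 0.0)
    w = (np.pi + np.arccos(np.clip(ratio, -1.0, 1.0))) / 3.0
    p1 = 2.0 * u * np.cos(w) - b / (3.0 * a)
    p1 = np.clip(p1, np.maximum(0.0, delta), np.minimum(1.0, 1.0 + delta))
    return p1, p1 - delta


def score_stat_independent(delta, x1, n1, x2, n2, bias_correction=False):
    """Score statistic for H0: ``p1 - p2 = delta`` (vectorized in delta).

    Positive when the observed difference exceeds ``delta``.
    """
    p1_hat, p2_hat = x1 / n1, x2 / n2
    p1t, p2t = _fm_restricted_mle(p1_hat, p2_hat, n1, n2, delta)
    var = p1t * (1.0 - p1t) / n1 + p2t * (1.0 - p2t) / n2
    if bias_correction:  # Miettinen-Nurminen small-sample factor
        n = n1 + n2
        var = var * n / (n - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1_hat - p2_hat - np.asarray(delta, dtype=float)) / np.sqrt(var)
    # Zero variance occurs only at the extremes of the delta range; the
    # estimate minus delta then carries the sign.
    z = np.where(np.isnan(z), 0.0, z)
    return z


def _invert(stat, est, z_crit, tol=1e-8):
    """Invert a monotone (in delta) score statistic into a CI.

    ``stat(delta)`` must be decreasing in ``delta``; endpoints solve
    ``stat = +/- z_crit`` by bisection bracketed at [-1, 1].
    """

    def solve(lo, hi, target):
        # stat(lo) - target >= 0 >= stat(hi) - target by construction
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            val = stat(mid) - target
            if val > 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= tol:
                return 0.5 * (lo + hi)
        raise ConvergenceError("score-interval bisection failed to converge")

    lo_edge, hi_edge = -1.0 + _EDGE, 1.0 - _EDGE
    lower = lo_edge if stat(lo_edge) <= z_crit else solve(lo_edge, est, z_crit)
    upper = hi_edge if stat(hi_edge) >= -z_crit else solve(est, hi_edge, -z_crit)
    return lower, upper


def score_ci_diff_independent(
    x1: int, n1: int, x2: int, n2: int, level: float = 0.95,
    bias_correction: bool = False,
) -> ConfidenceInterval:
    """Score interval for ``p1 - p2`` from independent binomials.

    The interval is the set of differences ``delta`` whose score statistic,
    with variance at the restricted MLE under ``p1 - p2 = delta``, stays
    below the two-sided normal critical value.  ``bias_correction`` applies
    the Miettinen-Nurminen ``n / (n - 1)`` variance factor; the default is
    the plain restricted-MLE (Farrington-Manning) variance.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be at least 1")
    z_crit = normal_quantile(0.5 + level / 2.0)
    est = x1 / n1 - x2 / n2

    def stat(delta):
        return float(score_stat_independent(delta, x1, n1, x2, n2, bias_correction))

    lower, upper = _invert(stat, est, z_crit)
    return ConfidenceInterval(lower, upper, level, method="score")


def tango_score_stat(delta, b, c, n):
    """Tango's paired score statistic for H0: ``p1 - p2 = delta``.

    ``b`` and ``c`` are the discordant counts favoring test 1 and test 2,
    ``n`` the number of pairs.  The nuisance probability of a
    test-2-only success is profiled at its constrained MLE, the positive
    root of a quadratic.  Vectorized in ``delta``; positive when the
    observed difference exceeds ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    A = 2.0 * n
    B = delta * (2.0 * n - b + c) - b - c
    C = -c * delta * (1.0 - delta)
    p21 = (-B + np.sqrt(np.maximum(B * B - 4.0 * A * C, 0.0))) / (2.0 * A)
    var = n * (2.0 * p21 + delta * (1.0 - delta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (b - c - n * delta) / np.sqrt(var)
    z = np.where(np.isnan(z), 0.0, z)
    return z


def tango_ci_diff_paired(b: int, c: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Tango's asymptotic score interval for a paired difference.

    Parameters
    ----------
    b, c
        Discordant pair counts: ``b`` pairs where only the experimental
        test succeeded, ``c`` pairs where only the comparator did.
    n
        Total number of pairs (concordant pairs included).

    Unlike the paired Wald interval this inversion is range preserving and
    remains a proper interval at ``b = c = 0``.
    """
    if n < 1:
        raise ValueError("number of pairs must be at least 1")
    if b < 0 or c < 0 or b + c > n:
        raise ValueError("discordant counts must be nonnegative with b + c <= n")
    z_crit = normal_quantile(0.5 + level / 2.0)
    est = (b - c) / n

    def stat(delta):
        return float(tango_score_stat(delta, b, c, n))

    lower, upper = _invert(stat, est, z_crit)
    return ConfidenceInterval(lower, upper, level, method="tango")


def iut_decision(
    ci_se: ConfidenceInterval,
    ci_sp: ConfidenceInterval,
    margin_se: float = 0.0,
    margin_sp: float = 0.0,
) -> bool:
    """Intersection-Union decision on the co-primary endpoints.

    The global null is rejected iff *both* endpoint intervals lie strictly
    above their margins (zero margins for superiority).  Because each
    endpoint is tested at its own level and both must reject, the global
    type-I error is bounded by the per-endpoint level without adjustment.
    """
    return ci_se.lower > margin_se and ci_sp.lower > margin_sp
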