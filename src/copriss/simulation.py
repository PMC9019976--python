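"""Monte-Carlo operating characteristics of fixed and adaptive designs.

Paired data are generated as correlated bivariate binary outcomes: the
number of diseased participants is binomial in the true prevalence, and
within each disease stratum the two tests' results follow a multinomial
over the four joint outcome cells.  The dependence between the tests is
parametrized by the joint success probability - the probability both
tests are simultaneously correct-positive among diseased (TPPR) or
correct-negative among non-diseased (TNNR) - which maps one-to-one onto
the discordance proportion via ``psi = p_E + p_C - 2 * joint``.

A scenario pairs true generating parameters with the (possibly wrong)
planning assumptions, and the engine measures rejection rate (type-I
error under the null, power under the alternative), the distribution of
the realized sample size against the size a clairvoyant planner would
compute from the true nuisance parameters, and the bias of the blinded
interim estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .adaptive import (
    analyze_paired,
    analyze_unpaired,
    run_adaptive_trial,
)
from .core_design import AccuracyParams, DesignSpec
from .exceptions import InvalidDependenceError
from .intervals import PairedCountTable, UnpairedCounts
from .sample_size import PairedDependence, optimal_sample_size, psi_min

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "psi_to_tppr",
    "tppr_to_psi",
    "sample_paired_counts",
    "sample_unpaired_counts",
    "run_scenario",
    "monte_carlo_halfwidth",
    "initial_scenario",
]


def psi_to_tppr(p_e: float, p_c: float, psi: float) -> float:
    """Joint success probability implied by a discordance proportion.

    ``joint = (p_e + p_c - psi) / 2``; raises if any of the four induced
    joint-outcome cell probabilities would be negative.
    """
    joint = (p_e + p_c - psi) / 2.0
    cells = _joint_cells(p_e, p_c, psi)
    if min(cells) < -1e-12:
        raise InvalidDependenceError(
            f"psi = {psi} incompatible with marginals ({p_e}, {p_c}): "
            f"joint cell probabilities {cells}"
        )
    return joint


def tppr_to_psi(p_e: float, p_c: float, joint: float) -> float:
    """Discordance proportion implied by a joint success probability."""
    return p_e + p_c - 2.0 * joint


def _joint_cells(p_e: float, p_c: float, psi: float):
    """Cell probabilities (both succeed, E only, C only, both fail)."""
    joint = (p_e + p_c - psi) / 2.0
    return (joint, p_e - joint, p_c - joint, 1.0 - p_e - p_c + joint)


def sample_paired_counts(
    params_true: AccuracyParams,
    dep_true: PairedDependence,
    n: int,
    rng: np.random.Generator,
) -> PairedCountTable:
    """Draw one paired study of ``n`` participants.

    Disease status is binomial in the prevalence; within each stratum the
    four cross-classified cells are multinomial with probabilities implied
    by the marginal accuracies and the discordance proportion.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    # psi_to_tppr validates that all four cells are nonnegative
    psi_to_tppr(params_true.se_e, params_true.se_c, dep_true.psi_d)
    psi_to_tppr(params_true.sp_e, params_true.sp_c, dep_true.psi_nd)
    cells_d = np.clip(
        _joint_cells(params_true.se_e, params_true.se_c, dep_true.psi_d), 0.0, 1.0
    )
    cells_nd = np.clip(
        _joint_cells(params_true.sp_e, params_true.sp_c, dep_true.psi_nd), 0.0, 1.0
    )
    n_d = int(rng.binomial(n, params_true.prevalence))
    d11, d10, d01, d00 = rng.multinomial(n_d, cells_d / cells_d.sum()) if n_d else (0, 0, 0, 0)
    # non-diseased cells in success order (both correct-negative first),
    # mapped onto the positive-indicator table layout
    s11, s10, s01, s00 = (
        rng.multinomial(n - n_d, cells_nd / cells_nd.sum()) if n - n_d else (0, 0, 0, 0)
    )
    return PairedCountTable(
        d11=int(d11), d10=int(d10), d01=int(d01), d00=int(d00),
        nd00=int(s11), nd01=int(s10), nd10=int(s01), nd11=int(s00),
    )


def sample_unpaired_counts(
    params_true: AccuracyParams, n_per_arm: int, rng: np.random.Generator
) -> UnpairedCounts:
    """Draw one unpaired study with ``n_per_arm`` participants per arm."""
    if n_per_arm < 0:
        raise ValueError("n_per_arm must be nonnegative")
    pi = params_true.prevalence
    n_d_e = int(rng.binomial(n_per_arm, pi))
    n_d_c = int(rng.binomial(n_per_arm, pi))
    return UnpairedCounts(
        tp_e=int(rng.binomial(n_d_e, params_true.se_e)),
        n_d_e=n_d_e,
        tn_e=int(rng.binomial(n_per_arm - n_d_e, params_true.sp_e)),
        n_nd_e=n_per_arm - n_d_e,
        tp_c=int(rng.binomial(n_d_c, params_true.se_c)),
        n_d_c=n_d_c,
        tn_c=int(rng.binomial(n_per_arm - n_d_c, params_true.sp_c)),
        n_nd_c=n_per_arm - n_d_c,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: truth, planning assumptions, and scale.

    A true discordance proportion below the minimum admissible for the
    true accuracies is lifted to that minimum on construction (the grid of
    scenarios keeps a common nominal value across effect sizes, which can
    undershoot the bound at large effects).
    """

    design_kind: str
    params_true: AccuracyParams
    params_assumed: AccuracyParams
    dep_true: Optional[PairedDependence] = None
    dep_assumed: Optional[PairedDependence] = None
    alpha: float = 0.05
    power_overall: float = 0.8
    n_runs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design_kind not in ("paired", "unpaired"):
            raise ValueError(f"unknown design_kind {self.design_kind!r}")
        if self.design_kind == "paired":
            if self.dep_true is None or self.dep_assumed is None:
                raise ValueError("paired scenarios need dep_true and dep_assumed")
            lifted = PairedDependence(
                psi_d=max(
                    self.dep_true.psi_d,
                    psi_min(self.params_true.se_c, self.params_true.se_e),
                ),
                psi_nd=max(
                    self.dep_true.psi_nd,
                    psi_min(self.params_true.sp_c, self.params_true.sp_e),
                ),
            )
            if lifted != self.dep_true:
                object.__setattr__(self, "dep_true", lifted)
            self.dep_true.validate_against(self.params_true)
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")

    @property
    def spec(self) -> DesignSpec:
        return DesignSpec(
            design_kind=self.design_kind,
            alpha=self.alpha,
            power_overall=self.power_overall,
        )

    @property
    def is_null(self) -> bool:
        """True when both endpoint differences are zero in truth."""
        return (
            self.params_true.se_diff == 0.0 and self.params_true.sp_diff == 0.0
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregated operating characteristics of one scenario."""

    design: str  # "fixed" or "adaptive"
    rejection_rate: float
    n_true: int
    n_mean: float
    rmse_n: float
    bias: Dict[str, float] = field(default_factory=dict)
    mc_halfwidth: float = float("nan")
    n_runs: int = 0
    n_redraws: int = 0
    n_failures: int = 0


def monte_carlo_halfwidth(p: float, n_runs: int) -> float:
    """Half-width ``1.96 * sqrt(p (1 - p) / n_runs)`` of a simulated rate."""
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    return 1.96 * math.sqrt(p * (1.0 - p) / n_runs)


def _true_sized_n(config: ScenarioConfig) -> int:
    """Optimal N a planner knowing the true nuisance parameters would use.

    Accuracy assumptions stay at their planning values; only prevalence
    and dependence come from the truth.
    """
    params = replace(
        config.params_assumed, prevalence=config.params_true.prevalence
    )
    if config.design_kind == "paired":
        dep = config.dep_true
        assert dep is not None
        dep = PairedDependence(
            psi_d=max(dep.psi_d, psi_min(params.se_c, params.se_e)),
            psi_nd=max(dep.psi_nd, psi_min(params.sp_c, params.sp_e)),
        )
        return optimal_sample_size(config.spec, params, dep).n_final
    return optimal_sample_size(config.spec, params).n_final


def _run_fixed(config: ScenarioConfig, rng: np.random.Generator):
    """One fixed-design trial: size from assumptions, no interim."""
    spec = config.spec
    n_fixed = optimal_sample_size(
        spec, config.params_assumed, config.dep_assumed
    ).n_final
    redraws = 0
    if config.design_kind == "paired":
        while True:
            table = sample_paired_counts(
                config.params_true, config.dep_true, n_fixed, rng
            )
            if table.n_diseased >= 1 and table.n_nondiseased >= 1:
                break
            redraws += 1
        _, _, reject = analyze_paired(table, spec.alpha)
    else:
        while True:
            counts = sample_unpaired_counts(config.params_true, n_fixed, rng)
            if min(counts.n_d_e, counts.n_d_c, counts.n_nd_e, counts.n_nd_c) >= 1:
                break
            redraws += 1
        _, _, reject = analyze_unpaired(counts, spec.alpha)
    return reject, n_fixed, redraws


def run_scenario(config: ScenarioConfig, adaptive: bool) -> ScenarioResult:
    """Monte-Carlo evaluation of one scenario.

    Per-run randomness comes from substreams spawned deterministically
    from the scenario seed, so results are reproducible and independent of
    run order.  Runs that fail (e.g. no non-degenerate sample) are counted
    and re-raised only if all runs fail.
    """
    spec = config.spec
    n_true = _true_sized_n(config)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_runs)

    rejects = np.empty(config.n_runs, dtype=bool)
    n_finals = np.empty(config.n_runs, dtype=float)
    pis, psis_d, psis_nd = [], [], []
    redraws = 0
    failures = 0
    last_error: Optional[Exception] = None

    with warnings.catch_warnings():
        # interim discordance below the admissible floor is routine in
        # H0-style scenarios; the per-run clamp warning would flood logs
        warnings.simplefilter("ignore", UserWarning)
        for i, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            try:
                if adaptive:
                    record = run_adaptive_trial(
                        spec,
                        config.params_true,
                        config.params_assumed,
                        config.dep_true,
                        rng,
                    )
                    rejects[i] = record.reject
                    n_finals[i] = record.n_final
                    redraws += record.n_redraws
                    pis.append(record.estimates.pi_hat)
                    if record.estimates.psi_d_hat is not None:
                        psis_d.append(record.estimates.psi_d_hat)
                        psis_nd.append(record.estimates.psi_nd_hat)
                else:
                    reject, n_fixed, r = _run_fixed(config, rng)
                    rejects[i] = reject
                    n_finals[i] = n_fixed
                    redraws += r
            except Exception as exc:  # per-run failures are counted, not dropped
                rejects[i] = False
                n_finals[i] = np.nan
                failures += 1
                last_error = exc

    if failures == config.n_runs and last_error is not None:
        raise last_error
    ok = ~np.isnan(n_finals)
    rate = float(np.mean(rejects[ok]))
    n_mean = float(np.mean(n_finals[ok]))
    rmse = float(np.sqrt(np.mean((n_finals[ok] - n_true) ** 2)))

    bias: Dict[str, float] = {}
    if adaptive:
        bias["pi"] = _relative_bias(pis, config.params_true.prevalence)
        if psis_d:
            assert config.dep_true is not None
            bias["psi_d"] = _relative_bias(psis_d, config.dep_true.psi_d)
            bias["psi_nd"] = _relative_bias(psis_nd, config.dep_true.psi_nd)

    return ScenarioResult(
        design="adaptive" if adaptive else "fixed",
        rejection_rate=rate,
        n_true=n_true,
        n_mean=n_mean,
        rmse_n=rmse,
        bias=bias,
        mc_halfwidth=monte_carlo_halfwidth(rate, int(ok.sum())),
        n_runs=int(ok.sum()),
        n_redraws=redraws,
        n_failures=failures,
    )


def _relative_bias(values, truth: float) -> float:
    if truth == 0.0:
        return float("nan")
    return (float(np.mean(values)) - truth) / truth


def initial_scenario(
    design_kind: str = "paired",
    under_null: bool = False,
    n_runs: int = 10_000,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """The simulation study's base scenario.

    Comparator accuracies 0.8 / 0.7 with a planned +0.1 improvement on
    both endpoints, true prevalence 0.2 assumed at 0.3, true discordance
    (0.11, 0.14) assumed at (0.18, 0.24); per-endpoint two-sided 0.05 and
    overall target power 0.8.  ``under_null`` sets both true effects to
    zero while keeping the planning assumptions.  ``overrides`` replace
    individual fields (e.g. ``psi_d_true=0.26`` or ``pi_true=0.6``).
    """
    values = dict(
        se_c=0.8, sp_c=0.7, se_effect=0.1, sp_effect=0.1,
        pi_true=0.2, pi_assumed=None,
        psi_d_true=0.11, psi_nd_true=0.14,
        psi_d_assumed=0.18, psi_nd_assumed=0.24,
        alpha=0.05, power_overall=0.8,
    )
    unknown = set(overrides) - set(values)
    if unknown:
        raise TypeError(f"unknown scenario overrides: {sorted(unknown)}")
    values.update(overrides)
    if values["pi_assumed"] is None:
        values["pi_assumed"] = values["pi_true"] + 0.1

    se_e_true = values["se_c"] + (0.0 if under_null else values["se_effect"])
    sp_e_true = values["sp_c"] + (0.0 if under_null else values["sp_effect"])
    params_true = AccuracyParams(
        se_c=values["se_c"], se_e=se_e_true,
        sp_c=values["sp_c"], sp_e=sp_e_true,
        prevalence=values["pi_true"],
    )
    params_assumed = AccuracyParams(
        se_c=values["se_c"], se_e=values["se_c"] + values["se_effect"],
        sp_c=values["sp_c"], sp_e=values["sp_c"] + values["sp_effect"],
        prevalence=values["pi_assumed"],
    )
    dep_true = dep_assumed = None
    if design_kind == "paired":
        dep_true = PairedDependence(values["psi_d_true"], values["psi_nd_true"])
        dep_assumed = PairedDependence(values["psi_d_assumed"], values["psi_nd_assumed"])
    return ScenarioConfig(
        design_kind=design_kind,
        params_true=params_true,
        params_assumed=params_assumed,
        dep_true=dep_true,
        dep_assumed=dep_assumed,
        alpha=values["alpha"],
        power_overall=values["power_overall"],
        n_runs=n_runs,
        seed=seed,
    )
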