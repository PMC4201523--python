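"""Incremental cost-effectiveness versus the no-treatment control.

The comparator contributes zero cost and zero QALY gain, so the
incremental means equal the treated cohort's means.  Uncertainty is
characterised by a non-parametric bootstrap: each replicate resamples
n patients with replacement jointly for cost and QALY gain (preserving
the within-patient correlation), and records the replicate mean cost,
mean QALY gain and their ratio.  95% confidence intervals use the
percentile method on the replicate cost and QALY means; decision
uncertainty is carried by the cost-effectiveness acceptability curve
(CEAC) rather than an ICER interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, DomainError
from .qaly import EconParams

__all__ = [
    "BootstrapSettings",
    "BootstrapResult",
    "CeacCurve",
    "icer",
    "bootstrap_cua",
    "percentile_interval",
    "ceac",
    "default_wtp_grid",
    "wtp_at_probability",
    "wtp_threshold_from_gdp",
    "convert_currency",
    "verdict",
]


@dataclass
class BootstrapSettings:
    """Resampling configuration: B replicates, seed, CI percentiles."""

    replications: int = 1000
    seed: int = 0
    ci_lower: float = 2.5
    ci_upper: float = 97.5

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise DomainError(f"replications must be >= 1, got {self.replications}")
        if not 0 <= self.ci_lower < self.ci_upper <= 100:
            raise DomainError(
                f"need 0 <= ci_lower < ci_upper <= 100, got ({self.ci_lower}, {self.ci_upper})"
            )


@dataclass
class BootstrapResult:
    """Replicate-level bootstrap output and its point estimates.

    ``delta_cost`` and ``delta_qaly`` are the B replicate incremental
    means; ``icers`` holds each replicate's ratio, NaN where the
    replicate QALY mean was not strictly positive (those replicates are
    excluded from ``mean_icer`` and counted in ``n_excluded``).
    ``mean_icer`` is the arithmetic mean over the retained replicate
    ICERs — the headline statistic — while ``icer_of_means`` is the
    ratio of the point means, reported alongside for transparency.
    """

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    icers: np.ndarray
    mean_cost: float
    cost_ci: tuple[float, float]
    mean_qaly: float
    qaly_ci: tuple[float, float]
    mean_icer: float
    icer_of_means: float
    n_excluded: int
    settings: BootstrapSettings = field(default_factory=BootstrapSettings)

    @property
    def n_replicates(self) -> int:
        return len(self.delta_cost)


@dataclass
class CeacCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    thresholds: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.thresholds.size == 0:
            raise AnalysisError("CEAC grid is empty")
        if np.any(np.diff(self.thresholds) <= 0):
            raise AnalysisError("CEAC grid must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise AnalysisError("CEAC probabilities must lie in [0, 1]")


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio ΔC/ΔE in CNY per QALY."""
    if delta_qaly == 0:
        raise DomainError("ICER undefined for zero incremental QALYs")
    return delta_cost / delta_qaly


def percentile_interval(samples, lo: float, hi: float) -> tuple[float, float]:
    """Percentile interval with linear interpolation between order statistics.

    The endpoint at percentile p sits at rank (n-1)·p/100 (0-based) in
    the sorted sample, interpolating linearly between the bracketing
    order statistics (numpy's default percentile convention).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise AnalysisError("percentile_interval needs a non-empty sample")
    if not lo < hi:
        raise DomainError(f"need lo < hi, got ({lo}, {hi})")
    lo_v, hi_v = np.percentile(x, [lo, hi], method="linear")
    return float(lo_v), float(hi_v)


def bootstrap_cua(costs, qaly_gains, settings: BootstrapSettings) -> BootstrapResult:
    """Bootstrap incremental costs, QALYs and ICERs for one cohort.

    ``costs`` and ``qaly_gains`` are parallel per-patient arrays.  Each
    of B replicates draws n patient indices with replacement and takes
    the two means over the same indices.  Reproducible under a fixed
    seed (PCG64 generator).
    """
    costs = np.asarray(costs, dtype=float)
    qaly_gains = np.asarray(qaly_gains, dtype=float)
    if costs.size == 0 or costs.shape != qaly_gains.shape:
        raise AnalysisError(
            f"need matching non-empty cost/QALY arrays, got shapes {costs.shape} and {qaly_gains.shape}"
        )
    n = costs.size
    rng = np.random.default_rng(settings.seed)
    idx = rng.integers(0, n, size=(settings.replications, n))
    delta_cost = costs[idx].mean(axis=1)
    delta_qaly = qaly_gains[idx].mean(axis=1)
    ok = delta_qaly > 0
    icers = np.where(ok, delta_cost / np.where(ok, delta_qaly, 1.0), np.nan)
    mean_icer = float(np.mean(icers[ok])) if ok.any() else float("nan")
    mean_cost = float(np.mean(costs))
    mean_qaly = float(np.mean(qaly_gains))
    return BootstrapResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icers=icers,
        mean_cost=mean_cost,
        cost_ci=percentile_interval(delta_cost, settings.ci_lower, settings.ci_upper),
        mean_qaly=mean_qaly,
        qaly_ci=percentile_interval(delta_qaly, settings.ci_lower, settings.ci_upper),
        mean_icer=mean_icer,
        icer_of_means=(mean_cost / mean_qaly) if mean_qaly != 0 else float("nan"),
        n_excluded=int((~ok).sum()),
        settings=settings,
    )


def default_wtp_grid(maximum: float = 150_000.0, step: float = 1_000.0) -> np.ndarray:
    """Willingness-to-pay grid 0..maximum in equal steps (CNY/QALY)."""
    if maximum <= 0 or step <= 0:
        raise DomainError("wtp grid maximum and step must be positive")
    return np.arange(0.0, maximum + step / 2, step)


def ceac(result: BootstrapResult, grid) -> CeacCurve:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold λ the probability is the fraction of bootstrap
    replicates with strictly positive net monetary benefit
    λ·ΔE_b − ΔC_b; a replicate exactly at zero counts as not
    cost-effective.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise AnalysisError("CEAC grid is empty")
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CeacCurve(grid, prob)


def wtp_at_probability(curve: CeacCurve, p: float) -> float:
    """Smallest grid threshold whose acceptability probability reaches p."""
    if not 0 <= p <= 1:
        raise DomainError(f"target probability must lie in [0, 1], got {p}")
    hits = np.nonzero(curve.probability >= p)[0]
    if hits.size == 0:
        raise AnalysisError(
            f"CEAC never reaches probability {p} within its grid "
            f"(max {curve.probability.max():.3f})"
        )
    return float(curve.thresholds[hits[0]])


def wtp_threshold_from_gdp(gdp_per_capita: float, multiplier: float = 3) -> float:
    """WHO-style willingness-to-pay threshold: multiplier × GDP per capita."""
    if gdp_per_capita <= 0 or multiplier <= 0:
        raise DomainError("gdp_per_capita and multiplier must be positive")
    return gdp_per_capita * multiplier


def convert_currency(amount_cny: float, rate_cny_per_usd: float) -> int:
    """Convert CNY to USD at a fixed rate, rounded half-up to whole dollars."""
    if rate_cny_per_usd <= 0:
        raise DomainError("exchange rate must be positive")
    return int(math.floor(amount_cny / rate_cny_per_usd + 0.5))


def verdict(mean_icer: float, params: EconParams) -> str:
    """WHO-convention verdict for an ICER.

    ``highly_cost_effective`` below one GDP per capita,
    ``cost_effective`` below the WTP threshold (3 × GDP by default),
    otherwise ``not_cost_effective``.
    """
    if not np.isfinite(mean_icer):
        return "undetermined"
    if mean_icer < params.gdp_per_capita_cny:
        return "highly_cost_effective"
    if mean_icer < params.wtp_threshold_cny_per_qaly:
        return "cost_effective"
    return "not_cost_effective"
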