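"""Seeded Monte Carlo propagation of concentration and intake uncertainty.

Each scenario (one food, one roasting stage, one population group) carries a
fitted concentration distribution (normal, from the three stage replicates)
and a fitted intake distribution (the Anderson-Darling best fit of the
survey data).  Per iteration, a concentration and an intake are drawn
independently and pushed through the hazard-quotient chain; the resulting
HQ distribution is summarised by its mean, requested percentiles (default
5th and 95th) and the exceedance probability Pr(HQ > 1).  The hazard index
sums the per-food HQ draws within an iteration.

Negative sampled concentrations are retained by default: a normal
concentration model with a large coefficient of variation places real mass
below zero, and the lower summary percentiles of HQ are then legitimately
negative.  Truncation at zero is available as an explicit option for
physically constrained reanalysis.

Reproducibility: one master seed plus the scenario key (food, roast day,
group) deterministically derives an independent substream per scenario, so
adding or removing scenarios never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exposure import ExposureParameters
from .fitting import FittedDistribution, family_frozen

__all__ = [
    "SimulationConfig",
    "ScenarioSpec",
    "RiskDistributionSummary",
    "point_mass",
    "scenario_rng",
    "sample_family",
    "simulate_hq",
    "simulate_hi",
    "percentile",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Iteration count, master seed, truncation policy and summary quantiles."""

    seed: int
    n_iter: int = 10_000
    truncate_negative: bool = False
    percentiles: tuple[float, ...] = (0.05, 0.95)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError(f"n_iter must be >= 1, got {self.n_iter!r}")
        if any(not 0 < q < 1 for q in self.percentiles):
            raise ValueError(f"percentiles must lie in (0, 1): {self.percentiles!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated exposure: food x roasting stage x population group."""

    food: str
    roast_day: int
    group: str
    c_dist: FittedDistribution
    ir_dist: FittedDistribution
    params: ExposureParameters


@dataclass(frozen=True)
class RiskDistributionSummary:
    """Monte Carlo summary of HQ (or HI, with food='ALL') for one scenario."""

    food: str
    roast_day: int
    group: str
    mean: float
    p05: float
    p95: float
    prob_hq_above_1: float
    n_iter: int
    seed: int
    quantiles: dict[float, float] = field(default_factory=dict)


def point_mass(value: float, family: str = "normal") -> FittedDistribution:
    """A degenerate (zero-variance) distribution, for bridging Monte Carlo
    summaries back to deterministic point estimates."""
    if family != "normal":
        raise ValueError("point masses are represented as zero-scale normals")
    return FittedDistribution(
        family="normal",
        params={"loc": float(value), "scale": 0.0},
        n=1,
        loglik=float("nan"),
        ad_stat=float("nan"),
        converged=True,
    )


def scenario_rng(
    seed: int, food: str, roast_day: int, group: str, role: str = ""
) -> np.random.Generator:
    """Independent, reproducible random stream for one scenario component.

    The stream is keyed by a stable hash of (food, roast_day, group, role)
    combined with the master seed, so the draws for a scenario depend only
    on its identity, never on how many other scenarios are simulated.
    """
    key = f"{food}|{roast_day}|{group}|{role}".encode()
    digest = int.from_bytes(hashlib.sha256(key).digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def sample_family(
    dist: FittedDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n inverse-CDF draws from a fitted family on a seeded uniform stream.

    A zero scale is the degenerate limit: every draw equals the location.
    """
    params = dist.params
    scale_like = params.get("scale", params.get("sdlog"))
    if scale_like is not None and scale_like < 0:
        raise ValueError(f"negative scale parameter in {dist.family}: {params}")
    u = rng.uniform(size=n)
    if scale_like == 0:
        loc = params.get("loc")
        if loc is None:
            raise ValueError(f"degenerate {dist.family} has no location")
        return np.full(n, float(loc))
    return np.asarray(family_frozen(dist.family, params).ppf(u), dtype=float)


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile: the k-th order statistic sits at
    probability (k-1)/(n-1).  Fixed convention for reproducibility."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("percentile of an empty vector")
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q!r}")
    return float(np.quantile(x, q, method="linear"))


def _hq_draws(scenario: ScenarioSpec, config: SimulationConfig) -> np.ndarray:
    c_rng = scenario_rng(
        config.seed, scenario.food, scenario.roast_day, scenario.group, "conc"
    )
    ir_rng = scenario_rng(
        config.seed, scenario.food, scenario.roast_day, scenario.group, "intake"
    )
    c = sample_family(scenario.c_dist, config.n_iter, c_rng)
    ir = sample_family(scenario.ir_dist, config.n_iter, ir_rng)
    if config.truncate_negative:
        c = np.maximum(c, 0.0)
        ir = np.maximum(ir, 0.0)
    p = scenario.params
    return c * ir * p.ef * p.ed / (p.bw * p.at * p.rfd)


def _summarize(
    hq: np.ndarray,
    scenario_food: str,
    roast_day: int,
    group: str,
    config: SimulationConfig,
) -> RiskDistributionSummary:
    if config.n_iter < 20 and config.percentiles:
        warnings.warn(
            f"n_iter={config.n_iter} is too small for stable tail percentiles",
            stacklevel=3,
        )
    quantiles = {q: percentile(hq, q) for q in config.percentiles}
    return RiskDistributionSummary(
        food=scenario_food,
        roast_day=roast_day,
        group=group,
        mean=float(np.mean(hq)),
        p05=quantiles.get(0.05, percentile(hq, 0.05)),
        p95=quantiles.get(0.95, percentile(hq, 0.95)),
        prob_hq_above_1=float(np.mean(hq > 1.0)),
        n_iter=config.n_iter,
        seed=config.seed,
        quantiles=quantiles,
    )


def simulate_hq(
    scenario: ScenarioSpec, config: SimulationConfig
) -> RiskDistributionSummary:
    """Monte Carlo HQ distribution for one scenario."""
    hq = _hq_draws(scenario, config)
    return _summarize(hq, scenario.food, scenario.roast_day, scenario.group, config)


def simulate_hi(
    scenarios: Sequence[ScenarioSpec], config: SimulationConfig
) -> RiskDistributionSummary:
    """Monte Carlo hazard index: per-iteration sum of HQ over foods.

    All scenarios must share one group and one roasting day.  Draws are
    independent across foods (each food keeps its own keyed substream).
    """
    if not scenarios:
        raise ValueError("simulate_hi requires at least one scenario")
    groups = {s.group for s in scenarios}
    days = {s.roast_day for s in scenarios}
    if len(groups) > 1 or len(days) > 1:
        raise ValueError(
            f"simulate_hi requires one group and one roast_day, "
            f"got groups={sorted(groups)} days={sorted(days)}"
        )
    hi = np.zeros(config.n_iter)
    for s in scenarios:
        hi += _hq_draws(s, config)
    return _summarize(hi, "ALL", scenarios[0].roast_day, scenarios[0].group, config)
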