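"""Rejection ABC calibration of T-model parameters against mean ring width.

Approximate Bayesian computation in its simplest rejection form: draw
parameter vectors independently from truncated-normal priors (location =
median of published values, sd = half the median), run the forward growth
model, and accept a draw when the simulated mean ring width falls within
+-2.5% of the target.  The posterior is summarized by the accepted draws;
the point estimate used downstream is the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tmodel import SpeciesParams


@dataclass(frozen=True)
class ParamPrior:
    """Truncated normal prior for one positive parameter."""

    median: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.median <= 0 or self.sd <= 0:
            raise ValueError("prior median and sd must be positive")
        if not self.lower < self.median < self.upper:
            raise ValueError("prior bounds must bracket the median")

    def distribution(self) -> stats.rv_continuous:
        a = (self.lower - self.median) / self.sd
        b = (self.upper - self.median) / self.sd
        return stats.truncnorm(a, b, loc=self.median, scale=self.sd)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the free parameters, keyed by SpeciesParams field name."""

    priors: Mapping[str, ParamPrior]

    @property
    def names(self) -> list[str]:
        return list(self.priors)


@dataclass(frozen=True)
class ABCConfig:
    n_draws: int = 10000
    tolerance_fraction: float = 0.025  # the +-2.5% convergence band
    seed: int = 0
    point_estimate: str = "mean"  # or "median"

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.tolerance_fraction <= 0:
            raise ValueError("tolerance_fraction must be positive")
        if self.point_estimate not in ("mean", "median"):
            raise ValueError("point_estimate must be 'mean' or 'median'")


@dataclass
class ABCResult:
    accepted: pd.DataFrame  # one row per accepted draw: parameters + 'summary'
    n_draws: int
    target: float
    tolerance_fraction: float
    point_estimate: dict[str, float] = field(default_factory=dict)
    posterior: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted) / self.n_draws


def build_priors(published_values: Mapping[str, Sequence[float] | float],
                 upper_multiple: float = 4.0, lower: float = 1e-9) -> PriorSpec:
    """Priors from lists of published values per parameter.

    Location = median of the published values; sd = median / 2; truncation at
    0+ and ``upper_multiple`` x median.
    """
    priors = {}
    for name, values in published_values.items():
        vals = np.atleast_1d(np.asarray(values, dtype=float))
        if vals.size == 0:
            raise ValueError(f"no published values for parameter '{name}'")
        med = float(np.median(vals))
        if med <= 0:
            raise ValueError(f"median published value for '{name}' must be positive")
        priors[name] = ParamPrior(median=med, sd=med / 2.0, lower=lower,
                                  upper=upper_multiple * med)
    return PriorSpec(priors)


def abc_rejection(forward: Callable[[dict[str, float]], float], target: float,
                  priors: PriorSpec, config: ABCConfig) -> ABCResult:
    """Rejection ABC: accept draws whose forward summary is within the band.

    ``forward`` maps a draw (dict of the free parameters) to the summary
    statistic (mean simulated ring width, mm).  Acceptance requires
    |summary - target| <= tolerance_fraction * target.  Deterministic given
    the config seed.  Zero acceptances raise rather than silently widening
    the band.
    """
    if target <= 0:
        raise ValueError("target summary must be positive")
    rng = np.random.default_rng(config.seed)
    names = priors.names
    draws = {
        name: priors.priors[name].distribution().rvs(size=config.n_draws, random_state=rng)
        for name in names
    }
    band = config.tolerance_fraction * target
    rows = []
    for i in range(config.n_draws):
        theta = {name: float(draws[name][i]) for name in names}
        summary = forward(theta)
        if np.isfinite(summary) and abs(summary - target) <= band:
            rows.append({**theta, "summary": summary})
    accepted = pd.DataFrame(rows, columns=names + ["summary"])
    if accepted.empty:
        raise RuntimeError(
            f"ABC accepted 0 of {config.n_draws} draws for target {target:.4g} "
            f"(+-{100 * config.tolerance_fraction:.1f}%); increase n_draws or widen "
            "the tolerance explicitly"
        )
    posterior = accepted[names].agg(["mean", "median", "std"]).T
    estimator = accepted[names].mean() if config.point_estimate == "mean" else accepted[names].median()
    return ABCResult(
        accepted=accepted,
        n_draws=config.n_draws,
        target=target,
        tolerance_fraction=config.tolerance_fraction,
        point_estimate={k: float(v) for k, v in estimator.items()},
        posterior=posterior,
    )


def optimize_allocation(forcing, co2_level: float, target_mean_rw: float,
                        fixed: SpeciesParams, config: ABCConfig,
                        priors: PriorSpec | None = None,
                        d0: float = 0.3, ring_years=None):
    """Two-parameter ABC over the allocation parameters (L, zeta) at fixed CO2.

    All other species parameters stay at their (modern-calibrated) values in
    ``fixed``.  The forcing must be prepared; a constant CO2 series at
    ``co2_level`` replaces whatever is attached.  Returns (lai, zeta, result).
    """
    from . import pmodel as _pm
    from .synthetic import generate_co2_series
    from .tmodel import simulate_rings

    run = forcing.copy()
    run.co2 = generate_co2_series(run.years, "constant", co2_level)
    monthly = _pm.run_pmodel(run)
    gpp_annual = _pm.annual_potential_gpp(monthly)
    if ring_years is not None:
        gpp_annual = gpp_annual.loc[[y for y in ring_years if y in gpp_annual.index]]
    if priors is None:
        priors = build_priors({"lai": fixed.lai, "zeta": fixed.zeta})

    def forward(theta: dict[str, float]) -> float:
        params = fixed.with_(**theta)
        return simulate_rings(gpp_annual, params, d0=d0).mean_width()

    result = abc_rejection(forward, target_mean_rw, priors, config)
    return result.point_estimate["lai"], result.point_estimate["zeta"], result


__all__ = [
    "ParamPrior",
    "PriorSpec",
    "ABCConfig",
    "ABCResult",
    "build_priors",
    "abc_rejection",
    "optimize_allocation",
]
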