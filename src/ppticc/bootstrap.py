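"""Parametric-bootstrap confidence intervals for components and ICCs.

Each iteration simulates a fresh balanced dataset from the fitted
variance components, refits it by REML, and evaluates every requested
functional of the refitted components (individual variances, any ICC
variant, any average-measures ICCk).  Percentile intervals are then read
off the bootstrap distribution of each functional.

Conventions (documented because the literature leaves them open):

* percentile method with inverted-CDF empirical quantiles, so with n
  replicates the interval endpoints are order statistics — in particular
  two replicates give exactly [min, max];
* non-converged refits are dropped and counted, never imputed;
* iteration i draws from substream i of the master seed, so the intervals
  do not depend on execution order and are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .reml import FitResult, fit_reml_values
from .simulate import simulate_values
from .types import Design, VarianceComponents

__all__ = ["IntervalEstimate", "parametric_bootstrap", "default_statistics"]

Statistic = Callable[[VarianceComponents], float]


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with percentile-bootstrap bounds at a stated level."""

    point: float
    lower: float
    upper: float
    level: float
    n_iterations: int
    n_failed: int

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def parametric_bootstrap(
    fit: FitResult,
    design: Design,
    statistics: Mapping[str, Statistic],
    n_iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, IntervalEstimate]:
    """Percentile intervals for functionals of the fitted variance components.

    Parameters
    ----------
    fit
        A converged REML fit; its components are the simulation truth.
    design
        Layout of each simulated replicate (normally the observed design;
        a different one answers "what if I had measured more subjects").
    statistics
        Mapping name -> functional of :class:`VarianceComponents`, e.g.
        ``lambda c: construct_icc(c, spec).value`` or an attribute getter
        for a single variance.
    n_iterations, level, seed
        Replicate count (study convention: 1000), confidence level and
        master seed; identical inputs give identical intervals.
    """
    if not fit.converged:
        raise ValueError("refusing to bootstrap from a non-converged fit")
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    if not statistics:
        raise ValueError("statistics list is empty: nothing to bootstrap")

    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_iterations)
    names = list(statistics)
    draws: dict[str, list[float]] = {name: [] for name in names}
    n_failed = 0
    for ss in streams:
        values = simulate_values(design, fit.components, ss)
        refit = fit_reml_values(values)
        if not refit.converged:
            n_failed += 1
            continue
        for name in names:
            draws[name].append(float(statistics[name](refit.components)))
    if n_failed == n_iterations:
        raise RuntimeError("all bootstrap refits failed to converge")

    alpha = 1.0 - level
    out: dict[str, IntervalEstimate] = {}
    for name in names:
        arr = np.asarray(draws[name])
        lo = float(np.quantile(arr, alpha / 2, method="inverted_cdf"))
        hi = float(np.quantile(arr, 1.0 - alpha / 2, method="inverted_cdf"))
        out[name] = IntervalEstimate(
            point=float(statistics[name](fit.components)),
            lower=lo, upper=hi, level=level,
            n_iterations=n_iterations, n_failed=n_failed)
    return out


def default_statistics(k_avg: int = 2, l_avg: int = 10) -> dict[str, Statistic]:
    """The study's reporting panel: five components and four ICC variants."""
    from .icc import ICCSpec, construct_icc, icck_session
    from .types import COMPONENT_NAMES

    stats: dict[str, Statistic] = {}
    for name in COMPONENT_NAMES:
        stats[name] = (lambda c, n=name: getattr(c, n))
    stats["icc_session"] = (
        lambda c: construct_icc(c, ICCSpec(frozenset({"session"}))).value)
    stats["icc_session_reps"] = (
        lambda c: construct_icc(c, ICCSpec(frozenset({"session", "repetition"}))).value)
    stats["icc_session_side_reps"] = (
        lambda c: construct_icc(
            c, ICCSpec(frozenset({"session", "side", "repetition"}))).value)
    stats["icck_session"] = (
        lambda c: icck_session(c, k_avg, l_avg).value)
    return stats
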