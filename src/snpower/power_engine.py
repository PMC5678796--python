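"""Empirical power at fixed n, and sample-size search to a target power.

Power is the fraction of Monte-Carlo replicates in which the Wald z test
detects the genotype effect at level alpha. Each replicate draws its own
RNG substream from the scenario seed, so any replicate is reproducible in
isolation and results do not depend on evaluation order.

The sample-size search brackets the (noisy, monotone) power curve by
doubling n, then bisects on n with a fixed replicate count per
evaluation, returning the smallest evaluated n at the bracket's upper end.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .inference import FitResult, fit_glm, wald_test
from .simcohort import (
    ScenarioConfig,
    code_genotype,
    combine_alleles,
    simulate_alleles,
    simulate_binary_outcome,
    simulate_continuous_outcome,
    subject_effect_sd,
    substream,
)

__all__ = [
    "PowerEstimate",
    "SampleSizeResult",
    "estimate_power",
    "required_sample_size",
    "STREAM_POWER",
    "STREAM_SEARCH",
    "STREAM_PAIRED",
]

# Stream identifiers keep the power estimator, the sample-size search and
# the paired misspecification runs on disjoint substreams of one seed.
STREAM_POWER = 1
STREAM_SEARCH = 2
STREAM_PAIRED = 3

DEFAULT_SEARCH_REPS = 500
DEFAULT_N_CAP = 10_000_000
DEFAULT_N_MIN = 10


@dataclasses.dataclass(frozen=True)
class PowerEstimate:
    """Empirical power with its Monte-Carlo standard error."""

    power: float
    mc_se: float
    reps: int
    n: int
    n_nonconverged: int


@dataclasses.dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the sample-size search.

    ``search_trace`` records every (n, power) evaluation in order;
    ``achieved_power`` is the search-time power at ``n_required``.
    """

    n_required: int
    achieved_power: float
    target_power: float
    search_trace: list


def _family(config: ScenarioConfig) -> str:
    return "logistic" if config.outcome_type == "binary" else "gaussian"


def simulate_replicate(config: ScenarioConfig, n: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts and outcome for one replicate under the true model."""
    a, b = simulate_alleles(n, config.maf, rng)
    allele_count = combine_alleles(a, b)
    g_true = code_genotype(allele_count, config.true_model)
    if config.outcome_type == "binary":
        outcome = simulate_binary_outcome(
            g_true, config.beta0, config.beta1,
            subject_effect_sd(config.baseline_or), rng)
    else:
        outcome = simulate_continuous_outcome(
            g_true, config.beta0, config.beta1, config.trait_sd, rng)
    return allele_count, outcome


def _fit_replicate(config: ScenarioConfig, allele_count: np.ndarray,
                   outcome: np.ndarray, coding: str) -> FitResult:
    g = code_genotype(allele_count, coding)
    return fit_glm(g, outcome, _family(config))


def estimate_power(config: ScenarioConfig, n: Optional[int] = None,
                   reps: Optional[int] = None,
                   stream: int = STREAM_POWER) -> PowerEstimate:
    """Empirical power of the analysis-model Wald test over replicates.

    Cohorts are generated under ``config.true_model`` and fitted under
    ``config.analysis_model``. Replicates where the fit fails (including
    monomorphic draws at very low MAF) count as non-detections; they are
    never resampled, which would bias power upward.
    """
    n = config.n if n is None else int(n)
    reps = config.reps if reps is None else int(reps)
    detections = 0
    nonconverged = 0
    for r in range(reps):
        rng = substream(config.seed, stream, n, r)
        allele_count, outcome = simulate_replicate(config, n, rng)
        fit = _fit_replicate(config, allele_count, outcome,
                             config.analysis_model)
        if not fit.converged:
            nonconverged += 1
        if wald_test(fit, config.alpha):
            detections += 1
    power = detections / reps
    mc_se = math.sqrt(power * (1.0 - power) / reps)
    return PowerEstimate(power=power, mc_se=mc_se, reps=reps, n=n,
                         n_nonconverged=nonconverged)


def required_sample_size(config: ScenarioConfig,
                         search_reps: int = DEFAULT_SEARCH_REPS,
                         n_min: int = DEFAULT_N_MIN,
                         n_cap: int = DEFAULT_N_CAP,
                         rel_tol: float = 0.02) -> SampleSizeResult:
    """Smallest n (up to ``rel_tol`` resolution) reaching the target power.

    Geometric bracketing doubles n until the search-time power estimate
    meets ``config.target_power``, then bisection narrows the bracket to a
    relative width of ``rel_tol``. The returned n is the bracket's upper
    end, so its achieved power is at or above target (and in particular
    within one Monte-Carlo SE of it); the power at the bracket's lower end
    is below target.
    """
    if config.is_null:
        raise ValueError("target power unreachable: effect size is null "
                         "(OR = 1 or beta1 = 0)")
    target = config.target_power
    trace: list[tuple[int, float]] = []

    def power_at(n: int) -> float:
        est = estimate_power(config, n=n, reps=search_reps,
                             stream=STREAM_SEARCH)
        trace.append((n, est.power))
        return est.power

    n = int(n_min)
    p = power_at(n)
    if p >= target:
        return SampleSizeResult(n_required=n, achieved_power=p,
                                target_power=target, search_trace=trace)
    lo, hi, p_hi = n, None, None
    while p < target:
        lo = n
        n *= 2
        if n > n_cap:
            raise RuntimeError(
                f"sample-size bracket exceeded cap {n_cap}; trace={trace}")
        p = power_at(n)
    hi, p_hi = n, p

    while hi - lo > max(1, int(rel_tol * hi)):
        mid = (lo + hi) // 2
        p_mid = power_at(mid)
        if p_mid >= target:
            hi, p_hi = mid, p_mid
        else:
            lo = mid
    return SampleSizeResult(n_required=hi, achieved_power=p_hi,
                            target_power=target, search_trace=trace)
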