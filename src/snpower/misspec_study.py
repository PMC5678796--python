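"""Paired comparison of true-model vs misspecified-model analyses.

Data are generated under a true dominant ("binary") genetic model and each
simulated cohort is fitted twice: once with the correct carrier-indicator
coding and once with the incorrect additive allele-count coding. Because
both arms consume the identical cohort in every replicate, power gaps and
effect-size shrinkage are estimated with paired precision.

Sweeps over MAF grids (sample size at target power, power at fixed n,
shrinkage per arm) and over effect-size grids (mean estimated effect vs
the configured effect) reproduce the study's two headline analyses.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .power_engine import (
    DEFAULT_SEARCH_REPS,
    STREAM_PAIRED,
    PowerEstimate,
    SampleSizeResult,
    _fit_replicate,
    required_sample_size,
    simulate_replicate,
)
from .simcohort import ADDITIVE, DOMINANT, ScenarioConfig, substream

__all__ = [
    "MisspecComparison",
    "run_misspec_scenario",
    "run_maf_sweep",
    "run_effect_sweep",
    "comparison_rows",
    "default_effect_grid",
]

ARMS = ("true", "misspec")
_ARM_CODING = {"true": DOMINANT, "misspec": ADDITIVE}


@dataclasses.dataclass(frozen=True)
class MisspecComparison:
    """Paired results for one scenario (dominant truth).

    ``power_true``/``power_misspec`` come from fitting the same cohorts
    under the dominant and additive codings. ``n_true``/``n_misspec`` are
    sample-size searches per analysis coding (None when not requested).
    ``mean_effect_*`` averages exp(beta_hat) (binary) or beta_hat
    (continuous) over converged replicates; ``shrinkage_*`` is
    ``1 - mean(beta_hat) / beta_true`` on the log-OR scale for binary
    outcomes and the raw coefficient scale for continuous ones.
    """

    scenario: ScenarioConfig
    power_true: PowerEstimate
    power_misspec: PowerEstimate
    n_true: Optional[SampleSizeResult]
    n_misspec: Optional[SampleSizeResult]
    mean_effect_true: float
    mean_effect_misspec: float
    shrinkage_true: float
    shrinkage_misspec: float


def _aggregate_arm(config: ScenarioConfig, betas: list, detections: int,
                   nonconverged: int, reps: int, n: int
                   ) -> tuple[PowerEstimate, float, float]:
    power = detections / reps
    est = PowerEstimate(power=power,
                        mc_se=math.sqrt(power * (1.0 - power) / reps),
                        reps=reps, n=n, n_nonconverged=nonconverged)
    if betas:
        mean_beta = float(np.mean(betas))
        if config.outcome_type == "binary":
            mean_effect = float(np.mean(np.exp(betas)))
        else:
            mean_effect = mean_beta
        shrinkage = 1.0 - mean_beta / config.beta1
    else:
        mean_effect = math.nan
        shrinkage = math.nan
    return est, mean_effect, shrinkage


def run_misspec_scenario(scenario: ScenarioConfig,
                         do_sample_size: bool = True,
                         search_reps: int = DEFAULT_SEARCH_REPS
                         ) -> MisspecComparison:
    """Run one paired true-vs-additive comparison.

    Each replicate simulates a single cohort under the dominant truth and
    fits it under both codings (a recoding of the same allele counts, not
    a regeneration), so the comparison is paired within replicate. When
    ``do_sample_size`` is set, a sample-size search at the scenario's
    target power is run for each analysis coding as well.
    """
    if scenario.true_model != DOMINANT:
        raise ValueError("true_model: misspecification study requires "
                         "dominant_binary truth")
    if scenario.is_null:
        raise ValueError("effect_size: misspecification study requires a "
                         "non-null effect")
    n, reps = scenario.n, scenario.reps
    betas = {arm: [] for arm in ARMS}
    detections = {arm: 0 for arm in ARMS}
    nonconverged = {arm: 0 for arm in ARMS}
    for r in range(reps):
        rng = substream(scenario.seed, STREAM_PAIRED, n, r)
        allele_count, outcome = simulate_replicate(scenario, n, rng)
        for arm in ARMS:
            fit = _fit_replicate(scenario, allele_count, outcome,
                                 _ARM_CODING[arm])
            if fit.converged:
                betas[arm].append(fit.beta_hat)
                if fit.p_value < scenario.alpha:
                    detections[arm] += 1
            else:
                nonconverged[arm] += 1

    results = {arm: _aggregate_arm(scenario, betas[arm], detections[arm],
                                   nonconverged[arm], reps, n)
               for arm in ARMS}
    n_true = n_misspec = None
    if do_sample_size:
        n_true = required_sample_size(
            scenario.replace(analysis_model=DOMINANT), search_reps=search_reps)
        n_misspec = required_sample_size(
            scenario.replace(analysis_model=ADDITIVE), search_reps=search_reps)
    return MisspecComparison(
        scenario=scenario,
        power_true=results["true"][0], power_misspec=results["misspec"][0],
        n_true=n_true, n_misspec=n_misspec,
        mean_effect_true=results["true"][1],
        mean_effect_misspec=results["misspec"][1],
        shrinkage_true=results["true"][2],
        shrinkage_misspec=results["misspec"][2],
    )


def run_maf_sweep(base: ScenarioConfig, maf_grid: Sequence[float],
                  do_sample_size: bool = True,
                  search_reps: int = DEFAULT_SEARCH_REPS
                  ) -> list[MisspecComparison]:
    """Paired comparisons across a MAF grid (sample size, power, shrinkage).

    The grid must be sorted ascending. Every scenario keeps the base seed:
    shared substreams couple the allele draws monotonely across MAFs,
    which sharpens the monotone-trend comparisons.
    """
    if list(maf_grid) != sorted(maf_grid):
        raise ValueError("maf_grid: must be sorted ascending")
    comparisons = []
    for maf in maf_grid:
        scenario = base.replace(maf=float(maf))
        comparisons.append(run_misspec_scenario(
            scenario, do_sample_size=do_sample_size, search_reps=search_reps))
    return comparisons


def default_effect_grid(base: ScenarioConfig) -> list[float]:
    """Eight default effect sizes: OR 1.1..1.8 or beta 0.1..0.8 x trait SD."""
    if base.outcome_type == "binary":
        return [round(1.0 + 0.1 * k, 1) for k in range(1, 9)]
    return [0.1 * k * base.trait_sd for k in range(1, 9)]


def run_effect_sweep(base: ScenarioConfig, effect_grid: Sequence[float],
                     maf_grid: Sequence[float] = (0.008, 0.025, 0.1)
                     ) -> pd.DataFrame:
    """Mean estimated effect per arm across (MAF, effect size) cells.

    Returns one tidy row per (maf, effect_size, arm) with the mean
    estimated effect, the configured expected effect on the same scale,
    and the shrinkage — the per-MAF view of how much the additive coding
    attenuates a dominant effect.
    """
    if len(effect_grid) < 2:
        raise ValueError("effect_grid: need at least 2 effect sizes")
    rows = []
    for maf in maf_grid:
        for effect in effect_grid:
            scenario = base.replace(maf=float(maf), effect_size=float(effect))
            comp = run_misspec_scenario(scenario, do_sample_size=False)
            for arm in ARMS:
                rows.append({
                    "outcome_type": scenario.outcome_type,
                    "maf": maf,
                    "effect_size": effect,
                    "arm": arm,
                    "expected_effect": effect if scenario.outcome_type
                    == "continuous" else scenario.effect_size,
                    "mean_effect": getattr(comp, f"mean_effect_{arm}"),
                    "shrinkage": getattr(comp, f"shrinkage_{arm}"),
                    "power": getattr(comp, f"power_{arm}").power,
                    "n": scenario.n,
                    "reps": scenario.reps,
                    "seed": scenario.seed,
                })
    return pd.DataFrame(rows)


def comparison_rows(comp: MisspecComparison) -> list[dict]:
    """Two schema-conformant result rows (arm = true, misspec)."""
    s = comp.scenario
    rows = []
    for arm in ARMS:
        power: PowerEstimate = getattr(comp, f"power_{arm}")
        size: Optional[SampleSizeResult] = getattr(comp, f"n_{arm}")
        rows.append({
            "outcome_type": s.outcome_type,
            "maf": s.maf,
            "effect_size": s.effect_size,
            "prevalence": s.prevalence,
            "baseline_or": s.baseline_or,
            "trait_sd": s.trait_sd,
            "n": s.n,
            "alpha": s.alpha,
            "target_power": s.target_power,
            "reps": s.reps,
            "arm": arm,
            "power": power.power,
            "mc_se": power.mc_se,
            "n_required": size.n_required if size is not None else math.nan,
            "mean_effect": getattr(comp, f"mean_effect_{arm}"),
            "shrinkage": getattr(comp, f"shrinkage_{arm}"),
            "n_nonconverged": power.n_nonconverged,
            "seed": s.seed,
        })
    return rows
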