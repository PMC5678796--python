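"""Synthetic single-SNP cohort generation.

A bi-allelic SNP is simulated under Hardy-Weinberg equilibrium by drawing
two independent Bernoulli(MAF) allele vectors (one per homologous
chromosome) and summing them into a per-individual risk-allele count.
The count is then coded as a regression covariate under a genetic model:

* ``dominant_binary`` -- complete dominance; carriers (one or two copies of
  the risk allele) share the full effect, so the covariate is a 0/1
  carrier indicator.
* ``additive`` -- effect proportional to the allele count; covariate in
  {0, 1, 2}.

Outcomes are generated from a generalized linear predictor
``LP = beta0 + beta1 * g`` built on the TRUE-model coding:

* binary: a zero-mean normal subject effect (unmeasured heterogeneity in
  disease risk, parameterized by a "baseline odds ratio" between the 95th
  and 5th population risk percentiles) is added to LP, and the outcome is
  Bernoulli(expit(LP)).
* continuous: the outcome is Normal(LP, trait_sd); no subject effect.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DOMINANT",
    "ADDITIVE",
    "Z95",
    "ScenarioConfig",
    "Cohort",
    "substream",
    "derive_seed",
    "simulate_alleles",
    "combine_alleles",
    "code_genotype",
    "beta0_from_prevalence",
    "subject_effect_sd",
    "simulate_binary_outcome",
    "simulate_continuous_outcome",
    "simulate_cohort",
    "cohort_to_frame",
]

DOMINANT = "dominant_binary"
ADDITIVE = "additive"
MODELS = (DOMINANT, ADDITIVE)
OUTCOME_TYPES = ("binary", "continuous")

#: One-sided 95th percentile of the standard normal distribution.
Z95 = 1.6448536269514722


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a reproducible RNG substream for ``(seed, *key)``.

    Streams are derived by counter-based splitting via
    :class:`numpy.random.SeedSequence` spawn keys, so any (stream-id, n,
    replicate) combination yields the same draws regardless of evaluation
    order or parallelization.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def derive_seed(seed: int, index: int) -> int:
    """Derive a scenario-level child seed from a root seed and a counter."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _check(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{field}: {msg}")


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Complete parameterization of one simulation scenario.

    Parameters
    ----------
    maf
        Minor allele frequency, in (0, 1).
    effect_size
        For binary outcomes, the odds ratio per unit of the TRUE-model
        coded genotype (stored internally on the log scale, see
        :attr:`beta1`); for continuous outcomes, the mean shift per unit
        of the TRUE-model coded genotype. ``effect_size == 1`` (binary)
        or ``0`` (continuous) encodes the null.
    outcome_type
        ``"binary"`` or ``"continuous"``.
    n
        Number of individuals per simulated cohort.
    true_model, analysis_model
        Genetic model used to generate outcomes / to code the fitted
        covariate. Misspecification is a recoding of the same allele
        counts, never a regeneration.
    prevalence
        Disease prevalence; sets the binary-outcome intercept.
    baseline_or
        Odds ratio between the 95th and 5th population risk percentile
        attributable to unmeasured determinants (binary outcomes only).
    trait_sd, trait_mean
        Residual SD and intercept of the continuous outcome.
    alpha
        Two-sided significance level of the Wald z test.
    target_power
        Power targeted by the sample-size search.
    reps
        Monte-Carlo replicates.
    seed
        Root RNG seed; all substreams derive from it.
    """

    maf: float
    effect_size: float
    outcome_type: str
    n: int = 1000
    true_model: str = DOMINANT
    analysis_model: str = DOMINANT
    prevalence: float = 0.1
    baseline_or: float = 10.0
    trait_sd: float = 1.0
    trait_mean: float = 0.0
    alpha: float = 0.05
    target_power: float = 0.80
    reps: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        _check(isinstance(self.n, (int, np.integer)) and self.n >= 1, "n",
               "must be a positive integer")
        _check(0.0 < self.maf < 1.0, "maf", "must lie strictly in (0, 1)")
        _check(self.true_model in MODELS, "true_model",
               f"must be one of {MODELS}")
        _check(self.analysis_model in MODELS, "analysis_model",
               f"must be one of {MODELS}")
        _check(self.outcome_type in OUTCOME_TYPES, "outcome_type",
               f"must be one of {OUTCOME_TYPES}")
        if self.outcome_type == "binary":
            _check(self.effect_size > 0.0, "effect_size",
                   "odds ratio must be positive for binary outcomes")
            _check(0.0 < self.prevalence < 1.0, "prevalence",
                   "must lie strictly in (0, 1)")
            _check(self.baseline_or >= 1.0, "baseline_or", "must be >= 1")
        else:
            _check(math.isfinite(self.effect_size), "effect_size",
                   "must be finite")
            _check(self.trait_sd > 0.0, "trait_sd", "must be positive")
        _check(0.0 < self.alpha < 1.0, "alpha", "must lie strictly in (0, 1)")
        _check(0.0 < self.target_power < 1.0, "target_power",
               "must lie strictly in (0, 1)")
        _check(isinstance(self.reps, (int, np.integer)) and self.reps >= 1,
               "reps", "must be a positive integer")
        _check(isinstance(self.seed, (int, np.integer)) and self.seed >= 0,
               "seed", "must be a non-negative integer")

    @property
    def beta1(self) -> float:
        """True effect on the linear-predictor scale (log-OR for binary)."""
        if self.outcome_type == "binary":
            return math.log(self.effect_size)
        return float(self.effect_size)

    @property
    def beta0(self) -> float:
        """Intercept of the linear predictor."""
        if self.outcome_type == "binary":
            return beta0_from_prevalence(self.prevalence)
        return float(self.trait_mean)

    @property
    def is_null(self) -> bool:
        return self.beta1 == 0.0

    def replace(self, **changes) -> "ScenarioConfig":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class Cohort:
    """One simulated sample.

    ``allele_count`` holds per-individual risk-allele counts in {0, 1, 2};
    ``g_coded`` is the covariate under ``coding_used``; ``outcome`` is
    binary {0, 1} or real-valued.
    """

    allele_count: np.ndarray
    g_coded: np.ndarray
    outcome: np.ndarray
    coding_used: str


def simulate_alleles(n: int, maf: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw two independent Bernoulli(``maf``) allele vectors of length ``n``.

    The risk allele is coded 1, the wild allele 0; one vector per
    homologous chromosome.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError("n: must be a positive integer")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf: must lie strictly in (0, 1); "
                         "maf=0 or 1 would produce a monomorphic cohort")
    # Inverse-CDF draws keep substreams aligned across scenarios that share
    # a seed (common random numbers), and couple carriers monotonely in maf.
    a = (rng.random(n) < maf).astype(np.int8)
    b = (rng.random(n) < maf).astype(np.int8)
    return a, b


def combine_alleles(allele_a: np.ndarray, allele_b: np.ndarray) -> np.ndarray:
    """Sum the two allele vectors into genotypes 0 (0+0), 1 (0+1), 2 (1+1)."""
    a = np.asarray(allele_a)
    b = np.asarray(allele_b)
    if a.shape != b.shape:
        raise ValueError("allele vectors: length mismatch")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("allele vectors: entries must be 0 or 1")
    return (a + b).astype(np.int8)


def code_genotype(allele_count: np.ndarray, model: str) -> np.ndarray:
    """Code allele counts as the regression covariate for ``model``.

    ``additive`` is the identity on {0, 1, 2}; ``dominant_binary``
    collapses heterozygotes and homozygous carriers into a single risk
    class (carrier indicator).
    """
    ac = np.asarray(allele_count)
    if not np.isin(ac, (0, 1, 2)).all():
        raise ValueError("allele_count: entries must be in {0, 1, 2}")
    if model == ADDITIVE:
        return ac.astype(np.int8)
    if model == DOMINANT:
        return (ac >= 1).astype(np.int8)
    raise ValueError(f"model: unknown genetic model {model!r}")


def beta0_from_prevalence(prevalence: float) -> float:
    """Log-odds of the disease prevalence (binary-outcome intercept)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence: must lie strictly in (0, 1)")
    return math.log(prevalence / (1.0 - prevalence))


def subject_effect_sd(baseline_or: float) -> float:
    """SD of the subject effect implied by a baseline odds ratio.

    The baseline OR is the odds ratio between an individual at the 95th
    and one at the 5th percentile of population risk. On the log-odds
    scale that contrast spans ``2 * Z95`` standard deviations of the
    zero-mean normal subject effect, hence
    ``sd = ln(baseline_or) / (2 * Z95)``; the 95th-vs-5th odds ratio of
    the simulated effect then equals ``baseline_or`` exactly.
    """
    if baseline_or < 1.0:
        raise ValueError("baseline_or: must be >= 1")
    return math.log(baseline_or) / (2.0 * Z95)


def simulate_binary_outcome(g_coded: np.ndarray, beta0: float,
                            beta1_log_or: float, subject_sd: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(expit(LP)) outcomes with a normal subject effect in LP."""
    if subject_sd < 0.0:
        raise ValueError("subject_sd: must be non-negative")
    g = np.asarray(g_coded, dtype=float)
    # scale=0 is a legal degenerate normal; drawing it anyway keeps the
    # stream aligned with heterogeneous scenarios under a shared seed.
    s_effect = rng.normal(0.0, subject_sd, g.shape[0])
    lp = beta0 + beta1_log_or * g + s_effect
    if not np.isfinite(lp).all():
        raise FloatingPointError("non-finite linear predictor")
    mu = expit(lp)
    return (rng.random(g.shape[0]) < mu).astype(np.int8)


def simulate_continuous_outcome(g_coded: np.ndarray, beta0: float,
                                beta1: float, trait_sd: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Normal(LP, trait_sd) outcomes; no subject effect for this family."""
    if trait_sd < 0.0:
        raise ValueError("trait_sd: must be non-negative")
    g = np.asarray(g_coded, dtype=float)
    lp = beta0 + beta1 * g
    return lp + rng.normal(0.0, trait_sd, g.shape[0])


def simulate_cohort(config: ScenarioConfig,
                    rng: Optional[np.random.Generator] = None,
                    n: Optional[int] = None) -> Cohort:
    """Simulate one cohort under ``config.true_model``.

    The outcome is generated from the TRUE-model coding; analysis-time
    recodings are applied downstream with :func:`code_genotype` so that a
    misspecified analysis sees exactly the same individuals.
    """
    if rng is None:
        rng = substream(config.seed, 0, 0)
    n = config.n if n is None else n
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
    return Cohort(allele_count=allele_count, g_coded=g_true,
                  outcome=outcome, coding_used=config.true_model)


def cohort_to_frame(cohort: Cohort, analysis_model: str) -> pd.DataFrame:
    """Tidy per-individual view of a cohort (debugging export)."""
    return pd.DataFrame({
        "id": np.arange(len(cohort.allele_count)),
        "allele_count": cohort.allele_count,
        "g_true": cohort.g_coded,
        "g_analysis": code_genotype(cohort.allele_count, analysis_model),
        "outcome": cohort.outcome,
    })
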