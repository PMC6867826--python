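"""Analysis layer: replicate ensembles, fixation-probability estimation,
ensemble-average trajectories, the frequency-independence predictor, Kimura's
closed form, two-allele control models, and an exact absorbing-chain oracle.

The central quantity is the fixation probability Pfix(x0) of a modifier allele
started at frequency x0. Under frequency-independent selection the per-capita
fixation probability p1 = Pfix(1/N) is constant, so

    Pfix(x0) = 1 - (1 - p1)^(x0 * N)

i.e. the probability that at least one of the x0*N initial copies fixes. The
predictor :func:`eq1_predict` implements this; comparing it against direct
Monte-Carlo estimates at several x0 is the operational test of frequency
independence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .dfe import DfeSpec, FreqDepParams, freq_dep_s
from .wf_core import (
    ConfigurationError,
    Outcome,
    OutcomeStatus,
    SimParams,
    Trajectory,
    run_until_absorption,
)

__all__ = [
    "EstimationError",
    "FixationEstimate",
    "AverageTrajectory",
    "TwoAlleleParams",
    "derive_seed",
    "run_replicates",
    "estimate_pfix",
    "eq1_predict",
    "kimura_pfix",
    "two_allele_run",
    "two_allele_pfix",
    "average_trajectories",
    "markov_exact_pfix",
]

logger = logging.getLogger(__name__)

_PROGRESS_EVERY = 10_000


class EstimationError(RuntimeError):
    """No usable replicates (e.g. every replicate censored)."""


@dataclass(frozen=True)
class FixationEstimate:
    """Monte-Carlo estimate of Pfix(x0) with a 95% Wilson score interval.

    Censored replicates are excluded from the denominator: the point estimate
    is n_fixed / (n_reps - n_censored). Wilson intervals are used because the
    estimates of interest sit near zero, where Wald intervals misbehave.
    """

    x0: float
    n_reps: int
    n_fixed: int
    n_censored: int
    p_hat: float
    ci_low: float
    ci_high: float
    base_seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ValueError("confidence interval must bracket the point estimate")
        if self.n_fixed + self.n_censored > self.n_reps:
            raise ValueError("n_fixed + n_censored exceeds n_reps")


@dataclass(frozen=True)
class AverageTrajectory:
    """Ensemble-mean modifier frequency per generation over a horizon."""

    horizon: int
    mean_freq: np.ndarray
    n_reps: int
    n_censored: int = 0


@dataclass(frozen=True)
class TwoAlleleParams:
    """A pure two-allele Wright-Fisher model (no background mutation).

    mode "constant_s" uses a fixed selection coefficient ``s_ben``; mode
    "frequency_dependent" recomputes s(x) = b + m_slope*x from the focal
    allele's current frequency every generation.
    """

    N: int
    x0: float
    mode: str = "constant_s"
    s_ben: float = 0.0
    freq_dep: Optional[FreqDepParams] = None
    max_generations: int = 10**6

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if not 0.0 <= self.x0 <= 1.0:
            raise ConfigurationError(f"x0 must be in [0, 1], got {self.x0}")
        if self.mode not in ("constant_s", "frequency_dependent"):
            raise ConfigurationError(f"unknown two-allele mode {self.mode!r}")
        if self.mode == "frequency_dependent" and self.freq_dep is None:
            raise ConfigurationError("frequency_dependent mode requires freq_dep")


def derive_seed(base_seed: int, replicate_id: int) -> np.random.SeedSequence:
    """Deterministic per-replicate RNG stream from (base_seed, replicate_id).

    Uses numpy's SeedSequence entropy-pooling so replicate streams are
    independent of execution order and safe to run in parallel.
    """
    return np.random.SeedSequence([int(base_seed), int(replicate_id)])


def run_replicates(
    params: SimParams,
    dfe: Optional[DfeSpec] = None,
    n_reps: int = 1,
    record: bool = True,
) -> List[Trajectory]:
    """Run ``n_reps`` independent replicates of the mutator engine.

    Replicate r is seeded from (params.base_seed, r); results do not depend on
    execution order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    trajs = []
    for r in range(n_reps):
        trajs.append(
            run_until_absorption(
                params, dfe=dfe, seed=derive_seed(params.base_seed, r),
                record=record, replicate_id=r,
            )
        )
        if (r + 1) % _PROGRESS_EVERY == 0:
            logger.info("replicates completed: %d / %d", r + 1, n_reps)
    _log_tally(trajs)
    return trajs


def _log_tally(trajs: Sequence[Trajectory]) -> None:
    fixed = sum(t.outcome.status is OutcomeStatus.FIXED for t in trajs)
    lost = sum(t.outcome.status is OutcomeStatus.LOST for t in trajs)
    logger.info(
        "outcomes: %d fixed, %d lost, %d censored", fixed, lost, len(trajs) - fixed - lost
    )


def _wilson(n_fixed: int, n_eff: int) -> tuple[float, float]:
    lo, hi = proportion_confint(n_fixed, n_eff, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate_pfix(
    params: SimParams,
    dfe: Optional[DfeSpec] = None,
    n_reps: int = 1,
) -> FixationEstimate:
    """Estimate Pfix(x0) as the fraction of replicates ending in fixation.

    Censored replicates are excluded from the denominator and reported; if all
    replicates are censored no estimate exists and :class:`EstimationError` is
    raised.
    """
    trajs = run_replicates(params, dfe=dfe, n_reps=n_reps, record=False)
    n_fixed = sum(t.outcome.status is OutcomeStatus.FIXED for t in trajs)
    n_cens = sum(t.outcome.status is OutcomeStatus.CENSORED for t in trajs)
    n_eff = n_reps - n_cens
    if n_eff == 0:
        raise EstimationError("all replicates censored; increase max_generations")
    p_hat = n_fixed / n_eff
    lo, hi = _wilson(n_fixed, n_eff)
    # Wilson endpoints can round-trip outside [lo, p, hi] at the boundaries
    lo, hi = min(lo, p_hat), max(hi, p_hat)
    return FixationEstimate(
        x0=params.n_mutators_initial / params.N,
        n_reps=n_reps, n_fixed=n_fixed, n_censored=n_cens,
        p_hat=p_hat, ci_low=lo, ci_high=hi, base_seed=params.base_seed,
    )


def eq1_predict(p_single: float, x0: float, N: int) -> float:
    """Pfix(x0) implied by frequency independence: 1 - (1 - p1)^(x0*N).

    ``p_single`` is the per-capita (single-copy) fixation probability; the
    prediction is the chance that at least one of the x0*N independent initial
    copies fixes. Strictly increasing in both arguments on (0, 1).
    """
    if not 0.0 <= p_single <= 1.0:
        raise ValueError(f"p_single must be a probability, got {p_single}")
    n_copies = x0 * N
    if not 0.5 <= round(n_copies) <= N:
        raise ValueError(f"x0*N = {n_copies} must round into [1, N]")
    if p_single == 1.0:
        return 1.0
    return -math.expm1(n_copies * math.log1p(-p_single))


def kimura_pfix(s: float, N: int, x0: float) -> float:
    """Diffusion-approximation fixation probability of a selected allele.

    Pfix = (1 - exp(-2*s*N*x0)) / (1 - exp(-2*s*N)); the s -> 0 limit is the
    neutral value x0. Valid for haploid Wright-Fisher dynamics with genic
    selection s.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must be in [0, 1]")
    a = 2.0 * s * N
    if abs(a) < 1e-12:
        return x0
    if a < -700.0:  # both expm1 terms overflow; use the asymptotic ratio
        return math.exp(a * (1.0 - x0))
    return math.expm1(-a * x0) / math.expm1(-a)


def _two_allele_prob(count: np.ndarray, p: TwoAlleleParams) -> np.ndarray:
    """Expected next-generation frequency x(1+s)/(1+x*s) of the focal allele."""
    x = count / p.N
    if p.mode == "constant_s":
        s = p.s_ben
    else:
        s = freq_dep_s(x, p.freq_dep)
    prob = x * (1.0 + s) / (1.0 + x * s)
    return np.clip(prob, 0.0, 1.0)


def two_allele_run(
    p: TwoAlleleParams, seed=None, record: bool = True, replicate_id: int = 0
) -> Trajectory:
    """One replicate of the two-allele model: binomial Wright-Fisher sampling
    of the focal-allele count, run to absorption at 0 or N."""
    n0 = int(round(p.x0 * p.N))
    if n0 == 0:
        raise ConfigurationError("round(x0 * N) = 0: no focal-allele copies to track")
    rng = np.random.default_rng(seed)
    count = n0
    freqs = [count / p.N] if record else None
    t = 0
    while 0 < count < p.N and t < p.max_generations:
        prob = float(_two_allele_prob(np.asarray(count), p))
        count = int(rng.binomial(p.N, prob))
        t += 1
        if record:
            freqs.append(count / p.N)
    if count == p.N:
        status = OutcomeStatus.FIXED
    elif count == 0:
        status = OutcomeStatus.LOST
    else:
        status = OutcomeStatus.CENSORED
    return Trajectory(
        replicate_id=replicate_id, seed=seed, outcome=Outcome(status, t),
        final_freq=count / p.N,
        freq=np.asarray(freqs) if record else None, _x0=n0 / p.N,
    )


def two_allele_pfix(p: TwoAlleleParams, n_reps: int, base_seed: int = 0) -> FixationEstimate:
    """Monte-Carlo Pfix for the two-allele model, vectorized across replicates.

    All replicates advance in lock-step from a single RNG stream seeded with
    ``base_seed``; per-replicate trajectories are not retained.
    """
    n0 = int(round(p.x0 * p.N))
    if n0 == 0:
        raise ConfigurationError("round(x0 * N) = 0: no focal-allele copies to track")
    rng = np.random.default_rng(base_seed)
    counts = np.full(n_reps, n0, dtype=np.int64)
    active = (counts > 0) & (counts < p.N)
    t = 0
    while active.any() and t < p.max_generations:
        prob = _two_allele_prob(counts[active], p)
        counts[active] = rng.binomial(p.N, prob)
        active = (counts > 0) & (counts < p.N)
        t += 1
    n_fixed = int((counts == p.N).sum())
    n_cens = int(active.sum())
    n_eff = n_reps - n_cens
    if n_eff == 0:
        raise EstimationError("all replicates censored; increase max_generations")
    p_hat = n_fixed / n_eff
    lo, hi = _wilson(n_fixed, n_eff)
    lo, hi = min(lo, p_hat), max(hi, p_hat)
    return FixationEstimate(
        x0=n0 / p.N, n_reps=n_reps, n_fixed=n_fixed, n_censored=n_cens,
        p_hat=p_hat, ci_low=lo, ci_high=hi, base_seed=base_seed,
    )


def average_trajectories(trajs: Sequence[Trajectory], horizon: int) -> AverageTrajectory:
    """Ensemble-mean frequency per generation through ``horizon``.

    Absorbed replicates are padded with 0 (LOST) or 1 (FIXED) beyond their
    absorption generation -- without padding the long-horizon mean could not
    converge to Pfix. Censored replicates are padded with their final recorded
    frequency and counted in ``n_censored``.
    """
    if not trajs:
        raise ValueError("average_trajectories requires at least one trajectory")
    if any(t.freq is None for t in trajs):
        raise ValueError("all trajectories must have been run with record=True")
    x0s = {float(t.freq[0]) for t in trajs}
    if len(x0s) > 1:
        raise ValueError(f"trajectories mix starting frequencies: {sorted(x0s)}")
    total = np.zeros(horizon + 1)
    n_cens = 0
    for t in trajs:
        f = t.freq[: horizon + 1]
        total[: f.shape[0]] += f
        if f.shape[0] < horizon + 1:
            if t.outcome.status is OutcomeStatus.CENSORED:
                n_cens += 1
            total[f.shape[0]:] += t.final_freq
    return AverageTrajectory(
        horizon=horizon, mean_freq=total / len(trajs), n_reps=len(trajs),
        n_censored=n_cens,
    )


def markov_exact_pfix(
    N: int,
    fitness_rule: Union[float, Callable[[float], float], FreqDepParams],
    x0: float,
) -> float:
    """Exact fixation probability of the two-allele model by linear solve.

    Builds the (N+1)-state Wright-Fisher binomial transition matrix (absorbing
    at 0 and N) from the same sampling rule as :func:`two_allele_run` and
    solves the absorption-at-N probabilities. ``fitness_rule`` is a constant
    selection coefficient, a callable s(x), or :class:`FreqDepParams`. Dense
    solve, so N is capped at 200.
    """
    if N > 200:
        raise ValueError(f"N = {N} too large for a dense transition matrix (max 200)")
    if N < 2:
        raise ValueError("N must be >= 2")
    i0 = int(round(x0 * N))
    if not 0 <= i0 <= N:
        raise ValueError("x0 must be in [0, 1]")
    if isinstance(fitness_rule, FreqDepParams):
        s_of_x = lambda x: freq_dep_s(x, fitness_rule)
    elif callable(fitness_rule):
        s_of_x = fitness_rule
    else:
        s_const = float(fitness_rule)
        s_of_x = lambda x: s_const

    interior = np.arange(1, N)
    x = interior / N
    s = np.array([s_of_x(xi) for xi in x])
    prob = np.clip(x * (1.0 + s) / (1.0 + x * s), 0.0, 1.0)
    # P[i, j] = Binom(N, prob_i).pmf(j) for interior i
    P = stats.binom.pmf(np.arange(N + 1)[None, :], N, prob[:, None])
    Q = P[:, 1:N]
    R_fix = P[:, N]
    u = np.linalg.solve(np.eye(N - 1) - Q, R_fix)
    full = np.concatenate([[0.0], u, [1.0]])
    return float(full[i0])
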