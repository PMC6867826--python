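"""Discrete-generation Wright-Fisher engine for mutation-rate modifier hitchhiking.

The model is a haploid asexual population of constant size ``N`` evolving in
discrete, non-overlapping generations. Individuals carry 99 fitness-affecting
loci plus one mutation-rate modifier locus; the modifier ("mutator") allele is
itself fitness-neutral but multiplies the genomic mutation rate ``m_fold``-fold.
The population is represented as *lineages* -- subpopulations sharing an
identical genotype -- so the state is a handful of (n_ben, n_del, is_mutator)
classes rather than N individuals.

Each generation:

1. **Selection/reproduction**: new lineage sizes are one multinomial draw of N
   trials with probabilities ``f_i * w_i / w_bar``, where ``f_i`` is a lineage's
   frequency, ``w_i`` its fitness, and ``w_bar`` the population mean fitness.
2. **Mutation**: each lineage acquires ``M ~ Poisson(size * U_tot)`` new
   fitness mutations (``U_tot = (U_ben + U_del) * m_fold`` for mutators), split
   ``Binomial(M, U_ben / (U_ben + U_del))`` into beneficial and deleterious
   hits; each hit converts one parent individual into a new size-1 lineage with
   one additional mutation at a previously unmutated locus.

A run continues until the modifier allele is absorbed (frequency 0 or 1) or a
censoring horizon is reached. The modifier locus itself never mutates, so
absorption is permanent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "DegeneratePopulationError",
    "SimParams",
    "Lineage",
    "Population",
    "OutcomeStatus",
    "Outcome",
    "Trajectory",
    "lineage_fitness",
    "mean_fitness",
    "resample",
    "mutate",
    "step",
    "run_until_absorption",
]


class ConfigurationError(ValueError):
    """A simulation parameterization violates its contract."""


class DegeneratePopulationError(RuntimeError):
    """Every lineage has fitness zero; multinomial weights are undefined.

    N is constant by construction, so this is an error rather than silent
    extinction.
    """


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of one mutator-hitchhiking scenario.

    Parameters
    ----------
    N : population size (constant).
    U_ben, U_del : beneficial / deleterious mutation rate per individual per
        generation (non-mutator baseline).
    s_ben : beneficial effect magnitude (> 0).
    s_del : deleterious effect, stored as conventionally printed, i.e. a
        non-positive number; the engine uses its magnitude so deleterious
        mutations decrease fitness.
    m_fold : mutator mutation-rate multiplier (>= 1).
    x0 : initial mutator frequency; round(x0 * N) individuals start as
        mutators.
    L : number of fitness-affecting loci (each mutated at most once).
    dfe_mode : "constant" or "exponential" distribution of fitness effects.
    max_generations : censoring horizon.
    base_seed : seed from which per-replicate RNG streams are derived.
    """

    N: int
    U_ben: float
    U_del: float
    s_ben: float
    s_del: float
    m_fold: float
    x0: float
    L: int = 99
    dfe_mode: str = "constant"
    max_generations: int = 10**6
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.U_ben < 0 or self.U_del < 0:
            raise ConfigurationError("mutation rates U_ben, U_del must be >= 0")
        if self.s_ben <= 0:
            raise ConfigurationError(f"s_ben must be > 0, got {self.s_ben}")
        if self.s_del > 0:
            raise ConfigurationError(
                f"s_del is stored as printed (non-positive), got {self.s_del}"
            )
        if self.m_fold < 1:
            raise ConfigurationError(f"m_fold must be >= 1, got {self.m_fold}")
        if not 0.0 <= self.x0 <= 1.0:
            raise ConfigurationError(f"x0 must be in [0, 1], got {self.x0}")
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if self.dfe_mode not in ("constant", "exponential"):
            raise ConfigurationError(
                f"dfe_mode must be 'constant' or 'exponential', got {self.dfe_mode!r}"
            )
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be a positive integer")

    @property
    def n_mutators_initial(self) -> int:
        """Initial mutator count, round(x0 * N)."""
        return int(round(self.x0 * self.N))


@dataclass(frozen=True)
class Lineage:
    """A subpopulation sharing one genotype (read-only view for inspection)."""

    size: int
    n_ben: int
    n_del: int
    is_mutator: bool
    fitness: float


class OutcomeStatus(enum.Enum):
    FIXED = "FIXED"
    LOST = "LOST"
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class Outcome:
    """Absorption result of one replicate."""

    status: OutcomeStatus
    generations_elapsed: int


@dataclass
class Trajectory:
    """Per-generation mutator frequency of one replicate and its outcome.

    ``freq`` holds one entry per generation starting at t = 0; when a run is
    executed without recording it is ``None`` and only ``final_freq`` and the
    outcome are retained.
    """

    replicate_id: int
    seed: object
    outcome: Outcome
    final_freq: float
    freq: Optional[np.ndarray] = None

    @property
    def x0(self) -> float:
        return float(self.freq[0]) if self.freq is not None else self._x0

    _x0: float = field(default=np.nan, repr=False)


class Population:
    """Generation index plus a collection of lineages summing to N.

    Internally stored as parallel numpy arrays (one entry per lineage) for
    speed; the ``lineages`` property materializes :class:`Lineage` views.
    """

    __slots__ = ("generation", "N", "n_ben", "n_del", "is_mutator", "fitness", "size")

    def __init__(
        self,
        generation: int,
        N: int,
        n_ben: np.ndarray,
        n_del: np.ndarray,
        is_mutator: np.ndarray,
        fitness: np.ndarray,
        size: np.ndarray,
    ) -> None:
        self.generation = generation
        self.N = N
        self.n_ben = n_ben
        self.n_del = n_del
        self.is_mutator = is_mutator
        self.fitness = fitness
        self.size = size

    @classmethod
    def initial(cls, params: SimParams) -> "Population":
        """Founding population: round(x0*N) mutator and N - round(x0*N)
        non-mutator wild-type individuals, all free of fitness mutations."""
        n_mut = params.n_mutators_initial
        if n_mut == 0:
            raise ConfigurationError(
                "round(x0 * N) = 0: no mutators to track "
                f"(x0={params.x0}, N={params.N})"
            )
        if n_mut == params.N:
            sizes, muts = [params.N], [True]
        else:
            sizes, muts = [params.N - n_mut, n_mut], [False, True]
        k = len(sizes)
        return cls(
            generation=0,
            N=params.N,
            n_ben=np.zeros(k, dtype=np.int64),
            n_del=np.zeros(k, dtype=np.int64),
            is_mutator=np.array(muts, dtype=bool),
            fitness=np.ones(k, dtype=np.float64),
            size=np.array(sizes, dtype=np.int64),
        )

    @property
    def lineages(self) -> Sequence[Lineage]:
        return [
            Lineage(int(s), int(b), int(d), bool(m), float(w))
            for s, b, d, m, w in zip(
                self.size, self.n_ben, self.n_del, self.is_mutator, self.fitness
            )
        ]

    @property
    def mutator_count(self) -> int:
        return int(self.size[self.is_mutator].sum())

    @property
    def mutator_frequency(self) -> float:
        return self.mutator_count / self.N

    def total_size(self) -> int:
        return int(self.size.sum())


def lineage_fitness(n_ben, n_del, params: SimParams):
    """Additive fitness ``w = 1 + x*s_ben - y*|s_del|``, floored at zero.

    Accepts scalars or arrays. ``s_del`` is stored as printed (negative); its
    magnitude is applied so deleterious mutations decrease fitness.
    """
    n_ben = np.asarray(n_ben)
    n_del = np.asarray(n_del)
    if np.any(n_ben < 0) or np.any(n_del < 0):
        raise ValueError("mutation counts must be non-negative")
    if np.any(n_ben + n_del > params.L):
        raise ValueError(f"n_ben + n_del exceeds the locus count L={params.L}")
    w = np.maximum(0.0, 1.0 + n_ben * params.s_ben - n_del * abs(params.s_del))
    return float(w) if w.ndim == 0 else w


def mean_fitness(pop: Population) -> float:
    """Population mean fitness, w_bar = sum_i f_i * w_i."""
    if pop.size.shape[0] == 0:
        raise DegeneratePopulationError("empty population")
    wbar = float(pop.size @ pop.fitness) / pop.N
    if wbar <= 0.0:
        raise DegeneratePopulationError("all lineages have fitness zero")
    return wbar


def resample(pop: Population, rng: np.random.Generator) -> Population:
    """Selection + reproduction: one multinomial draw of N individuals with
    per-lineage probabilities ``f_i * w_i / w_bar``. Zero-size lineages are
    pruned; genotypes are unchanged."""
    weights = pop.size * pop.fitness
    tot = weights.sum()
    if tot <= 0.0:
        raise DegeneratePopulationError("all lineages have fitness zero")
    new_size = rng.multinomial(pop.N, weights / tot)
    keep = new_size > 0
    return Population(
        pop.generation,
        pop.N,
        pop.n_ben[keep],
        pop.n_del[keep],
        pop.is_mutator[keep],
        pop.fitness[keep],
        new_size[keep],
    )


def _merge_classes(pop: Population, L: int) -> Population:
    """Merge lineages with identical (n_ben, n_del, is_mutator).

    Valid only under a constant DFE, where fitness is a function of the counts;
    merging changes the representation, not the sampling distribution.
    """
    key = (pop.n_ben * (L + 1) + pop.n_del) * 2 + pop.is_mutator
    uniq, first, inv = np.unique(key, return_index=True, return_inverse=True)
    if uniq.shape[0] == pop.size.shape[0]:
        return pop
    size = np.bincount(inv, weights=pop.size, minlength=uniq.shape[0]).astype(np.int64)
    return Population(
        pop.generation,
        pop.N,
        pop.n_ben[first],
        pop.n_del[first],
        pop.is_mutator[first],
        pop.fitness[first],
        size,
    )


def mutate(pop: Population, params: SimParams, dfe, rng: np.random.Generator) -> Population:
    """Poisson mutation with a binomial beneficial/deleterious split.

    Each lineage draws ``M ~ Poisson(size * U_tot)`` mutations, capped at its
    size (at most one new mutation per individual per generation; double hits
    have probability ~U^2 and are negligible at realistic rates). ``K ~
    Binomial(M, U_ben/(U_ben+U_del))`` of them are beneficial. Every hit moves
    one individual into a new lineage carrying one extra mutation; lineages
    with all L loci already mutated ignore further hits. The modifier locus
    never mutates, so ``is_mutator`` is inherited unchanged.
    """
    from .dfe import DfeSpec  # local import to avoid a cycle at module load

    U = params.U_ben + params.U_del
    if U == 0.0:
        return pop
    if dfe is None:
        dfe = DfeSpec(mode=params.dfe_mode)

    lam = pop.size * U
    if params.m_fold != 1.0:
        lam = np.where(pop.is_mutator, lam * params.m_fold, lam)
    M = rng.poisson(lam)
    np.minimum(M, pop.size, out=M)
    saturated = pop.n_ben + pop.n_del >= params.L
    if saturated.any():
        M[saturated] = 0
    if not M.any():
        return pop

    K = rng.binomial(M, params.U_ben / U)
    D = M - K
    parent_size = pop.size - M

    if dfe.mode == "constant":
        kb = K > 0
        kd = D > 0
        n_ben = np.concatenate([pop.n_ben, pop.n_ben[kb] + 1, pop.n_ben[kd]])
        n_del = np.concatenate([pop.n_del, pop.n_del[kb], pop.n_del[kd] + 1])
        is_mut = np.concatenate([pop.is_mutator, pop.is_mutator[kb], pop.is_mutator[kd]])
        size = np.concatenate([parent_size, K[kb], D[kd]])
        keep = size > 0
        n_ben, n_del, is_mut, size = n_ben[keep], n_del[keep], is_mut[keep], size[keep]
        fitness = np.maximum(
            0.0, 1.0 + n_ben * params.s_ben - n_del * abs(params.s_del)
        )
        out = Population(pop.generation, pop.N, n_ben, n_del, is_mut, fitness, size)
        return _merge_classes(out, params.L)

    # exponential DFE: every mutant founds its own size-1 lineage with an
    # individually drawn effect added to the parent's accumulated fitness
    ib = np.repeat(np.arange(pop.size.shape[0]), K)
    idx = np.repeat(np.arange(pop.size.shape[0]), D)
    eff_b = rng.exponential(dfe.mean_ben, ib.shape[0])
    eff_d = -rng.exponential(abs(dfe.mean_del), idx.shape[0])
    n_ben = np.concatenate([pop.n_ben, pop.n_ben[ib] + 1, pop.n_ben[idx]])
    n_del = np.concatenate([pop.n_del, pop.n_del[ib], pop.n_del[idx] + 1])
    is_mut = np.concatenate([pop.is_mutator, pop.is_mutator[ib], pop.is_mutator[idx]])
    fitness = np.concatenate(
        [
            pop.fitness,
            np.maximum(0.0, pop.fitness[ib] + eff_b),
            np.maximum(0.0, pop.fitness[idx] + eff_d),
        ]
    )
    size = np.concatenate(
        [parent_size, np.ones(ib.shape[0], np.int64), np.ones(idx.shape[0], np.int64)]
    )
    keep = size > 0
    return Population(
        pop.generation, pop.N, n_ben[keep], n_del[keep], is_mut[keep],
        fitness[keep], size[keep],
    )


def step(pop: Population, params: SimParams, dfe, rng: np.random.Generator) -> Population:
    """One Wright-Fisher generation: resample, then mutate."""
    out = mutate(resample(pop, rng), params, dfe, rng)
    return Population(
        pop.generation + 1, out.N, out.n_ben, out.n_del, out.is_mutator,
        out.fitness, out.size,
    )


def run_until_absorption(
    params: SimParams,
    dfe=None,
    seed=None,
    record: bool = True,
    replicate_id: int = 0,
) -> Trajectory:
    """Run one replicate until the modifier allele fixes or is lost.

    Returns a :class:`Trajectory` ending at the first generation with mutator
    frequency 0 or 1, or CENSORED when ``max_generations`` is reached first.
    With ``record=False`` the per-generation frequencies are not stored.
    """
    rng = np.random.default_rng(seed)
    pop = Population.initial(params)
    freq = pop.mutator_frequency
    freqs = [freq] if record else None
    t = 0
    while freq not in (0.0, 1.0) and t < params.max_generations:
        pop = step(pop, params, dfe, rng)
        freq = pop.mutator_frequency
        t += 1
        if record:
            freqs.append(freq)
    if freq == 1.0:
        status = OutcomeStatus.FIXED
    elif freq == 0.0:
        status = OutcomeStatus.LOST
    else:
        status = OutcomeStatus.CENSORED
    return Trajectory(
        replicate_id=replicate_id,
        seed=seed,
        outcome=Outcome(status, t),
        final_freq=freq,
        freq=np.asarray(freqs) if record else None,
        _x0=params.n_mutators_initial / params.N,
    )
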