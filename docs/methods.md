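# Methods

## The model

`mutsim` simulates a haploid, asexual population of fixed size *N* under the
Wright–Fisher model: discrete, non-overlapping generations in which the next
generation is drawn anew from the current one. A genotype is an array of
*L* = 99 fitness-affecting loci plus one mutation-rate modifier locus. The
modifier ("mutator") allele multiplies the genomic mutation rate *m_fold*-fold
and has no direct fitness effect; it never mutates itself, so its frequency is
a bounded martingale-like process with absorbing states 0 and 1, and every run
ends in loss or fixation (or censoring at `max_generations`, default 10⁶,
reported separately and never counted as an outcome).

The population is represented by **lineages** — classes of individuals sharing
a genotype — rather than individuals. Fitness is additive:
*w(x, y) = 1 + x·s_ben − y·|s_del|* for *x* beneficial and *y* deleterious
mutations, floored at zero so multinomial weights stay non-negative.
`s_del` is stored in config as conventionally printed (a negative number);
the engine applies its magnitude so deleterious mutations decrease fitness.
A population in which every lineage has fitness zero is an error
(`DegeneratePopulationError`), not a silent extinction, because *N* is
constant by construction.

Each generation, in order:

1. **Resampling.** New lineage sizes are one multinomial draw of *N* trials
   with probabilities *fᵢwᵢ/w̄*, where *w̄* = Σ*fᵢwᵢ*. Sizes sum to *N*
   exactly; empty lineages are pruned.
2. **Mutation.** Each lineage draws *M* ~ Poisson(size × *U_tot*) mutations,
   where *U_tot* = (*U_ben* + *U_del*)·*m_fold* for mutator lineages. *M* is
   capped at the lineage size — each individual acquires at most one new
   mutation per generation; multi-hit individuals have probability of order
   *U²* per individual per generation (~10⁻⁸ at the default rates) and are
   neglected. *K* ~ Binomial(*M*, *U_ben*/(*U_ben*+*U_del*)) of the hits are
   beneficial. Every hit moves one individual into a new lineage with one
   additional mutation at a previously unmutated locus; a lineage whose *L*
   loci are all mutated ignores further hits (locus identity itself is not
   stored — only the counts matter under a constant DFE).

Under the constant DFE, lineages with identical (*n_ben*, *n_del*,
*is_mutator*) are merged after mutation. Merging is a pure change of
representation: the multinomial and Poisson distributions depend only on class
totals, so the sampling distribution of every statistic is unchanged; a
property test asserts class keys stay unique and conservation holds. Under
the exponential DFE every mutation founds its own size-1 lineage carrying an
individually drawn effect (beneficial +Exp(mean 0.1), deleterious −Exp(mean
0.1) by default), accumulated additively on the same *w* scale and floored at
zero; no merging applies.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `N` | population size (individuals) | required |
| `U_ben`, `U_del` | beneficial / deleterious mutation rate, per individual per generation | required (study values 10⁻⁶, 10⁻⁴) |
| `s_ben`, `s_del` | fitness effects (s_del stored negative) | required (study values 0.1, −0.1) |
| `m_fold` | mutator rate multiplier | required (study value 100) |
| `x0` | initial mutator frequency; round(x0·N) copies, ≥ 1 enforced | required |
| `L` | fitness loci | 99 |
| `dfe_mode` | `constant` or `exponential` | constant |
| `max_generations` | censoring horizon | 10⁶ |
| `base_seed` | seed of record; replicate *r* runs on `SeedSequence([base_seed, r])` | 0 |

The seed rule makes replicates independent of execution order and safe to
parallelize; re-running any config with the same base seed is bit-identical.

## Estimation and predictors

`estimate_pfix` reports n_fixed/(n_reps − n_censored) with a 95% **Wilson
score** interval (statsmodels); Wilson is used because the probabilities of
interest sit near zero where Wald intervals collapse. The
frequency-independence predictor is Pfix(x0) = 1 − (1 − p₁)^(x0·N) with p₁
the measured single-copy value, evaluated via `expm1`/`log1p` for accuracy at
small p₁. `kimura_pfix` implements (1 − e^(−2sNx₀))/(1 − e^(−2sN)) with the
neutral limit x₀ taken explicitly for |2sN| < 10⁻¹²; for very strong negative
selection the ratio is computed in asymptotic form to avoid overflow.

The **two-allele** control model tracks a single focal-allele count with
binomial sampling at expected frequency x(1+s)/(1+xs) — the same
relative-fitness normalization as the main engine — where s is constant or
s(x) = b + m·x recomputed each generation. It deliberately omits background
mutation at the 99 loci; that suffices for the diffusion-formula and
oracle comparisons it exists for. The **exact oracle** builds the
(N+1)-state binomial transition matrix from the same rule and solves the
absorption system directly; it is restricted to N ≤ 200 (dense solve) and
serves as an independent cross-check of the sampler, not as an alternative
implementation path.

`average_trajectories` pads absorbed replicates with 0/1 to the requested
horizon — without padding, the long-horizon ensemble mean could not converge
to Pfix. Censored replicates are padded with their final frequency and
flagged.

## What the tests establish, and at what scale

Validation runs at three deliberately chosen problem sizes:

- **Full scale, reduced replication**: Pfix(1/N) at N = 10⁷ with 10⁵
  replicates in the suite (5×10⁵ in `scripts/acceptance.py`), enough for a
  ~±13% (±6%) standard error on a probability near 5.6×10⁻⁴.
- **Reduced scale for frequency-dependence properties**: N = 10⁵ with
  x₀·N ∈ {1, 2, 5, 10}. Replicates scale inversely with x₀ so each estimate
  accumulates ≳100 fixations; the single-copy arm gets 4×10⁵ replicates
  because its estimate parameterizes the independence prediction tested
  against the other arms.
- **Trajectory scale**: N = 10⁴ ensembles with recorded trajectories for
  ensemble-mean convergence and the individual-realization threshold pattern.

Passing these shows the engine reproduces the quantitative behavior of the
idealized model — not that any particular biological population obeys it. The
simulator mimics microbial evolution experiments only in the ways the model
states: constant N, complete linkage (no recombination), additive effects, at
most one new mutation per individual per generation, a modifier that never
reverts. Real experiments add bottlenecks, clonal interference among
finitely many sites, epistasis, and reversion, none of which are modeled.

## Numerical and design choices

- Multinomial/Poisson/binomial draws come from numpy's PCG64 generator; no
  approximations beyond the engine definitions above.
- The transient early dip of the ensemble-mean mutator frequency below x₀
  (visible in the convergence test and `examples/trajectories_and_averages.py`)
  reflects selection against the mutator's higher deleterious load; the
  package verifies the dip exists but does not analyze its mechanism.
- Exponential-DFE deleterious draws are truncated only by the fitness floor
  at w = 0; drawn effects themselves are not truncated.
- Ties/degenerate inputs: x0 values rounding to 0 copies are configuration
  errors ("no mutators to track"); x0 = 1 is absorbed at generation 0 and
  yields a degenerate estimate (p̂ = 1).
- TSV output uses `%.17g` floats and round-trip parsing so written tables
  reload bit-identically.

## Known limitations

- The lineage-merging fast path keys on mutation counts and is therefore
  exact only for the constant DFE; exponential-DFE runs carry one lineage per
  mutation and are practical at reduced N (≲10⁵), not at 10⁷.
- The exact oracle is dense linear algebra, hence N ≤ 200.
- Monte-Carlo fixation probabilities below ~10⁻⁵ need replicate counts beyond
  what the bundled tests run; the machinery supports them but budget one CPU
  for hours.
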