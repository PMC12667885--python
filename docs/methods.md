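# Methods

## Model

`stabsel` studies a single additive quantitative trait under Gaussian
stabilizing selection in a diploid, panmictic population of effective
size $N_e$. An individual with trait value $p$ has relative fitness

$$w(p) = \exp\left(-\frac{(p - \mathrm{opt})^2}{2 V_S}\right),$$

so the optimal phenotype has fitness one and $V_S$ (trait units²) sets
the inverse strength of selection — larger $V_S$, weaker selection.
Mutations affecting the trait arise at total rate $U$ per gamete per
generation ($U = \mu L$ for per-base rate $\mu$ and target size $L$)
with additive effects drawn from $\mathcal{N}(0, V_M)$ and no dominance,
epistasis, pleiotropy, or linkage (free recombination / linkage
equilibrium throughout).

At mutation–selection–drift balance, three classical ingredients
combine:

1. **Within-population phenotypes** are approximately
   $\mathcal{N}(\bar p, V_P)$, giving population mean fitness
   $\bar w = \sqrt{V_S / (V_P + V_S)}\,
   \exp(-\bar p^2 / 2(V_P + V_S))$ (optimum at zero).
2. **The population mean drifts**: the displacement $\delta$ of
   $\bar p$ from the optimum is $\mathcal{N}(0, V_S / 2N_e)$ at
   stationarity. Averaging over $\delta$,
   $E[\bar w] = \left[2 N_e V_S / (V_S + 2 N_e (V_P + V_S))\right]^{1/2}$.
3. **The genetic variance** follows the stochastic house-of-cards
   (SHOC) interpolation
   $V_G = 4 U V_S / (1 + V_S / (N_e V_M))$, which recovers the
   house-of-cards value $4 U V_S$ for strong effects
   ($N_e V_M \gg V_S$) and the drift-limited value $4 N_e U V_M$ for
   weak ones.

Substituting (3) into (2) yields the closed-form expected mean fitness

$$E[\bar w] = \left[\frac{2N_e}{1 + 2N_e\left(1 +
\frac{4 N_e U V_M}{N_e V_M + V_S}\right)}\right]^{1/2},$$

with the small-load expansion
$\mathrm{load} \approx 2 N_e V_M U / (N_e V_M + V_S) + 1/(4 N_e)$
exposing the two limits: load $\to 2U$ (from below) in large
populations with strong effects, and $\to 1/(4N_e)$ in small or
mutation-free ones. Setting the $N_e$ derivative to zero gives the
fitness-maximizing population size

$$N_e^\* = \frac{V_S\,(1 + \sqrt{8 U V_S / V_M})}{8 U V_S - V_M},$$

which is positive — i.e. a *finite* population maximizes expected mean
fitness — exactly when $U > V_M / (8 V_S)$. The interplay is: small
populations carry less genetic variance (less standing load) but drift
farther from the optimum; when $U$ is large the variance term dominates
and an intermediate size wins.

**Environmental variance.** Uncorrelated noise
$\mathcal{N}(0, V_E)$ added to phenotypes is absorbed into the fitness
function by the substitution $V_S \to V_S + V_E$. The substitution is
applied uniformly — in the fitness prediction, the SHOC variance, the
optimum, and the condition ($U > V_M / 8(V_S + V_E)$) — because the
absorbed model is mathematically identical to a no-noise model with the
wider fitness function acting on genetic values. `ModelParams.vs_eff`
implements it in one place.

**Boundary case.** At $8 U V_S = V_M$ exactly, the denominator of
$N_e^\*$ vanishes and the optimum recedes to infinity;
`optimal_ne` reports *no finite optimum* there, consistent with the
strict inequality in the condition.

`load_approx` is exposed as a load (1 − fitness) rather than a fitness
because its only role is reading off the $2U$ and $1/(4N_e)$ limits;
the exact closed form remains the primary prediction, and tests hold
the expansion to the exact value only loosely (10% at a mid-range
architecture), since it is a truncated series with no stated accuracy
range.

## Numeric oracles

Every closed form is checked against an independent numeric route:

- `mean_fitness_numeric` and `expected_mean_fitness_numeric` evaluate
  the single and nested fitness integrals by adaptive quadrature
  (`scipy.integrate.quad`, absolute and relative tolerance $10^{-12}$,
  bounds at ±12 standard deviations — tail mass is negligible relative
  to the $10^{-8}$ test tolerances). The nested oracle integrates the
  *numeric* inner integral, so it shares no algebra with the closed
  form it checks.
- `optimal_ne_numeric` maximizes the closed-form fitness over
  continuous $N_e$ with a 400-point log-spaced bracketing scan on
  $[10^{-2}, 10^{10}]$ followed by bounded scalar minimization in
  $\log N_e$ (`xatol` $10^{-13}$). $N_e$ is treated as continuous, as
  in the derivative-based derivation.

## Wright–Fisher simulator

The simulator is the package's synthetic-data generator: it emulates
the model's assumptions directly rather than any empirical data set.

- **Life cycle.** Discrete generations; $N$ diploid, monoecious
  individuals with selfing allowed. Each offspring draws two parents
  independently with probability proportional to fitness, computed from
  the phenotype (genetic value + fresh $\mathcal{N}(0, V_E)$ noise each
  generation, when $V_E > 0$).
- **Transmission.** Each segregating mutation is transmitted
  independently: heterozygous with probability 1/2, homozygous always
  (free recombination; no genetic map). This realizes the
  linkage-equilibrium assumption of the theory exactly.
- **Mutation.** Infinite sites: each new mutation occupies a fresh
  site, arriving as Poisson($U$) per gamete with effect
  $\mathcal{N}(0, V_M)$ — matching the house-of-cards assumption that
  a new allele's effect is drawn fresh rather than perturbing the
  parental allele.
- **Fixations** are folded into a phenotype offset (adding
  $2 \times$ effect) instead of being dropped: fixed mutations displace
  the population mean relative to the optimum, and discarding them
  would bias mean fitness upward. A conservation test asserts pruning
  never changes any individual's phenotype.
- **Census = effective size.** The simulated Wright–Fisher census size
  plays the role of $N_e$ in the predictions (no separate sexes,
  sweeps, or structure would decouple them here).
- **Recording.** After a burn-in of $10N$ generations (about ten times
  the slowest relaxation timescale, $\max(2N, V_S/V_G)$ generations,
  for the architectures studied), the mean fitness, genetic variance
  (population variance of genetic values), and mean phenotype are
  recorded every $N/10$ generations for `n_samples` samples (default
  30, i.e. about $3N$ generations of equilibrium per replicate).
  Replicates are fully independent runs with seeds derived from the
  experiment seed via `numpy` `SeedSequence`; a given (config, seed)
  is bit-reproducible.
- **Aggregation.** Across replicates, each quantity's statistic is the
  replicate time-average; the 95% interval is the normal approximation
  mean ± 1.96 SE over replicate means. With 20 replicates the normal
  and t intervals differ by ~6% in width; coverage of the normal
  interval is checked by simulation in the tests.

### Engines

Two interchangeable engines implement the identical process:

- `engine="steps"`: explicit numpy operations (`mutate`,
  `phenotypes_and_fitness`, `reproduce`, `prune_fixed`) on a dense
  genotype matrix — the readable reference implementation, unit-tested
  operation by operation.
- `engine="fast"` (default): a fused numba kernel storing genotypes
  sparsely (per-individual lists of carried sites). At equilibrium most
  sites are rare, so work scales with allele copies (~30k per
  generation at $N = 1000$, $U = 0.01$) rather than
  $N \times \text{sites}$ (~270k), and the Mendelian coin flips use
  batched random bits in a branch-free inner loop. About 4× faster
  than the steps engine at $N = 1000$, $U = 0.01$, and the advantage
  grows with problem size since its cost tracks the sparse entry count.

The engines consume independent random streams, so they agree in
distribution, not bitwise; a cross-check test compares their
across-replicate means at CI scale. The `vs = inf` configuration turns
selection off entirely (uniform parent choice), which isolates mutation
and drift and lets the neutral limit $V_G = 4 N U V_M$ be tested
exactly.

## Validation experiments

`run_sweep` reproduces the theory-vs-simulation comparison over a
factorial $(N_e, U, V_M)$ grid at $V_S = 1$: per cell, the closed-form
prediction beside the across-replicate mean and 95% CI for mean
fitness, genetic variance, and the squared displacement of the mean
phenotype (whose expectation the theory puts at $V_S / 2N_e$).
*Coverage* means the simulated CI contains the analytic prediction —
the same visual criterion as overlaying points on curves — not a formal
hypothesis test. Per-cell seeds derive from (base seed, cell index), so
cells are reproducible under grid reordering.

The default `DESK_GRID` ($N_e \in \{500, 1000\}$,
$U \in \{0.005, 0.01\}$, $V_M \in \{10^{-4}, 10^{-3}\}$, 20 replicates)
stays inside the regimes where the approximations hold; these problem
sizes keep the full grid to minutes of compute while leaving
prediction–simulation discrepancies well above CI resolution if they
existed. The `FULL_GRID` preset spans the breakdown regimes as well and
takes hours. `breakdown_diagnostics` maps failing cells onto the two
known failure modes: *small populations* (simulated
$\mathrm{Var}(\bar p)$ off $V_S/2N_e$ by more than 50%, i.e. the
Gaussian drift law for the mean has failed — expected at
$N_e \sim \mathcal{O}(100)$ and below) and *SHOC underestimation*
(simulated $V_G$ CI entirely above the prediction — expected for strong
effects and high mutation rates).

`small_vs_large_comparison` simulates the headline phenomenon with an
architecture chosen to make it cheap and unambiguous: $U = 0.1$,
$V_M = 0.1$, $V_S = 1$ gives $N_e^\* \approx 5.5$, so the comparison
pits $N = 5$ against $N = 500$ (100×), 12 replicates each. The
predicted gap (~0.05) is an order of magnitude above replicate SE;
the realized gap is larger still, because at this strong-effect, high-
rate architecture the SHOC formula underestimates $V_G$ in the large
population — the breakdown works in the phenomenon's favor.

## What the generator does and does not show

The simulator realizes exactly the assumptions of the closed forms
(additivity, free recombination, Gaussian effects, constant optimum,
panmixia). Agreement therefore validates the *derivation chain* —
SHOC variance, drift of the mean, Gaussian within-population
phenotypes — at the simulated parameter ranges; it says nothing about
real traits with dominance, epistasis, pleiotropy, linkage,
non-Gaussian effects, or changing optima, all outside scope. The
human-trait worked example (`mu = 1e-8`, `L = 1e6`, $V_S/V_P = 60$,
$V_M < V_P$) is an order-of-magnitude plausibility argument, not an
empirical fit.

## Numerical choices and edge cases

- Parameter validation happens at construction (`ModelParams`,
  `SimConfig`); errors name the offending field.
- `mean_fitness_at(vp=0)` short-circuits to the point-mass value; the
  quadrature oracle raises if its error estimate exceeds $10^{-8}$.
- A population whose every fitness underflows to zero (pathological
  $V_S$, $V_M$) raises with advice rather than dividing by zero; sweep
  cells that fail are flagged and reported, not fatal.
- Fixed seeds make every statistical test deterministic; acceptance
  bands were sized from the sampling distribution of each statistic
  (binomial, chi-square, or replicate-SE scale), not tuned to runs.
- Simulated $\mathrm{Var}(\bar p)$ is measured as the mean squared
  displacement from the known optimum (pooling samples and replicates)
  rather than the within-series variance, since the series length can
  be short relative to the mean's autocorrelation time
  ($\sim V_S / V_G$ generations) in weak-effect cells.

## Known limitations

- The theory's accuracy degrades exactly where the diagnostics flag it
  (small $N_e$; strong effects with high $U$); the package documents
  and detects this rather than correcting it.
- The normal-approximation CI slightly undercovers at small replicate
  counts; replicate counts below ~10 should be interpreted with care.
- The sparse kernel assumes per-site allele counts fit in int32 and
  sites-per-individual stay far below the site capacity; both hold by
  orders of magnitude for the intended parameter ranges.
- Continuous-$N_e$ optima ($N_e^\*$ can be below 1 for extreme $U$) are
  reported as-is; interpreting them as census sizes requires rounding.
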