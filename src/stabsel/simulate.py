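"""Individual-based diploid Wright-Fisher simulation of an additive
polygenic trait under Gaussian stabilizing selection.

The population is monoecious with selfing allowed; each generation, two
parents per offspring are drawn with probability proportional to fitness.
Mutation is infinite-sites: every new mutation occupies a fresh site,
arriving at rate ``u`` per gamete with effect drawn from Normal(0, vm).
Segregating sites are transmitted independently (free recombination /
linkage equilibrium). Mutations that fix are folded into a phenotype
offset rather than dropped, because fixations displace the mean
phenotype from the optimum and discarding them would bias mean fitness
upward.

Two engines produce statistically identical processes: ``"fast"`` (a
fused numba kernel, the default) and ``"steps"`` (the explicit numpy
operations below, used for unit testing and inspection). They consume
independent random streams, so results agree in distribution, not
bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams

__all__ = [
    "SimConfig",
    "PopulationState",
    "SimResult",
    "ReplicateSummary",
    "mutate",
    "phenotypes_and_fitness",
    "reproduce",
    "prune_fixed",
    "run_replicate",
    "run_replicates",
    "summarize",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation experiment.

    ``burn_in`` defaults to ``10 * n`` generations and ``record_every``
    to ``max(1, n // 10)``, standard choices for reaching and sampling
    mutation-selection-drift equilibrium. ``vs = inf`` is allowed and
    turns selection off (all fitnesses one), which isolates mutation and
    drift.
    """

    n: int
    u: float
    vm: float
    vs: float
    ve: float = 0.0
    optimum: float = 0.0
    burn_in: Optional[int] = None
    record_every: Optional[int] = None
    n_samples: int = 30
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"SimConfig.n = {self.n!r} must be >= 2")
        if self.u < 0:
            raise ValueError(f"SimConfig.u = {self.u!r} must be >= 0")
        if self.vm <= 0:
            raise ValueError(f"SimConfig.vm = {self.vm!r} must be > 0")
        if self.vs <= 0:
            raise ValueError(f"SimConfig.vs = {self.vs!r} must be > 0")
        if self.ve < 0:
            raise ValueError(f"SimConfig.ve = {self.ve!r} must be >= 0")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("SimConfig.burn_in must be >= 0")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("SimConfig.record_every must be >= 1")
        if self.n_samples < 1:
            raise ValueError("SimConfig.n_samples must be >= 1")
        if self.replicates < 1:
            raise ValueError("SimConfig.replicates must be >= 1")

    @property
    def burn_in_(self) -> int:
        return 10 * self.n if self.burn_in is None else self.burn_in

    @property
    def record_every_(self) -> int:
        return max(1, self.n // 10) if self.record_every is None else self.record_every

    @property
    def neutral(self) -> bool:
        """True when selection is disabled (``vs`` infinite)."""
        return math.isinf(self.vs)

    def to_params(self, ne: Optional[float] = None) -> ModelParams:
        """The analytic parameter bundle matching this simulation, with
        census size standing in for the effective size."""
        return ModelParams(
            ne=float(self.n if ne is None else ne),
            u=self.u, vm=self.vm, vs=self.vs, ve=self.ve, optimum=self.optimum,
        )


@dataclass
class PopulationState:
    """Per-individual mutation bookkeeping.

    ``genotypes`` holds counts in {0, 1, 2} of each segregating mutation
    for each individual, shape ``(n, n_sites)``; ``effects`` the additive
    effect per site; ``offset`` the summed contribution ``2 * effect`` of
    every fixed mutation. Individual i's genetic value is
    ``offset + genotypes[i] @ effects``.
    """

    genotypes: np.ndarray
    effects: np.ndarray
    offset: float = 0.0
    generation: int = 0

    @classmethod
    def initial(cls, n: int) -> "PopulationState":
        return cls(
            genotypes=np.zeros((n, 0), dtype=np.int8),
            effects=np.zeros(0, dtype=float),
        )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def genetic_values(self) -> np.ndarray:
        return self.offset + self.genotypes.astype(float) @ self.effects

    def allele_counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=0, dtype=np.int64)


def mutate(pop: PopulationState, cfg: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Add new mutations: each of the ``2n`` gametes of this generation
    receives Poisson(``u``) new mutations at fresh sites, with effects
    drawn from Normal(0, vm).

    Pooled across gametes this is Poisson(``2 n u``) new heterozygous
    singletons in random individuals.
    """
    n_new = rng.poisson(2.0 * pop.n * cfg.u)
    if n_new == 0:
        return pop
    cols = np.zeros((pop.n, n_new), dtype=np.int8)
    carriers = rng.integers(0, pop.n, size=n_new)
    cols[carriers, np.arange(n_new)] = 1
    return replace(
        pop,
        genotypes=np.concatenate([pop.genotypes, cols], axis=1),
        effects=np.concatenate(
            [pop.effects, rng.normal(0.0, math.sqrt(cfg.vm), size=n_new)]
        ),
    )


def phenotypes_and_fitness(
    pop: PopulationState, cfg: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Phenotypes (genetic value plus fresh Normal(0, ve) noise) and
    Gaussian fitnesses for the current generation."""
    phen = pop.genetic_values()
    if cfg.ve > 0:
        phen = phen + rng.normal(0.0, math.sqrt(cfg.ve), size=pop.n)
    if cfg.neutral:
        fit = np.ones(pop.n)
    else:
        fit = np.exp(-((phen - cfg.optimum) ** 2) / (2.0 * cfg.vs))
    return phen, fit


def reproduce(
    pop: PopulationState,
    fitnesses: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """One round of fitness-weighted Wright-Fisher reproduction.

    Each of the ``n`` offspring draws two parents independently with
    probability proportional to fitness (selfing allowed). A parent
    transmits each heterozygous mutation with probability 1/2 and each
    homozygous mutation always: with genotype g the transmission
    probability is g/2, realized below as ``(g + random bit) // 2``.
    """
    w = np.asarray(fitnesses, dtype=float)
    if w.shape != (pop.n,):
        raise ValueError("fitness vector length must equal population size")
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            "all fitnesses underflowed to zero; increase vs or reduce vm"
        )
    parents = rng.choice(pop.n, size=(2, pop.n), p=w / total)
    bits = rng.integers(0, 2, size=(2, pop.n, pop.n_sites), dtype=np.int8)
    gametes = (pop.genotypes[parents] + bits) >> 1
    return replace(
        pop,
        genotypes=(gametes[0] + gametes[1]).astype(np.int8),
        generation=pop.generation + 1,
    )


def prune_fixed(pop: PopulationState) -> PopulationState:
    """Drop lost sites and fold fixed sites into the phenotype offset.

    No individual's genetic value changes: a fixed site contributes
    ``2 * effect`` to everyone, which moves into ``offset``.
    """
    counts = pop.allele_counts()
    fixed = counts == 2 * pop.n
    keep = (counts > 0) & ~fixed
    if keep.all():
        return pop
    return replace(
        pop,
        genotypes=np.ascontiguousarray(pop.genotypes[:, keep]),
        effects=pop.effects[keep],
        offset=pop.offset + 2.0 * pop.effects[fixed].sum(),
    )


@dataclass(frozen=True)
class SimResult:
    """Post-burn-in time series for one replicate.

    ``mean_fitness``, ``vg`` (population variance of genetic values) and
    ``pbar`` (mean phenotype) each hold ``n_samples`` values recorded
    every ``record_every`` generations.
    """

    mean_fitness: np.ndarray
    vg: np.ndarray
    pbar: np.ndarray
    seed: int
    config: SimConfig

    def __post_init__(self) -> None:
        ns = self.config.n_samples
        for name in ("mean_fitness", "vg", "pbar"):
            if len(getattr(self, name)) != ns:
                raise ValueError(f"{name} series length != n_samples")

    def time_average(self, quantity: str) -> float:
        return float(np.mean(getattr(self, quantity)))

    def pbar_sq(self) -> np.ndarray:
        """Squared displacement of the mean phenotype from the optimum."""
        return (self.pbar - self.config.optimum) ** 2


def run_replicate(cfg: SimConfig, seed: Optional[int] = None, engine: str = "fast") -> SimResult:
    """Run one replicate to equilibrium and record its time series.

    Fully reproducible: the same (config, seed, engine) gives the same
    series bitwise. ``seed`` defaults to ``cfg.seed``.
    """
    seed = cfg.seed if seed is None else seed
    if engine == "fast":
        from ._kernel import wf_kernel

        mf, vg, pb = wf_kernel(
            cfg.n,
            cfg.u,
            cfg.vm,
            0.0 if cfg.neutral else cfg.vs,
            cfg.ve,
            cfg.optimum,
            cfg.burn_in_,
            cfg.record_every_,
            cfg.n_samples,
            int(seed) % (2**31),
            cfg.neutral,
        )
        return SimResult(mean_fitness=mf, vg=vg, pbar=pb, seed=seed, config=cfg)
    if engine != "steps":
        raise ValueError(f"unknown engine {engine!r}")

    rng = np.random.default_rng(seed)
    pop = PopulationState.initial(cfg.n)
    mf = np.empty(cfg.n_samples)
    vg = np.empty(cfg.n_samples)
    pb = np.empty(cfg.n_samples)
    burn_in, every, n_samples = cfg.burn_in_, cfg.record_every_, cfg.n_samples
    total_gens = burn_in + (n_samples - 1) * every + 1
    k = 0
    for gen in range(total_gens):
        phen, fit = phenotypes_and_fitness(pop, cfg, rng)
        if gen >= burn_in and (gen - burn_in) % every == 0:
            z = pop.genetic_values()
            mf[k] = fit.mean()
            vg[k] = z.var()
            pb[k] = phen.mean()
            k += 1
            if k == n_samples:
                break
        pop = prune_fixed(mutate(reproduce(pop, fit, cfg, rng), cfg, rng))
    return SimResult(mean_fitness=mf, vg=vg, pbar=pb, seed=seed, config=cfg)


def replicate_seeds(cfg: SimConfig) -> np.ndarray:
    """Independent per-replicate seeds derived from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    return ss.generate_state(cfg.replicates) % (2**31)


def run_replicates(cfg: SimConfig, engine: str = "fast") -> list[SimResult]:
    """Run ``cfg.replicates`` independent replicates."""
    return [run_replicate(cfg, seed=int(s), engine=engine) for s in replicate_seeds(cfg)]


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate aggregate of one scalar quantity.

    The statistic per replicate is its time average over samples; the
    95% interval is the normal approximation ``mean +/- 1.96 SE`` over
    replicate means.
    """

    quantity: str
    mean: float
    ci_low: float
    ci_high: float
    replicate_means: np.ndarray = field(repr=False)

    @property
    def ci_halfwidth(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


_QUANTITIES = ("mean_fitness", "vg", "pbar", "pbar_sq")


def summarize(
    results: Sequence[SimResult], quantity: str = "mean_fitness"
) -> ReplicateSummary:
    """Across-replicate mean and 95% CI of a recorded quantity.

    ``quantity`` is one of ``mean_fitness``, ``vg``, ``pbar`` or
    ``pbar_sq`` (squared displacement of the mean phenotype from the
    optimum, whose expectation the theory puts at ``vs / (2 n)``).
    """
    if len(results) < 2:
        raise ValueError("summarize needs at least 2 replicates")
    if quantity not in _QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; one of {_QUANTITIES}")
    if quantity == "pbar_sq":
        means = np.array([float(r.pbar_sq().mean()) for r in results])
    else:
        means = np.array([r.time_average(quantity) for r in results])
    m = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(len(means)))
    return ReplicateSummary(
        quantity=quantity,
        mean=m,
        ci_low=m - 1.96 * se,
        ci_high=m + 1.96 * se,
        replicate_means=means,
    )
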