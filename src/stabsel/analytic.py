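"""Closed-form predictions for mean fitness under Gaussian stabilizing
selection on one additive polygenic trait, at mutation-selection-drift
balance, together with independent numeric oracles (adaptive quadrature,
numeric maximization) used to verify them.

The model: individual fitness is Gaussian in the trait value with width
``vs``; phenotypes within a population are Normal(pbar, vp); the mean
phenotype itself drifts around the optimum with variance ``vs / (2 ne)``.
The genetic variance at balance follows the stochastic house-of-cards
(SHOC) interpolation between the strong-effect house-of-cards regime
(``vg = 4 u vs``) and the weak-effect drift regime (``vg = 4 ne u vm``).
Combining the two gives a closed form for the expected mean fitness as a
function of population size, which is maximized at a finite ``ne``
whenever ``u > vm / (8 (vs + ve))``.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize

from .params import (
    FitnessSummary,
    ModelParams,
    OptimumResult,
    PhenotypeDistribution,
)

__all__ = [
    "gaussian_fitness",
    "mean_fitness_at",
    "mean_fitness_numeric",
    "expected_mean_fitness_given_vp",
    "expected_mean_fitness_numeric",
    "vg_shoc",
    "pbar_displacement_variance",
    "phenotype_distribution",
    "expected_mean_fitness",
    "fitness_summary",
    "load_approx",
    "optimal_ne",
    "optimal_ne_numeric",
    "finite_optimum_condition",
]

#: integration half-width in standard deviations; wide enough that the
#: truncated Gaussian tails are negligible against 1e-10 tolerances
_QUAD_SD = 12.0
_QUAD_EPS = 1e-12


def gaussian_fitness(p, params: ModelParams, *, absorb_ve: bool = False):
    """Relative fitness of an individual with trait value ``p``.

    ``w(p) = exp(-(p - optimum)^2 / (2 vs))``, so the optimal phenotype
    has fitness one. With ``absorb_ve=True`` the width is ``vs + ve``,
    the effective fitness function acting on genetic values when
    uncorrelated environmental noise contributes to the phenotype.

    Accepts scalars or arrays; returns values in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("trait value p must be finite")
    width = params.vs_eff if absorb_ve else params.vs
    out = np.exp(-((p - params.optimum) ** 2) / (2.0 * width))
    return out if out.ndim else float(out)


def mean_fitness_at(pbar: float, vp: float, vs: float) -> float:
    """Mean fitness of a population with Normal(pbar, vp) phenotypes.

    Averaging the Gaussian fitness function over the phenotype
    distribution (optimum at zero) gives

        wbar = sqrt(vs / (vp + vs)) * exp(-pbar^2 / (2 (vp + vs))).
    """
    if vs <= 0:
        raise ValueError(f"vs = {vs!r} must be > 0")
    if vp < 0:
        raise ValueError(f"vp = {vp!r} must be >= 0")
    return math.sqrt(vs / (vp + vs)) * math.exp(-(pbar**2) / (2.0 * (vp + vs)))


def mean_fitness_numeric(pbar: float, vp: float, vs: float) -> float:
    """Quadrature oracle for :func:`mean_fitness_at` (tests only).

    Integrates ``w(p) * Normal(p; pbar, vp)`` by adaptive quadrature.
    """
    if vs <= 0:
        raise ValueError(f"vs = {vs!r} must be > 0")
    if vp == 0:
        return math.exp(-(pbar**2) / (2.0 * vs))
    sd = math.sqrt(vp)

    def integrand(p: float) -> float:
        return math.exp(-(p**2) / (2.0 * vs)) * math.exp(
            -((p - pbar) ** 2) / (2.0 * vp)
        ) / (sd * math.sqrt(2.0 * math.pi))

    lo, hi = pbar - _QUAD_SD * sd, pbar + _QUAD_SD * sd
    value, err = integrate.quad(integrand, lo, hi, epsabs=_QUAD_EPS, epsrel=_QUAD_EPS)
    if err > 1e-8:
        raise RuntimeError(f"quadrature did not converge (error estimate {err:g})")
    return value


def expected_mean_fitness_given_vp(ne: float, vp: float, vs: float) -> float:
    """Expected mean fitness once mean-phenotype drift is averaged out.

    The mean phenotype fluctuates around the optimum with variance
    ``vs / (2 ne)``; integrating the population mean fitness over those
    fluctuations gives

        E[wbar] = [2 ne vs / (vs + 2 ne (vp + vs))]^(1/2),

    which decreases with ``vp`` and recovers ``sqrt(vs / (vp + vs))`` as
    ``ne`` grows large.
    """
    if ne < 1:
        raise ValueError(f"ne = {ne!r} must be >= 1")
    if vs <= 0:
        raise ValueError(f"vs = {vs!r} must be > 0")
    if vp < 0:
        raise ValueError(f"vp = {vp!r} must be >= 0")
    return math.sqrt(2.0 * ne * vs / (vs + 2.0 * ne * (vp + vs)))


def expected_mean_fitness_numeric(ne: float, vp: float, vs: float) -> float:
    """Nested-quadrature oracle for :func:`expected_mean_fitness_given_vp`
    (tests only).

    Evaluates the double integral over phenotype ``p`` and mean phenotype
    ``pbar`` with the displacement density Normal(0, vs / (2 ne)); both
    integrals use adaptive quadrature with absolute tolerance <= 1e-10
    and bounds at +/- 12 standard deviations.
    """
    if ne < 1:
        raise ValueError(f"ne = {ne!r} must be >= 1")
    if vs <= 0:
        raise ValueError(f"vs = {vs!r} must be > 0")
    delta_var = vs / (2.0 * ne)
    delta_sd = math.sqrt(delta_var)

    def outer(pbar: float) -> float:
        dens = math.exp(-(pbar**2) / (2.0 * delta_var)) / (
            delta_sd * math.sqrt(2.0 * math.pi)
        )
        return dens * mean_fitness_numeric(pbar, vp, vs)

    lo, hi = -_QUAD_SD * delta_sd, _QUAD_SD * delta_sd
    value, err = integrate.quad(
        outer, lo, hi, epsabs=_QUAD_EPS, epsrel=_QUAD_EPS, limit=200
    )
    if err > 1e-8:
        raise RuntimeError(f"quadrature did not converge (error estimate {err:g})")
    return value


def vg_shoc(params: ModelParams, *, absorb_ve: bool = False) -> float:
    """Equilibrium additive genetic variance under the stochastic
    house-of-cards (SHOC) interpolation.

        vg = 4 u vs / (1 + vs / (ne vm)).

    Strong effects (``ne vm >> vs``) recover the house-of-cards result
    ``4 u vs``; weak effects recover the drift-limited ``4 ne u vm``.
    """
    vs = params.vs_eff if absorb_ve else params.vs
    return 4.0 * params.u * vs / (1.0 + vs / (params.ne * params.vm))


def pbar_displacement_variance(params: ModelParams) -> float:
    """Variance ``vs_eff / (2 ne)`` of the mean-phenotype displacement
    from the optimum at stationarity."""
    return params.vs_eff / (2.0 * params.ne)


def phenotype_distribution(params: ModelParams) -> PhenotypeDistribution:
    """Equilibrium phenotype moments: SHOC genetic variance, phenotypic
    variance ``vg + ve``, mean at the optimum in expectation, and the
    drift variance of the mean."""
    vg = vg_shoc(params, absorb_ve=True)
    return PhenotypeDistribution(
        mean=params.optimum,
        vg=vg,
        vp=vg + params.ve,
        delta_var=pbar_displacement_variance(params),
    )


def expected_mean_fitness(params: ModelParams, ne: Optional[float] = None) -> float:
    """Expected mean fitness at mutation-selection-drift balance.

    Substituting the SHOC genetic variance into the drift-averaged mean
    fitness gives the closed form

        E[wbar] = [2 ne / (1 + 2 ne (1 + 4 ne u vm / (ne vm + vs)))]^(1/2)

    with ``vs`` replaced by ``vs + ve`` throughout (environmental noise
    is absorbed into the fitness function). ``ne`` overrides
    ``params.ne`` when given, which the optimum search uses to treat
    population size as the free variable.
    """
    n = params.ne if ne is None else ne
    if n <= 0:
        raise ValueError(f"ne = {n!r} must be > 0")
    vs = params.vs_eff
    ratio = 4.0 * n * params.u * params.vm / (n * params.vm + vs)
    return math.sqrt(2.0 * n / (1.0 + 2.0 * n * (1.0 + ratio)))


def fitness_summary(params: ModelParams) -> FitnessSummary:
    """Expected mean fitness and genetic load for one parameter set."""
    return FitnessSummary(expected_wbar=expected_mean_fitness(params))


def load_approx(params: ModelParams, ne: Optional[float] = None) -> float:
    """Small-load expansion of the genetic load.

        load ~= 2 ne vm u / (ne vm + vs) + 1 / (4 ne),

    the complement of the first-order expansion of the closed-form
    fitness. Reads off the two limits directly: ``2 u`` for large
    populations with strong effects, ``1 / (4 ne)`` for small ones. The
    exact closed form (:func:`expected_mean_fitness`) remains the primary
    prediction; this expansion is only loosely accurate in between.
    """
    n = params.ne if ne is None else ne
    if n <= 0:
        raise ValueError(f"ne = {n!r} must be > 0")
    vs = params.vs_eff
    return 2.0 * n * params.vm * params.u / (n * params.vm + vs) + 1.0 / (4.0 * n)


def finite_optimum_condition(params: ModelParams) -> OptimumResult:
    """Whether expected mean fitness is maximized at a finite population
    size, with the thresholds that decide it.

    The condition is ``u > vm / (8 (vs + ve))`` (strict); equivalently
    ``L > vm / (8 mu (vs + ve))`` in terms of target size when the
    per-base rate ``mu`` is known. ``ne_star`` is not computed here; see
    :func:`optimal_ne`.
    """
    threshold_u = params.vm / (8.0 * params.vs_eff)
    threshold_L = None
    if params.mu is not None and params.mu > 0:
        threshold_L = params.vm / (8.0 * params.mu * params.vs_eff)
    finite = params.u > threshold_u
    return OptimumResult(
        finite=finite, ne_star=None if not finite else _ne_star(params),
        threshold_u=threshold_u, threshold_L=threshold_L,
    )


def _ne_star(params: ModelParams) -> float:
    vs = params.vs_eff
    num = vs * (1.0 + math.sqrt(8.0 * params.u * vs / params.vm))
    return num / (8.0 * params.u * vs - params.vm)


def optimal_ne(params: ModelParams) -> OptimumResult:
    """Closed-form population size maximizing expected mean fitness.

    Setting the ``ne`` derivative of the closed-form fitness to zero
    yields

        ne* = vs (1 + sqrt(8 u vs / vm)) / (8 u vs - vm)

    (``vs`` meaning ``vs + ve``), positive exactly when
    ``8 u vs > vm``. At the boundary ``8 u vs = vm`` the denominator
    vanishes and the optimum recedes to infinity, reported as no finite
    optimum. ``params.ne`` is ignored.
    """
    return finite_optimum_condition(params)


def optimal_ne_numeric(
    params: ModelParams,
    *,
    ne_lo: float = 1e-2,
    ne_hi: float = 1e10,
    n_scan: int = 400,
) -> Tuple[float, float]:
    """Numeric-maximization oracle for :func:`optimal_ne` (tests only).

    Scans ``log ne`` over ``[ne_lo, ne_hi]``, brackets the best point,
    then refines with bounded scalar minimization. Returns
    ``(ne_star, expected_wbar)``. Population size is treated as a
    continuous variable throughout.
    """
    grid = np.logspace(math.log10(ne_lo), math.log10(ne_hi), n_scan)
    values = np.array([expected_mean_fitness(params, ne=n) for n in grid])
    k = int(np.argmax(values))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_scan - 1)]

    res = optimize.minimize_scalar(
        lambda lg: -expected_mean_fitness(params, ne=math.exp(lg)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-13},
    )
    ne_best = math.exp(res.x)
    return ne_best, expected_mean_fitness(params, ne=ne_best)
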