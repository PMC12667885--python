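"""Parameter bundles and result records shared across the analytic model,
the Wright-Fisher simulator, and the validation sweeps.

All trait-scale quantities are in trait units (variances in trait units
squared); mutation rates are per gamete per generation; population sizes
count diploid individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ModelParams",
    "PhenotypeDistribution",
    "FitnessSummary",
    "OptimumResult",
]

#: relative tolerance for the U = mu * L consistency check
_U_MUL_RTOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the single-trait Gaussian stabilizing-selection model.

    Parameters
    ----------
    ne : float
        Effective population size (diploid individuals). Treated as a
        continuous quantity by the closed forms.
    u : float
        Total per-gamete mutation rate per generation across all
        trait-affecting loci. Equals ``mu * L`` when both are supplied.
    vm : float
        Variance of the effect-size distribution of new mutations.
        New mutational effects are drawn from ``Normal(0, vm)``.
    vs : float
        Inverse strength of stabilizing selection: the squared width of
        the Gaussian fitness function. Larger ``vs`` means weaker
        selection.
    ve : float, optional
        Environmental variance added to phenotypes, default 0. Absorbed
        into the fitness function as ``vs + ve`` wherever that absorption
        is exact.
    optimum : float, optional
        Optimal trait value, default 0.
    mu : float, optional
        Per-base haploid mutation rate per generation. Informational
        unless paired with ``L``.
    L : float, optional
        Mutational target size of the trait in bases.

    Raises
    ------
    ValueError
        If any parameter violates its domain, or if ``mu * L`` disagrees
        with ``u`` beyond relative tolerance 1e-12.
    """

    ne: float
    u: float
    vm: float
    vs: float
    ve: float = 0.0
    optimum: float = 0.0
    mu: Optional[float] = None
    L: Optional[float] = None

    def __post_init__(self) -> None:
        checks = [
            (self.ne >= 1, "ne", "must be >= 1"),
            (self.u >= 0, "u", "must be >= 0"),
            (self.vm > 0, "vm", "must be > 0"),
            (self.vs > 0, "vs", "must be > 0"),
            (self.ve >= 0, "ve", "must be >= 0"),
        ]
        for ok, name, msg in checks:
            value = getattr(self, name)
            if not (ok and math.isfinite(value)):
                raise ValueError(f"ModelParams.{name} = {value!r} {msg} and be finite")
        if not math.isfinite(self.optimum):
            raise ValueError(f"ModelParams.optimum = {self.optimum!r} must be finite")
        if self.mu is not None and self.mu < 0:
            raise ValueError(f"ModelParams.mu = {self.mu!r} must be >= 0")
        if self.L is not None and self.L < 0:
            raise ValueError(f"ModelParams.L = {self.L!r} must be >= 0")
        if self.mu is not None and self.L is not None:
            expected = self.mu * self.L
            if not math.isclose(self.u, expected, rel_tol=_U_MUL_RTOL, abs_tol=0.0):
                raise ValueError(
                    f"ModelParams.u = {self.u!r} inconsistent with mu * L = {expected!r}"
                )

    @property
    def vs_eff(self) -> float:
        """Effective width of the fitness function, ``vs + ve``.

        Uncorrelated environmental noise broadens the realized fitness
        function acting on genetic values, so everywhere the closed forms
        use ``vs`` they may equivalently use ``vs + ve`` on genetic values
        alone.
        """
        return self.vs + self.ve

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Moments of the phenotype distribution at mutation-selection-drift
    balance.

    ``mean`` is the population mean phenotype; ``vp`` and ``vg`` are the
    phenotypic and additive genetic variances (equal when there is no
    environmental noise); ``delta_var`` is the variance of the random
    displacement of the mean phenotype from the optimum, ``vs / (2 ne)``
    under the diffusion prediction.
    """

    mean: float
    vp: float
    vg: float
    delta_var: float

    def __post_init__(self) -> None:
        if self.vp < 0 or self.vg < 0 or self.delta_var < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class FitnessSummary:
    """Expected mean fitness and the corresponding genetic load."""

    expected_wbar: float
    load: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.expected_wbar <= 1.0):
            raise ValueError(f"expected_wbar = {self.expected_wbar!r} not in (0, 1]")
        object.__setattr__(self, "load", 1.0 - self.expected_wbar)


@dataclass(frozen=True)
class OptimumResult:
    """Whether a finite population size maximizes expected mean fitness.

    ``finite`` is True exactly when the total mutation rate exceeds
    ``threshold_u = vm / (8 (vs + ve))``; then ``ne_star`` holds the
    maximizing effective size. ``threshold_L`` is the equivalent bound on
    the mutational target size, available when the per-base rate ``mu``
    is known.
    """

    finite: bool
    ne_star: Optional[float]
    threshold_u: float
    threshold_L: Optional[float] = None

    def __post_init__(self) -> None:
        if self.finite and (self.ne_star is None or self.ne_star <= 0):
            raise ValueError("finite optimum requires ne_star > 0")
        if not self.finite and self.ne_star is not None:
            raise ValueError("ne_star must be absent when no finite optimum exists")
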