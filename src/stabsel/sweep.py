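"""Validation sweeps: simulated versus predicted mean fitness, genetic
variance, and mean-phenotype fluctuations over a (population size,
mutation rate, mutational variance) grid.

Each grid cell runs a set of independent Wright-Fisher replicates and
places the closed-form predictions next to the across-replicate 95%
confidence intervals — prediction curves overlaid with simulated
points and error bars. Diagnostics flag the two regimes where the closed forms
are expected to fail: very small populations, where the Gaussian
approximation for mean-phenotype drift breaks down, and strong-effect /
high-rate architectures, where the stochastic house-of-cards formula
underestimates the genetic variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analytic
from .params import ModelParams
from .simulate import SimConfig, run_replicates, summarize

__all__ = [
    "SweepGrid",
    "SweepRow",
    "NonMonotonicReport",
    "BreakdownReport",
    "cell_seed",
    "HeadlineReport",
    "small_vs_large_comparison",
    "run_cell",
    "run_sweep",
    "sweep_dataframe",
    "nonmonotonic_fitness_check",
    "breakdown_diagnostics",
    "plot_sweep",
    "DESK_GRID",
    "FULL_GRID",
]


@dataclass(frozen=True)
class SweepGrid:
    """A factorial (ne, u, vm) validation grid at fixed vs, ve."""

    ne_values: tuple
    u_values: tuple
    vm_values: tuple
    vs: float = 1.0
    ve: float = 0.0
    replicates: int = 20
    n_samples: int = 30
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ne_values", "u_values", "vm_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"SweepGrid.{name} must be non-empty")
            if name == "u_values":  # u = 0 is a valid mutation-free control
                bad = any(v < 0 for v in vals)
            else:
                bad = any(v <= 0 for v in vals)
            if bad:
                raise ValueError(f"SweepGrid.{name} values must be positive")
        if self.replicates < 2:
            raise ValueError("SweepGrid.replicates must be >= 2 for CIs")

    def cells(self):
        idx = 0
        for ne in self.ne_values:
            for u in self.u_values:
                for vm in self.vm_values:
                    yield idx, int(ne), float(u), float(vm)
                    idx += 1

    @property
    def n_cells(self) -> int:
        return len(self.ne_values) * len(self.u_values) * len(self.vm_values)


#: desk-scale validation grid (regimes where the closed forms hold)
DESK_GRID = SweepGrid(
    ne_values=(500, 1000),
    u_values=(0.005, 0.01),
    vm_values=(1e-4, 1e-3),
)

#: wider grid spanning the breakdown regimes as well; several hours of
#: compute at the default replication
FULL_GRID = SweepGrid(
    ne_values=(100, 300, 1000, 3000, 10000),
    u_values=(0.001, 0.01, 0.05),
    vm_values=(1e-4, 1e-3, 1e-2),
)


@dataclass(frozen=True)
class SweepRow:
    """One validation cell: closed-form predictions beside simulated
    across-replicate means with 95% CIs."""

    ne: int
    u: float
    vm: float
    vs: float
    ve: float
    seed: int
    predicted: float = math.nan
    simulated: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    covered: bool = False
    vg_predicted: float = math.nan
    vg_simulated: float = math.nan
    vg_ci_low: float = math.nan
    vg_ci_high: float = math.nan
    vg_covered: bool = False
    pbar_var_predicted: float = math.nan
    pbar_var_simulated: float = math.nan
    error: Optional[str] = None


def cell_seed(base_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed from the grid's base seed.

    Derived through ``SeedSequence`` so cells stay reproducible under
    grid reordering or partial re-runs.
    """
    return int(np.random.SeedSequence((base_seed, cell_index)).generate_state(1)[0] % (2**31))


def run_cell(
    ne: int,
    u: float,
    vm: float,
    grid: SweepGrid,
    seed: int,
    engine: str = "fast",
) -> SweepRow:
    """Simulate one grid cell and compare it with the closed forms."""
    params = ModelParams(ne=float(ne), u=u, vm=vm, vs=grid.vs, ve=grid.ve)
    predicted = analytic.expected_mean_fitness(params)
    vg_pred = analytic.vg_shoc(params, absorb_ve=True)
    pvar_pred = analytic.pbar_displacement_variance(params)
    cfg = SimConfig(
        n=ne, u=u, vm=vm, vs=grid.vs, ve=grid.ve,
        n_samples=grid.n_samples, seed=seed, replicates=grid.replicates,
    )
    try:
        results = run_replicates(cfg, engine=engine)
    except Exception as exc:  # noqa: BLE001 - failed cells are flagged, not fatal
        return SweepRow(
            ne=ne, u=u, vm=vm, vs=grid.vs, ve=grid.ve, seed=seed,
            predicted=predicted, vg_predicted=vg_pred,
            pbar_var_predicted=pvar_pred, error=str(exc),
        )
    wbar = summarize(results, "mean_fitness")
    vg = summarize(results, "vg")
    pvar = summarize(results, "pbar_sq")
    return SweepRow(
        ne=ne, u=u, vm=vm, vs=grid.vs, ve=grid.ve, seed=seed,
        predicted=predicted,
        simulated=wbar.mean, ci_low=wbar.ci_low, ci_high=wbar.ci_high,
        covered=wbar.covers(predicted),
        vg_predicted=vg_pred,
        vg_simulated=vg.mean, vg_ci_low=vg.ci_low, vg_ci_high=vg.ci_high,
        vg_covered=vg.covers(vg_pred),
        pbar_var_predicted=pvar_pred, pbar_var_simulated=pvar.mean,
    )


def run_sweep(grid: SweepGrid, engine: str = "fast", progress: bool = False) -> list[SweepRow]:
    """Run every cell of the grid; failures are flagged per cell rather
    than aborting the sweep. Deterministic given ``grid.base_seed``."""
    rows = []
    for idx, ne, u, vm in grid.cells():
        if progress:
            print(f"[stabsel] cell {idx + 1}/{grid.n_cells}: ne={ne} u={u} vm={vm}")
        rows.append(run_cell(ne, u, vm, grid, cell_seed(grid.base_seed, idx), engine=engine))
    return rows


def sweep_dataframe(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


@dataclass(frozen=True)
class NonMonotonicReport:
    """Analytic rise-then-fall check of expected mean fitness in ne."""

    peak_ne: float
    peak_fitness: float
    ne_star: float
    grid_step_ratio: float
    peak_matches_ne_star: bool


def nonmonotonic_fitness_check(
    u: float,
    vm: float,
    vs: float = 1.0,
    ve: float = 0.0,
    ne_grid: Optional[np.ndarray] = None,
) -> NonMonotonicReport:
    """Verify that expected mean fitness rises then falls with ``ne``,
    peaking at the closed-form optimum.

    Raises ``ValueError`` when the finite-optimum condition
    ``u > vm / (8 (vs + ve))`` fails, since then no interior peak
    exists.
    """
    params = ModelParams(ne=1.0, u=u, vm=vm, vs=vs, ve=ve)
    opt = analytic.optimal_ne(params)
    if not opt.finite:
        raise ValueError(
            "no finite optimum: u <= vm / (8 (vs + ve)) "
            f"(u={u:g}, threshold={opt.threshold_u:g})"
        )
    if ne_grid is None:
        ne_grid = np.logspace(0, 8, 200)
    ne_grid = np.asarray(ne_grid, dtype=float)
    values = np.array([analytic.expected_mean_fitness(params, ne=n) for n in ne_grid])
    k = int(np.argmax(values))
    interior = 0 < k < len(ne_grid) - 1
    rises_then_falls = interior and values[k] > values[0] and values[k] > values[-1]
    step = ne_grid[min(k + 1, len(ne_grid) - 1)] / ne_grid[k]
    ratio = opt.ne_star / ne_grid[k]
    matches = rises_then_falls and (1.0 / step <= ratio <= step)
    return NonMonotonicReport(
        peak_ne=float(ne_grid[k]),
        peak_fitness=float(values[k]),
        ne_star=opt.ne_star,
        grid_step_ratio=float(step),
        peak_matches_ne_star=bool(matches),
    )


@dataclass(frozen=True)
class HeadlineReport:
    """Simulated mean fitness at a small population near the predicted
    optimum versus a population ``factor`` times larger."""

    n_small: int
    n_large: int
    ne_star: float
    wbar_small: float
    wbar_large: float
    ci_small: float
    ci_large: float

    @property
    def gap(self) -> float:
        return self.wbar_small - self.wbar_large

    @property
    def joint_ci(self) -> float:
        """Half-width of the CI on the difference of the two means."""
        return math.hypot(self.ci_small, self.ci_large)

    @property
    def significant(self) -> bool:
        return self.gap > self.joint_ci


def small_vs_large_comparison(
    u: float,
    vm: float,
    vs: float = 1.0,
    ve: float = 0.0,
    factor: int = 100,
    replicates: int = 12,
    n_samples: int = 30,
    base_seed: int = 0,
    engine: str = "fast",
) -> HeadlineReport:
    """Simulate the headline phenomenon: when ``u`` exceeds
    ``vm / (8 (vs + ve))``, a small population near the predicted optimal
    size out-performs one ``factor`` times larger in realized mean
    fitness.

    Raises ``ValueError`` when the finite-optimum condition fails.
    """
    params = ModelParams(ne=1.0, u=u, vm=vm, vs=vs, ve=ve)
    opt = analytic.optimal_ne(params)
    if not opt.finite:
        raise ValueError(
            f"no finite optimum for u={u:g}, vm={vm:g}: nothing to compare"
        )
    n_small = max(2, round(opt.ne_star))
    n_large = n_small * factor
    sums = []
    for idx, n in enumerate((n_small, n_large)):
        cfg = SimConfig(
            n=n, u=u, vm=vm, vs=vs, ve=ve, n_samples=n_samples,
            seed=cell_seed(base_seed, idx), replicates=replicates,
        )
        sums.append(summarize(run_replicates(cfg, engine=engine), "mean_fitness"))
    return HeadlineReport(
        n_small=n_small, n_large=n_large, ne_star=opt.ne_star,
        wbar_small=sums[0].mean, wbar_large=sums[1].mean,
        ci_small=sums[0].ci_halfwidth, ci_large=sums[1].ci_halfwidth,
    )


@dataclass(frozen=True)
class BreakdownReport:
    """Cells flagged against the two known failure modes of the theory."""

    small_ne_cells: list = field(default_factory=list)
    shoc_underestimate_cells: list = field(default_factory=list)
    failed_cells: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.small_ne_cells) + len(self.shoc_underestimate_cells)


#: relative deviation of simulated Var(pbar) from vs/(2 ne) that flags a cell
SMALL_NE_TOLERANCE = 0.5


def breakdown_diagnostics(rows: Sequence[SweepRow]) -> BreakdownReport:
    """Map sweep cells onto the theory's two stated failure modes.

    A cell is a *small-ne* breakdown when the simulated variance of the
    mean phenotype deviates from ``vs / (2 ne)`` by more than 50%
    (the Gaussian drift approximation for the mean has failed), and a
    *SHOC-underestimate* breakdown when the simulated genetic variance
    sits entirely above the predicted value (its 95% CI excludes it from
    above).
    """
    report = BreakdownReport()
    for r in rows:
        key = (r.ne, r.u, r.vm)
        if r.error is not None:
            report.failed_cells.append(key)
            continue
        if r.u == 0:
            continue
        if r.pbar_var_predicted > 0 and math.isfinite(r.pbar_var_simulated):
            rel = abs(r.pbar_var_simulated / r.pbar_var_predicted - 1.0)
            if rel > SMALL_NE_TOLERANCE:
                report.small_ne_cells.append(key)
        if math.isfinite(r.vg_ci_low) and r.vg_ci_low > r.vg_predicted:
            report.shoc_underestimate_cells.append(key)
    return report


def plot_sweep(rows: Sequence[SweepRow], path: str, vs: float = 1.0, ve: float = 0.0):
    """Panel plot of mean fitness vs population size: analytic curves
    with simulated points and 95% error bars, one panel per (u, vm)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep_dataframe(rows)
    combos = sorted(set(zip(df["u"], df["vm"])))
    ncol = len(combos)
    fig, axes = plt.subplots(1, ncol, figsize=(4 * ncol, 3.2), squeeze=False, sharey=False)
    for ax, (u, vm) in zip(axes[0], combos):
        sub = df[(df["u"] == u) & (df["vm"] == vm)]
        ne_curve = np.logspace(
            math.log10(max(1.0, sub["ne"].min() / 10)), math.log10(sub["ne"].max() * 10), 200
        )
        params = ModelParams(ne=1.0, u=u, vm=vm, vs=vs, ve=ve)
        curve = [analytic.expected_mean_fitness(params, ne=n) for n in ne_curve]
        ax.plot(ne_curve, curve, "-", color="C0", label="prediction")
        ax.errorbar(
            sub["ne"], sub["simulated"],
            yerr=[sub["simulated"] - sub["ci_low"], sub["ci_high"] - sub["simulated"]],
            fmt="o", color="C3", capsize=3, label="simulation",
        )
        ax.set_xscale("log")
        ax.set_xlabel("population size $N_e$")
        ax.set_title(f"$U$={u:g}, $V_M$={vm:g}", fontsize=10)
    axes[0][0].set_ylabel(r"mean fitness $E[\bar{w}]$")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
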