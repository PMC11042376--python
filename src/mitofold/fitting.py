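"""Grid-search fitting of chromatid-model parameters to a target P(s).

The three free parameters (average loop size, inter-condensin gap, linear
density along the axis) are explored on a grid; each grid point is scored
by simulating replicate chromatids, computing the ensemble P(s), and
measuring the RMS log10 deviation from the target over the fit range. Grid
search is used because each evaluation is a stochastic simulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chromatid import (ChromatidParams, build_chromatid,
                        build_nested_bottlebrush)
from .contacts import PsCurve, ps_curve_from_conformations
from .synthetic import exponential_loop_array

__all__ = [
    "FitSpec",
    "FitResult",
    "NestedChromatidParams",
    "simulate_ps",
    "goodness_of_fit",
    "fit_grid",
    "combine_nested_model",
]


@dataclass
class NestedChromatidParams:
    """Condensin II outer loops with condensin I loops nested inside."""

    outer: ChromatidParams
    inner: ChromatidParams

    @property
    def loops_per_outer(self) -> float:
        return self.outer.loop_bp / self.inner.loop_bp


@dataclass
class FitSpec:
    loop_bp_grid: tuple[float, ...] = (100e3, 200e3, 400e3, 800e3)
    gap_nm_grid: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0)
    linear_density_grid: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0)
    turn_mb: float | None = 17.0
    volume_density_mb_um3: float = 44.0
    helix_mode: str = "helical_cylinder"
    end_to_end_um: float = 4.0
    replicates: int = 10
    seed0: int = 0
    genome_mb: float = 100.0
    fit_range_bp: tuple[float, float] = (3e4, 6e7)
    bead_bp: int = 10_000

    def __post_init__(self) -> None:
        for g in (self.loop_bp_grid, self.gap_nm_grid, self.linear_density_grid):
            if len(g) == 0:
                raise ValueError("parameter grids must be non-empty")
        if self.fit_range_bp[0] >= self.fit_range_bp[1]:
            raise ValueError("invalid fit range")

    def params_at(self, loop_bp: float, gap_nm: float, lin_density: float
                  ) -> ChromatidParams:
        return ChromatidParams(
            loop_bp=loop_bp, gap_nm=gap_nm, linear_density_mb_um=lin_density,
            turn_mb=self.turn_mb if self.helix_mode == "helical_cylinder" else None,
            volume_density_mb_um3=self.volume_density_mb_um3,
            helix_mode=self.helix_mode, end_to_end_um=self.end_to_end_um,
            bead_bp=self.bead_bp,
        )


@dataclass
class FitResult:
    best_params: ChromatidParams
    gof: float
    surface: pd.DataFrame
    degenerate: bool = False

    def within_one_step(self, loop_bp: float, gap_nm: float,
                        spec: FitSpec) -> bool:
        """Whether the best grid point is the truth or a grid neighbor."""
        def ok(grid, best, true):
            grid = sorted(grid)
            if true not in grid:
                return False
            i, j = grid.index(best), grid.index(true)
            return abs(i - j) <= 1
        return (ok(spec.loop_bp_grid, self.best_params.loop_bp, loop_bp)
                and ok(spec.gap_nm_grid, self.best_params.gap_nm, gap_nm))


def simulate_ps(params: ChromatidParams | NestedChromatidParams,
                genome_mb: float = 100.0, replicates: int = 10,
                seed0: int = 0, bins_per_decade: float = 25.0,
                return_replicate_curves: bool = False):
    """Ensemble-averaged P(s) for a chromatid model.

    Each replicate draws its own exponential loop array and conformation;
    identical seeds give identical curves.
    """
    genome_bp = genome_mb * 1e6
    confs = []
    for r in range(replicates):
        seed = seed0 + 7919 * r
        if isinstance(params, NestedChromatidParams):
            loops_outer = exponential_loop_array(
                genome_bp, params.outer.loop_bp, seed,
                min_loop_bp=2 * params.outer.bead_bp)
            loops_inner = _nest_loops(loops_outer, params.inner.loop_bp,
                                      np.random.default_rng(seed + 1),
                                      min_loop_bp=2 * params.inner.bead_bp)
            conf = build_nested_bottlebrush(loops_outer, loops_inner,
                                            params.outer, params.inner,
                                            genome_bp, seed)
        else:
            loops = exponential_loop_array(genome_bp, params.loop_bp, seed,
                                           min_loop_bp=2 * params.bead_bp)
            conf = build_chromatid(loops, params, genome_bp, seed)
        confs.append(conf)
    if return_replicate_curves:
        return [ps_curve_from_conformations([c], bins_per_decade=bins_per_decade)
                for c in confs]
    return ps_curve_from_conformations(confs, bins_per_decade=bins_per_decade)


def _nest_loops(loops_outer: np.ndarray, mean_inner_bp: float,
                rng: np.random.Generator, min_loop_bp: float) -> np.ndarray:
    inner = []
    for a, b in loops_outer:
        cursor = a
        while cursor < b:
            size = max(rng.exponential(mean_inner_bp), min_loop_bp)
            inner.append((cursor, min(cursor + size, b)))
            cursor += size
    return np.array(inner, dtype=float)


def goodness_of_fit(model_ps: PsCurve, target_ps: PsCurve,
                    fit_range_bp: tuple[float, float] = (3e4, 6e7),
                    background_floor: float | None = None) -> float:
    """RMS of log10(model/target) over the fit range (lower is better).

    Bins where either curve sits at or below the background floor (default
    1e-6 of its maximum) are masked.
    """
    ok_t = np.isfinite(target_ps.p) & (target_ps.p > 0)
    ok_m = np.isfinite(model_ps.p) & (model_ps.p > 0)
    if background_floor is None:
        floor_t = 1e-6 * np.nanmax(target_ps.p)
        floor_m = 1e-6 * np.nanmax(model_ps.p)
    else:
        floor_t = floor_m = background_floor
    s_t = target_ps.s_bp
    lo = max(fit_range_bp[0], model_ps.s_bp[ok_m].min(), s_t[ok_t].min())
    hi = min(fit_range_bp[1], model_ps.s_bp[ok_m].max(), s_t[ok_t].max())
    if lo >= hi:
        raise ValueError("model and target P(s) ranges do not overlap the fit range")
    sel = ok_t & (s_t >= lo) & (s_t <= hi) & (target_ps.p > floor_t)
    # log-space interpolation of model onto target s grid, unit-sum scale-free
    lm = np.interp(np.log10(s_t[sel]), np.log10(model_ps.s_bp[ok_m]),
                   np.log10(model_ps.p[ok_m]))
    keep = lm > np.log10(floor_m)
    lt = np.log10(target_ps.p[sel])
    diff = (lm - lt)[keep]
    return float(np.sqrt(np.mean(diff ** 2)))


def fit_grid(target_ps: PsCurve, spec: FitSpec) -> FitResult:
    """Exhaustive grid evaluation; returns the best point and the surface."""
    rows = []
    for loop_bp, gap_nm, lin in itertools.product(
            spec.loop_bp_grid, spec.gap_nm_grid, spec.linear_density_grid):
        params = spec.params_at(loop_bp, gap_nm, lin)
        try:
            curves = simulate_ps(params, genome_mb=spec.genome_mb,
                                 replicates=spec.replicates, seed0=spec.seed0,
                                 return_replicate_curves=True)
            gofs = [goodness_of_fit(c, target_ps, spec.fit_range_bp)
                    for c in curves]
        except (ValueError, FloatingPointError) as err:
            warnings.warn(f"grid point ({loop_bp}, {gap_nm}, {lin}) failed: {err}")
            continue
        rows.append({
            "loop_bp": loop_bp, "gap_nm": gap_nm, "linear_density": lin,
            "gof": float(np.mean(gofs)),
            "gof_sem": float(np.std(gofs) / np.sqrt(len(gofs))),
        })
    if not rows:
        raise RuntimeError("all grid points failed")
    surface = pd.DataFrame(rows)
    best = surface.loc[surface["gof"].idxmin()]
    best_params = spec.params_at(best["loop_bp"], best["gap_nm"],
                                 best["linear_density"])
    # near-tied surface: absolute spread within noise, or spread small
    # relative to a uniformly poor fit level (nothing to discriminate)
    spread = surface["gof"].max() - surface["gof"].min()
    degenerate = bool(spread < 2 * surface["gof_sem"].median()
                      or spread < 0.1 * surface["gof"].min())
    if degenerate:
        warnings.warn("near-tied goodness-of-fit surface: degenerate fit")
    return FitResult(best_params, float(best["gof"]), surface, degenerate)


def combine_nested_model(params_II: ChromatidParams, params_I: ChromatidParams,
                         gap_adjustment: float = 1.0) -> NestedChromatidParams:
    """Combine independently fitted condensin II and I models.

    The outer (condensin II) geometry is kept; inner (condensin I) loops
    subdivide each outer loop, with the inner gap optionally rescaled
    (``gap_adjustment``) — the minor correction needed when the two
    independently fitted models are merged.
    """
    if params_I.loop_bp >= params_II.loop_bp:
        warnings.warn("inner loop size >= outer loop size: nesting is degenerate")
    inner = replace(params_I, gap_nm=params_I.gap_nm * gap_adjustment)
    return NestedChromatidParams(outer=params_II, inner=inner)
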