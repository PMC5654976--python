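"""Sequential BMO-MRA: independent minimization of each inter-spoke trapezoid.

Each of the n_spokes cyclic inter-spoke quads (bmo_i, bmo_{i+1},
ilm_{i+1}, ilm_i) is minimized on its own over BOTH ILM endpoint
parameters — a true 2-D minimization per trapezoid, with no continuity
constraint between neighbours — and the per-quad minima are summed
globally and per ONH sector. Because every quad sees the same candidate
set and chirality as the continuity-constrained solver, the sequential
total is a relaxation lower bound for the global solver's total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InputError
from .geometry import (
    Chirality,
    ILMCurve,
    StarScan,
    quad_area,
    quad_area_table,
    resolve_chirality,
    triangle_area,
)
from .results import RimAreaResult, SectorSurface, TrapezoidSolution
from .sectors import GARWAY_HEATH, SectorScheme, aggregate_sectors, quad_mid_angles

__all__ = ["SearchOptions", "minimize_trapezoid", "compute_mra_sequential"]


@dataclass(frozen=True)
class SearchOptions:
    """Candidate-set and refinement settings shared by both solvers.

    step_mm
        Arclength spacing of the uniform densification grid added to the
        ILM polyline vertices (default 10 um). ``None`` uses the vertices
        only.
    refine
        Whether to refine the winning grid candidates continuously
        (bounded Brent search within one candidate spacing).
    refine_tol
        Stop refining when an iteration improves the area by less than
        this (mm^2).
    max_sweeps
        Iteration cap for the refinement loop.
    """

    step_mm: float | None = 0.01
    refine: bool = True
    refine_tol: float = 1e-7
    max_sweeps: int = 100


def _refine_1d(f, t0: float, lo: float, hi: float, f0: float, xatol: float):
    """Bounded scalar minimization around t0; returns (t, f) never worse
    than the incumbent."""
    if hi - lo <= 0:
        return t0, f0
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    if res.fun < f0:
        return float(res.x), float(res.fun)
    return t0, f0


def minimize_trapezoid(
    bmo_i: np.ndarray,
    bmo_j: np.ndarray,
    curve_i: ILMCurve,
    curve_j: ILMCurve,
    diag: Chirality = Chirality.A,
    options: SearchOptions = SearchOptions(),
    sector_index: int = 0,
) -> TrapezoidSolution:
    """Minimize one quad's area jointly over both ILM endpoints.

    Exhaustive search over the candidate grid (all polyline vertices plus
    the uniform densification), then optional alternating continuous
    refinement of the two parameters within one candidate spacing of the
    winner. Ties go to the smallest arclength pair (row-major order of the
    grid).
    """
    t_i = curve_i.candidate_arclengths(options.step_mm)
    t_j = curve_j.candidate_arclengths(options.step_mm)
    if t_i.size == 0 or t_j.size == 0:
        raise InputError("empty candidate set")
    table = quad_area_table(
        bmo_i, bmo_j, curve_i.points_at(t_i), curve_j.points_at(t_j), diag
    )
    flat = int(np.argmin(table))  # first occurrence = lexicographic tie-break
    ri, cj = divmod(flat, table.shape[1])
    ti, tj = float(t_i[ri]), float(t_j[cj])
    area = float(table[ri, cj])

    if options.refine:
        step = options.step_mm or max(curve_i.total_arclength, curve_j.total_arclength)
        xatol = max(1e-9, 0.01 * step)
        for _ in range(options.max_sweeps):
            prev = area
            pj = curve_j.point_at(tj)
            ti, area = _refine_1d(
                lambda t: quad_area(bmo_i, bmo_j, pj, curve_i.point_at(t), diag),
                ti,
                max(0.0, ti - step),
                min(curve_i.total_arclength, ti + step),
                area,
                xatol,
            )
            pi = curve_i.point_at(ti)
            tj, area = _refine_1d(
                lambda t: quad_area(bmo_i, bmo_j, curve_j.point_at(t), pi, diag),
                tj,
                max(0.0, tj - step),
                min(curve_j.total_arclength, tj + step),
                area,
                xatol,
            )
            if prev - area < options.refine_tol:
                break
    return TrapezoidSolution(sector_index=sector_index, t_left=ti, t_right=tj, area=area)


def compute_mra_sequential(
    scan: StarScan,
    options: SearchOptions = SearchOptions(),
    chirality: Chirality | None = None,
    scheme: SectorScheme = GARWAY_HEATH,
) -> RimAreaResult:
    """Standard BMO-MRA: per-trapezoid independent minima, summed.

    Returns one :class:`TrapezoidSolution` per cyclic spoke pair and the
    global and per-sector area sums.
    """
    n = scan.n_spokes
    if n < 3:
        raise InputError("need at least 3 spokes")
    diag = resolve_chirality(scan.eye, chirality)

    solutions = []
    quads = []
    for i in range(n):
        j = (i + 1) % n
        si, sj = scan.spokes[i], scan.spokes[j]
        try:
            sol = minimize_trapezoid(
                si.bmo_point, sj.bmo_point, si.ilm_curve, sj.ilm_curve,
                diag, options, sector_index=i,
            )
        except InputError as exc:
            raise InputError(f"spoke {i}: {exc}") from exc
        solutions.append(sol)
        pi = si.ilm_curve.point_at(sol.t_left)
        pj = sj.ilm_curve.point_at(sol.t_right)
        quads.append(_split_quad(i, si.bmo_point, sj.bmo_point, pj, pi, diag))

    mid = quad_mid_angles(scan.angles_deg)
    sums = aggregate_sectors(scheme, quads, mid, axis_deg=scan.axis_deg)
    return RimAreaResult(
        method="sequential",
        quads=tuple(quads),
        sector_sums=sums,
        total=sums["global"],
        selection=tuple(solutions),
    )


def _split_quad(i, a, b, c, d, diag: Chirality) -> SectorSurface:
    if diag is Chirality.A:
        return SectorSurface(i, triangle_area(a, b, c), triangle_area(a, c, d))
    return SectorSurface(i, triangle_area(a, b, d), triangle_area(b, c, d))
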