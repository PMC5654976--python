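"""Globally optimized BMO-gMRA: continuity-constrained surface minimization.

The rim surface is discretized as two triangles per inter-spoke sector
(96 for a standard 48-spoke scan). BMO vertices are fixed; the one free
ILM vertex per spoke is shared by the two adjacent sectors, so the total
area must be minimized over all (typically 48) degrees of freedom
simultaneously. On the discretized candidate set this cyclic problem is
solved *exactly* by dynamic programming: condition on the candidate of
spoke 0, run a linear chain DP over spokes 1..n-1, close the cycle, and
take the best anchor — O(n * m^2 * m0) for n spokes with m candidates
each. An optional cyclic coordinate-descent refinement then moves each
vertex continuously along its ILM polyline; each accepted move can only
decrease the total.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InputError
from .geometry import (
    Chirality,
    StarScan,
    quad_area,
    quad_area_table,
    resolve_chirality,
)
from .results import RimAreaResult, RimVertexSelection, SectorSurface
from .sectors import GARWAY_HEATH, SectorScheme, aggregate_sectors, quad_mid_angles
from .sequential import SearchOptions, _split_quad

__all__ = ["dp_cyclic_min", "compute_gmra", "resolve_chirality", "build_cost_tables"]

_ANCHOR_CHUNK = 64  # anchors processed per block to bound the min-plus temp array


def dp_cyclic_min(tables: list[np.ndarray]) -> tuple[list[int], float]:
    """Exact minimum of a cyclic chain of pairwise cost tables.

    ``tables[i]`` has shape (m_i, m_{i+1 mod n}) and gives the quad area
    for every candidate pair of spokes i and i+1. Returns the argmin
    candidate indices (lexicographically smallest among optima) and the
    minimal total.
    """
    n = len(tables)
    if n < 2:
        raise InputError("need at least 2 sector tables")
    sizes = [t.shape[0] for t in tables]
    for i, t in enumerate(tables):
        if t.ndim != 2 or t.shape != (sizes[i], sizes[(i + 1) % n]):
            raise InputError(f"table {i} has inconsistent shape {t.shape}")
        if t.shape[0] == 0 or t.shape[1] == 0:
            raise InputError(f"empty candidate list at spoke {i}")

    m0 = sizes[0]
    # forward min-plus over the open chain, all anchors at once (chunked)
    best_total = np.inf
    best_anchor = -1
    totals = np.empty(m0)
    for lo in range(0, m0, _ANCHOR_CHUNK):
        hi = min(lo + _ANCHOR_CHUNK, m0)
        v = tables[0][lo:hi].copy()  # (chunk, m_1)
        for i in range(1, n - 1):
            v = np.min(v[:, :, None] + tables[i][None, :, :], axis=1)
        totals[lo:hi] = np.min(v + tables[-1].T[lo:hi], axis=1)
    best_anchor = int(np.argmin(totals))  # first occurrence = smallest anchor
    best_total = float(totals[best_anchor])

    # backward cost-to-go for the winning anchor, then greedy forward
    # reconstruction (smallest index among float-equal optima).
    w = [None] * n  # w[i][j] = min cost of sectors i..n-1 given spoke-i candidate j
    w[n - 1] = tables[n - 1][:, best_anchor]
    for i in range(n - 2, 0, -1):
        w[i] = np.min(tables[i] + w[i + 1][None, :], axis=1)

    indices = [best_anchor]
    tol = 1e-12 * max(1.0, abs(best_total))
    prev = best_anchor
    for i in range(1, n):
        vals = tables[i - 1][prev] + (w[i] if i < n else 0.0)
        cand = int(np.flatnonzero(vals <= vals.min() + tol)[0])
        indices.append(cand)
        prev = cand
    return indices, best_total


def build_cost_tables(
    scan: StarScan, diag: Chirality, step_mm: float | None
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-spoke candidates and per-sector pairwise area tables.

    Returns (candidate arclengths per spoke, candidate points per spoke,
    tables) where ``tables[i]`` is the (m_i, m_{i+1}) quad-area table of
    sector i. The same tables drive both the sequential minima and the
    cyclic DP, which is what makes the relaxation bound exact.
    """
    n = scan.n_spokes
    ts, pts = [], []
    for i, s in enumerate(scan.spokes):
        t = s.ilm_curve.candidate_arclengths(step_mm)
        if t.size == 0:
            raise InputError(f"spoke {i}: empty candidate set")
        ts.append(t)
        pts.append(s.ilm_curve.points_at(t))
    tables = []
    for i in range(n):
        j = (i + 1) % n
        tables.append(
            quad_area_table(
                scan.spokes[i].bmo_point, scan.spokes[j].bmo_point,
                pts[i], pts[j], diag,
            )
        )
    return ts, pts, tables


def compute_gmra(
    scan: StarScan,
    options: SearchOptions = SearchOptions(),
    chirality: Chirality | None = None,
    scheme: SectorScheme = GARWAY_HEATH,
    _tables=None,
) -> RimAreaResult:
    """BMO-gMRA: exact grid-global minimum, then continuous refinement.

    Continuity is enforced by construction: spoke i's ILM vertex is the
    shared corner of quads i-1 and i. On the candidate grid the returned
    selection is the exact global minimum (cyclic DP); the optional
    coordinate-descent refinement never increases the total.
    """
    n = scan.n_spokes
    if n < 3:
        raise InputError("need at least 3 spokes")
    diag = resolve_chirality(scan.eye, chirality)
    if _tables is None:
        ts, pts, tables = build_cost_tables(scan, diag, options.step_mm)
    else:
        ts, pts, tables = _tables
    indices, _ = dp_cyclic_min(tables)
    t_sel = np.array([ts[i][k] for i, k in enumerate(indices)])
    points = np.array([pts[i][k] for i, k in enumerate(indices)])
    bmo = scan.bmo_points

    def quad_i(i: int, pi: np.ndarray, pj: np.ndarray) -> float:
        j = (i + 1) % n
        return quad_area(bmo[i], bmo[j], pj, pi, diag)

    total = sum(quad_i(i, points[i], points[(i + 1) % n]) for i in range(n))

    if options.refine:
        step = options.step_mm or max(s.ilm_curve.total_arclength for s in scan.spokes)
        xatol = max(1e-9, 0.01 * step)
        converged = False
        for _ in range(options.max_sweeps):
            prev_total = total
            for k in range(n):
                km1 = (k - 1) % n
                curve = scan.spokes[k].ilm_curve
                p_prev = points[km1]
                p_next = points[(k + 1) % n]

                def local(t: float) -> float:
                    p = curve.point_at(t)
                    return quad_i(km1, p_prev, p) + quad_i(k, p, p_next)

                f0 = local(t_sel[k])
                lo = max(0.0, t_sel[k] - step)
                hi = min(curve.total_arclength, t_sel[k] + step)
                if hi <= lo:
                    continue
                res = minimize_scalar(
                    local, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
                )
                if res.fun < f0:
                    total -= f0 - float(res.fun)
                    t_sel[k] = float(res.x)
                    points[k] = curve.point_at(t_sel[k])
            if prev_total - total < options.refine_tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                "gMRA refinement did not converge within max_sweeps; "
                "returning last (still grid-optimal or better) iterate",
                RuntimeWarning,
            )

    quads = tuple(
        _split_quad(i, bmo[i], bmo[(i + 1) % n], points[(i + 1) % n], points[i], diag)
        for i in range(n)
    )
    mid = quad_mid_angles(scan.angles_deg)
    sums = aggregate_sectors(scheme, quads, mid, axis_deg=scan.axis_deg)
    return RimAreaResult(
        method="global",
        quads=quads,
        sector_sums=sums,
        total=sums["global"],
        selection=RimVertexSelection(t=t_sel, points=points),
    )


def compute_both(
    scan: StarScan,
    options: SearchOptions = SearchOptions(),
    chirality: Chirality | None = None,
    scheme: SectorScheme = GARWAY_HEATH,
) -> tuple[RimAreaResult, RimAreaResult]:
    """Sequential and global results from one shared set of cost tables.

    Sharing the tables guarantees the relaxation bound
    ``sequential.total <= global.total`` exactly (before refinement) and
    halves the table-construction work for ``--method both`` runs.
    """
    from .sequential import compute_mra_sequential

    diag = resolve_chirality(scan.eye, chirality)
    tables = build_cost_tables(scan, diag, options.step_mm)
    seq = compute_mra_sequential(scan, options, chirality=diag, scheme=scheme)
    glob = compute_gmra(scan, options, chirality=diag, scheme=scheme, _tables=tables)
    return seq, glob
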