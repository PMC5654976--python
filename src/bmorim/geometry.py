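"""Geometric primitives for radial ONH star scans.

Coordinate frame: right-handed, all lengths in millimetres. ``z`` is the
axial (depth) direction, the ``x``–``y`` plane is the en-face plane. Spoke
angles are measured counterclockwise from the temporal horizontal axis in
right-eye (OD) orientation; left-eye (OS) scans are mirrored about the
vertical en-face axis on load so that all internal processing happens in
the OD frame (laterality is retained for chirality resolution).

A *star scan* is the set of radial B-scans through the ONH centre; each
radial B-scan contributes two *spokes* (one per half), and each spoke
carries one Bruch's-membrane-opening (BMO) point plus the internal
limiting membrane (ILM) segmentation polyline of that half-scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "Chirality",
    "ILMCurve",
    "Spoke",
    "StarScan",
    "point3",
    "triangle_area",
    "quad_area",
    "quad_area_table",
    "interpolate_ilm",
    "bmo_polygon_area",
    "rigid_transform",
    "mirror_scan",
    "resolve_chirality",
]


def point3(x: float, y: float, z: float) -> np.ndarray:
    """A 3-D point as a float array of shape (3,), coordinates in mm."""
    p = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(p)):
        raise InputError(f"non-finite point coordinates: {p}")
    return p


class Chirality(Enum):
    """Which diagonal of an inter-spoke quad the two triangles share.

    For the quad (bmo_i, bmo_{i+1}, ilm_{i+1}, ilm_i):
    ``A`` shares the diagonal bmo_i–ilm_{i+1}; ``B`` shares bmo_{i+1}–ilm_i.
    """

    A = "A"
    B = "B"


def resolve_chirality(eye: str, override: Chirality | None = None) -> Chirality:
    """Diagonal orientation for a given laterality.

    The shared-edge orientation of the triangle pairs is reversed between
    right (OD) and left (OS) eyes so that the discretization carries no
    laterality bias: OD maps to ``A``, OS to ``B``. An explicit ``override``
    wins.
    """
    if override is not None:
        return override
    if eye == "OD":
        return Chirality.A
    if eye == "OS":
        return Chirality.B
    raise InputError(f"unknown eye laterality {eye!r}; expected 'OD' or 'OS'")


# ---------------------------------------------------------------------------
# areas

def _tri_norm(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    c = np.cross(u, v)
    return 0.5 * np.sqrt(np.sum(np.square(c), axis=-1))


def triangle_area(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Area of the 3-D triangle (p, q, r) in mm^2; 0 for degenerate input."""
    return float(_tri_norm(np.asarray(q, float) - p, np.asarray(r, float) - p))


def quad_area(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    diag: Chirality = Chirality.A,
) -> float:
    """Area of the (possibly non-planar) quad (a, b, c, d) as two triangles.

    Vertex order is (bmo_i, bmo_{i+1}, ilm_{i+1}, ilm_i) around the quad.
    With ``Chirality.A`` the triangles share the a–c diagonal, with
    ``Chirality.B`` the b–d diagonal. For non-planar quads the two choices
    differ; for planar quads they agree.
    """
    if diag is Chirality.A:
        return triangle_area(a, b, c) + triangle_area(a, c, d)
    return triangle_area(a, b, d) + triangle_area(b, c, d)


def quad_area_table(
    bmo_i: np.ndarray,
    bmo_j: np.ndarray,
    ilm_i: np.ndarray,
    ilm_j: np.ndarray,
    diag: Chirality,
) -> np.ndarray:
    """Quad areas for every (candidate on spoke i, candidate on spoke j) pair.

    ``ilm_i`` has shape (m_i, 3), ``ilm_j`` shape (m_j, 3); returns an
    (m_i, m_j) table. Row r, column c is the area of the quad
    (bmo_i, bmo_j, ilm_j[c], ilm_i[r]) under the given chirality.
    """
    a = np.asarray(bmo_i, float)
    b = np.asarray(bmo_j, float)
    c = np.asarray(ilm_j, float)
    d = np.asarray(ilm_i, float)
    if diag is Chirality.A:
        # triangles (a,b,c) + (a,c,d): first depends on c only
        t1 = _tri_norm(b - a, c - a)  # (m_j,)
        t2 = _tri_norm((c - a)[None, :, :], (d - a)[:, None, :])  # (m_i, m_j)
        return t1[None, :] + t2
    # triangles (a,b,d) + (b,c,d): first depends on d only
    t1 = _tri_norm(b - a, d - a)  # (m_i,)
    t2 = _tri_norm((c - b)[None, :, :], (d - b)[:, None, :])  # (m_i, m_j)
    return t1[:, None] + t2


# ---------------------------------------------------------------------------
# curves and scans

class ILMCurve:
    """A segmentation polyline parametrized by cumulative arclength.

    The arclength parametrization with linear interpolation makes the curve
    invariant to vertex resampling density. Zero-length segments are
    rejected so that the cumulative arclength is strictly increasing.
    """

    __slots__ = ("vertices", "cum_arclength")

    def __init__(self, vertices: Sequence[Sequence[float]] | np.ndarray):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InputError(f"ILM curve must be an (N, 3) array, got shape {v.shape}")
        if v.shape[0] < 2:
            raise InputError("ILM curve needs at least 2 vertices")
        if not np.all(np.isfinite(v)):
            raise InputError("ILM curve contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg <= 0.0):
            raise InputError("ILM curve has zero-length segment (duplicate vertices)")
        self.vertices = v
        self.cum_arclength = np.concatenate(([0.0], np.cumsum(seg)))

    @property
    def total_arclength(self) -> float:
        return float(self.cum_arclength[-1])

    def point_at(self, t: float) -> np.ndarray:
        """Point at arclength ``t`` (mm) by linear interpolation."""
        if not (0.0 <= t <= self.total_arclength):
            raise InputError(
                f"arclength {t} outside [0, {self.total_arclength}]"
            )
        return self.points_at(np.array([t]))[0]

    def points_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`point_at`; shape (len(t), 3)."""
        t = np.asarray(t, float)
        out = np.empty((t.shape[0], 3))
        for k in range(3):
            out[:, k] = np.interp(t, self.cum_arclength, self.vertices[:, k])
        # exact vertex parameters return the vertex bitwise, so degenerate
        # configurations (ILM through BMO) yield exactly zero areas
        j = np.clip(np.searchsorted(self.cum_arclength, t), 0, len(self.cum_arclength) - 1)
        hit = self.cum_arclength[j] == t
        if np.any(hit):
            out[hit] = self.vertices[j[hit]]
        return out

    def candidate_arclengths(self, step_mm: float | None) -> np.ndarray:
        """Candidate parameters: every polyline vertex, densified by a
        uniform arclength grid of spacing ``step_mm`` (``None`` disables
        densification)."""
        t = self.cum_arclength
        if step_mm is not None and step_mm > 0:
            grid = np.arange(0.0, self.total_arclength, step_mm)
            # drop grid points that collide with a vertex parameter to
            # rounding error; the vertex value is the canonical candidate
            tol = 1e-12 * max(1.0, self.total_arclength)
            j = np.searchsorted(t, grid)
            lo = np.abs(grid - t[np.clip(j - 1, 0, len(t) - 1)])
            hi = np.abs(t[np.clip(j, 0, len(t) - 1)] - grid)
            t = np.union1d(t, grid[np.minimum(lo, hi) > tol])
        return t

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ILMCurve":
        return ILMCurve(self.vertices @ np.asarray(rotation, float).T + translation)


def interpolate_ilm(curve: ILMCurve, t: float) -> np.ndarray:
    """Point on the ILM polyline at cumulative arclength ``t`` (mm)."""
    return curve.point_at(t)


@dataclass(frozen=True)
class Spoke:
    """One half of a radial B-scan: angle, BMO point, ILM polyline."""

    index: int
    angle_deg: float
    bmo_point: np.ndarray
    ilm_curve: ILMCurve

    def __post_init__(self):
        if not (0.0 <= self.angle_deg < 360.0):
            raise InputError(
                f"spoke {self.index}: angle {self.angle_deg} outside [0, 360)"
            )
        if not np.all(np.isfinite(self.bmo_point)):
            raise InputError(f"spoke {self.index}: non-finite BMO point")


@dataclass(frozen=True)
class StarScan:
    """A reconstructed star scan in the OD frame.

    ``eye`` records the acquired laterality (used to resolve chirality);
    the coordinates themselves are always in OD orientation. ``axis_deg``
    rotates the temporal reference axis before sector assignment
    (FoBMO-style axis alignment; default 0).
    """

    eye: str
    spokes: tuple[Spoke, ...]
    axis_deg: float = 0.0

    def __post_init__(self):
        if self.eye not in ("OD", "OS"):
            raise InputError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        object.__setattr__(self, "spokes", tuple(self.spokes))
        angles = np.array([s.angle_deg for s in self.spokes])
        if len(angles) and np.any(np.diff(angles) <= 0):
            raise InputError("spokes must be sorted by strictly increasing angle")

    @property
    def n_spokes(self) -> int:
        return len(self.spokes)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([s.angle_deg for s in self.spokes])

    @property
    def bmo_points(self) -> np.ndarray:
        return np.array([s.bmo_point for s in self.spokes])


def bmo_polygon_area(scan: StarScan) -> float:
    """Area (mm^2) of the BMO point polygon projected onto its
    least-squares best-fit plane.

    This is the package's definition of "BMO area". Requires >= 3 spokes.
    """
    pts = scan.bmo_points
    if pts.shape[0] < 3:
        raise InputError("BMO area needs at least 3 spokes")
    centred = pts - pts.mean(axis=0)
    # best-fit plane via SVD; first two right-singular vectors span it
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    uv = centred @ vt[:2].T
    x, y = uv[:, 0], uv[:, 1]
    return float(0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def rigid_transform(
    scan: StarScan, rotation: np.ndarray, translation: Sequence[float]
) -> StarScan:
    """Apply a proper rigid motion to every point of the scan.

    All areas are invariant under this operation (a tested property). The
    recorded spoke angles describe the acquisition geometry and are left
    untouched.
    """
    r = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
        raise InputError("rotation must be a 3x3 orthogonal matrix")
    if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
        raise InputError("rotation must be proper (det = +1)")
    spokes = tuple(
        replace(
            s,
            bmo_point=r @ s.bmo_point + t,
            ilm_curve=s.ilm_curve.transformed(r, t),
        )
        for s in scan.spokes
    )
    return replace(scan, spokes=spokes)


def mirror_scan(scan: StarScan) -> StarScan:
    """Mirror about the vertical en-face axis (x -> -x) and flip laterality.

    Spoke angles map theta -> (180 - theta) mod 360 and the spokes are
    re-sorted and re-indexed; this is the involution that takes an OS scan
    in device-native orientation into the OD frame and back.
    """
    mirrored = []
    for s in scan.spokes:
        bmo = s.bmo_point * np.array([-1.0, 1.0, 1.0])
        ilm = ILMCurve(s.ilm_curve.vertices * np.array([-1.0, 1.0, 1.0]))
        angle = (180.0 - s.angle_deg) % 360.0
        mirrored.append((angle, bmo, ilm))
    mirrored.sort(key=lambda rec: rec[0])
    spokes = tuple(
        Spoke(index=i, angle_deg=a, bmo_point=b, ilm_curve=c)
        for i, (a, b, c) in enumerate(mirrored)
    )
    eye = "OS" if scan.eye == "OD" else "OD"
    return StarScan(eye=eye, spokes=spokes, axis_deg=scan.axis_deg)
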