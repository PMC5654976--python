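"""ONH sector schemes and sector-wise aggregation of quad areas.

The default scheme is the Garway-Heath partition in the OD frame, with the
temporal axis at 0 degrees and angles increasing counterclockwise
(superior at 90 degrees): temporal [315, 45), temporal superior [45, 85),
nasal superior [85, 125), nasal [125, 235), nasal inferior [235, 275),
temporal inferior [275, 315). Sector labels use underscores so they can
double as CSV column names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .results import SectorSurface

__all__ = ["SectorScheme", "GARWAY_HEATH", "assign_sector", "aggregate_sectors", "quad_mid_angles"]


@dataclass(frozen=True)
class SectorScheme:
    """Named half-open angular intervals partitioning [0, 360).

    Intervals may wrap through 0 (the temporal sector does). Degrees,
    OD frame, relative to the temporal axis.
    """

    names: tuple[str, ...]
    boundaries: tuple[tuple[float, float], ...]  # half-open [lo, hi)

    def __post_init__(self):
        if len(self.names) != len(self.boundaries):
            raise InputError("scheme needs one interval per label")
        if len(set(self.names)) != len(self.names):
            raise InputError("sector labels must be unique")
        width = sum((hi - lo) % 360.0 or 360.0 for lo, hi in self.boundaries)
        if not np.isclose(width, 360.0):
            raise InputError(f"sector intervals cover {width} degrees, expected 360")


GARWAY_HEATH = SectorScheme(
    names=(
        "temporal",
        "temporal_superior",
        "nasal_superior",
        "nasal",
        "nasal_inferior",
        "temporal_inferior",
    ),
    boundaries=(
        (315.0, 45.0),
        (45.0, 85.0),
        (85.0, 125.0),
        (125.0, 235.0),
        (235.0, 275.0),
        (275.0, 315.0),
    ),
)


def assign_sector(scheme: SectorScheme, angle_deg: float) -> str:
    """Label of the unique scheme interval containing ``angle_deg``."""
    a = float(angle_deg) % 360.0
    for name, (lo, hi) in zip(scheme.names, scheme.boundaries):
        if lo <= hi:
            hit = lo <= a < hi
        else:  # wraps through 0
            hit = a >= lo or a < hi
        if hit:
            return name
    raise InputError(f"angle {angle_deg} not covered by scheme")  # pragma: no cover


def quad_mid_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Circular midpoint angle of each cyclic inter-spoke quad.

    Quad i sits between spoke i and spoke i+1 (mod n); its midpoint is the
    spoke angle plus half the (positive) angular gap to the next spoke.
    """
    a = np.asarray(angles_deg, float)
    gaps = (np.roll(a, -1) - a) % 360.0
    gaps[gaps == 0.0] = 360.0  # only possible for n == 1
    return (a + gaps / 2.0) % 360.0


def aggregate_sectors(
    scheme: SectorScheme,
    quads: list[SectorSurface] | tuple[SectorSurface, ...],
    mid_angles_deg: np.ndarray,
    axis_deg: float = 0.0,
) -> dict[str, float]:
    """Sum quad areas per sector; includes a ``"global"`` entry.

    ``axis_deg`` rotates the reference axis before assignment. The sector
    sums partition the global total exactly (same additions, grouped).
    """
    mid = np.asarray(mid_angles_deg, float)
    if len(quads) != mid.shape[0]:
        raise InputError(
            f"{len(quads)} quads but {mid.shape[0]} mid-angles"
        )
    sums = {name: 0.0 for name in scheme.names}
    total = 0.0
    for q, ang in zip(quads, mid):
        label = assign_sector(scheme, (ang - axis_deg) % 360.0)
        sums[label] += q.a_i
        total += q.a_i
    sums["global"] = total
    return sums
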