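"""Result containers shared by the sequential and global rim-area solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SectorSurface", "RimVertexSelection", "TrapezoidSolution", "RimAreaResult"]


@dataclass(frozen=True)
class SectorSurface:
    """One inter-spoke quad, split into its two triangles.

    ``a_i`` is by construction exactly ``delta_i1 + delta_i2``.
    """

    sector_index: int
    delta_i1: float
    delta_i2: float

    @property
    def a_i(self) -> float:
        return self.delta_i1 + self.delta_i2


@dataclass(frozen=True)
class TrapezoidSolution:
    """Minimizing endpoint pair of one independently optimized trapezoid."""

    sector_index: int
    t_left: float
    t_right: float
    area: float


@dataclass(frozen=True)
class RimVertexSelection:
    """One BMO–ILM connection per spoke: arclength parameters and points."""

    t: np.ndarray  # (n_spokes,) arclength in mm
    points: np.ndarray  # (n_spokes, 3)


@dataclass(frozen=True)
class RimAreaResult:
    """Minimum rim area of one eye under one optimization strategy.

    ``method`` is ``"sequential"`` (independent trapezoids, BMO-MRA) or
    ``"global"`` (continuity-constrained surface, BMO-gMRA). ``total`` is
    the sum of all quad areas; ``sector_sums`` additionally carries the
    ``"global"`` key equal to ``total``.
    """

    method: str
    quads: tuple[SectorSurface, ...]
    sector_sums: dict[str, float]
    total: float
    selection: RimVertexSelection | tuple[TrapezoidSolution, ...]
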