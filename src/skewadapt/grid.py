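"""Discrete motion-direction grid and direction signals.

The direction axis is elevation from horizontal in degrees: positive angles
are upward motion components, negative downward.  The default grid covers the
half circle [-90°, +90°] with 37 units at 5° spacing, which places the
decision readout channels (centered at ±90°) exactly on the grid endpoints.
A full-circle variant is available for users who prefer wrap-around
direction topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DirectionGrid", "DirectionSignal"]


@dataclass(frozen=True)
class DirectionGrid:
    """Uniform grid of direction-tuned units.

    Parameters
    ----------
    angles
        Direction preferences in degrees, strictly increasing.
    circular
        If True the grid covers the full circle and angular distances wrap.
    """

    angles: np.ndarray
    circular: bool = False

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.ndim != 1 or angles.size < 2:
            raise ValueError("grid needs at least two directions")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("grid angles must be strictly increasing")
        if not np.allclose(angles + angles[::-1], 0.0):
            raise ValueError("grid must be symmetric about 0°")
        if self.circular and (angles[0] <= -180.0 or angles[-1] > 180.0):
            raise ValueError("circular grid angles must lie in (-180°, 180°]")

    @classmethod
    def half_circle(cls, n: int = 37) -> "DirectionGrid":
        """Half-circle grid from -90° to +90° inclusive (default n = 37)."""
        return cls(np.linspace(-90.0, 90.0, n), circular=False)

    @classmethod
    def full_circle(cls, n: int = 37) -> "DirectionGrid":
        """Full-circle wrap-around grid, symmetric about 0° (default n = 37).

        For odd n the grid contains 0° exactly and every direction's mirror.
        """
        step = 360.0 / n
        return cls(step * (np.arange(n) - (n - 1) / 2.0), circular=True)

    @classmethod
    def default(cls) -> "DirectionGrid":
        """The package default: 37 direction units on the full circle.

        The wrap-around topology has no boundary nodes, so Gaussian direction
        kernels are exactly mass-preserving everywhere (a truncated half-range
        grid renormalizes its edge rows, which under strong feedback turns the
        endpoints into spurious attractors).
        """
        return cls.full_circle(37)

    @property
    def n(self) -> int:
        return self.angles.size

    @property
    def spacing(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def index_nearest(self, theta: float) -> int:
        """Index of the grid direction nearest to ``theta`` (degrees)."""
        if self.circular:
            d = np.abs((self.angles - theta + 180.0) % 360.0 - 180.0)
        else:
            d = np.abs(self.angles - theta)
        return int(np.argmin(d))

    def contains(self, theta: float) -> bool:
        if self.circular:
            return True
        return self.angles[0] <= theta <= self.angles[-1]

    def pairwise_distance(self) -> np.ndarray:
        """Matrix of angular distances between grid directions (degrees)."""
        d = self.angles[:, None] - self.angles[None, :]
        if self.circular:
            d = (d + 180.0) % 360.0 - 180.0
        return d


@dataclass
class DirectionSignal:
    """Non-negative activity over a :class:`DirectionGrid` (the R_θ vector)."""

    grid: DirectionGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.grid.n,):
            raise ValueError(
                f"signal length {values.shape} does not match grid size {self.grid.n}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("direction signal must be finite")
        self.values = values

    @classmethod
    def zeros(cls, grid: DirectionGrid) -> "DirectionSignal":
        return cls(grid, np.zeros(grid.n))

    def mirrored(self) -> "DirectionSignal":
        """Signal reflected about 0° (up/down mirror)."""
        if self.grid.circular:
            # map each angle to its negation on the circular grid
            idx = [self.grid.index_nearest(-a) for a in self.grid.angles]
            return DirectionSignal(self.grid, self.values[idx])
        return DirectionSignal(self.grid, self.values[::-1].copy())

    def __len__(self) -> int:
        return self.values.size
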