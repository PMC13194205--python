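"""Uniform one-dimensional grids and nonnegative density fields.

The model lives on the whole real line; numerically every field is sampled
on a symmetric, uniform node grid [-half_width, half_width] and treated as
zero outside (Dirichlet truncation, justified by the spatial decay of
solutions at infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .errors import InvalidParameterError

#: negative values smaller than this (in absolute value) are treated as
#: roundoff from solver steps and clipped to zero
NEGATIVITY_SLACK = 1e-12


@dataclass(frozen=True)
class SpatialGrid:
    """Symmetric uniform grid on [-half_width, half_width].

    ``n_nodes`` must be odd (so x = 0 is a node) and at least 65.
    """

    half_width: float
    n_nodes: int

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise InvalidParameterError("half_width must be positive")
        if self.n_nodes < 65 or self.n_nodes % 2 == 0:
            raise InvalidParameterError(
                f"n_nodes must be odd and >= 65, got {self.n_nodes}"
            )

    @property
    def spacing(self) -> float:
        return 2.0 * self.half_width / (self.n_nodes - 1)

    @cached_property
    def nodes(self) -> np.ndarray:
        x = np.linspace(-self.half_width, self.half_width, self.n_nodes)
        x.flags.writeable = False
        return x

    def indicator(self, intervals) -> np.ndarray:
        """Exact node indicator of a union of closed intervals."""
        x = self.nodes
        out = np.zeros_like(x)
        for lo, hi in intervals:
            out[(x >= lo) & (x <= hi)] = 1.0
        return out


@dataclass
class DensityField:
    """Nonnegative per-location larval density sampled on a grid."""

    grid: SpatialGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_nodes,):
            raise InvalidParameterError(
                f"values shape {v.shape} does not match grid ({self.grid.n_nodes},)"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("density values must be finite")
        if v.min(initial=0.0) < -NEGATIVITY_SLACK:
            raise InvalidParameterError(
                f"density has negative values below slack: min={v.min()}"
            )
        self.values = np.clip(v, 0.0, None)

    @property
    def sup_norm(self) -> float:
        return float(np.max(self.values))

    @property
    def mass(self) -> float:
        """Trapezoidal integral over the domain."""
        return float(np.trapezoid(self.values, dx=self.grid.spacing))

    def copy(self) -> "DensityField":
        return DensityField(self.grid, self.values.copy())


def constant_field(grid: SpatialGrid, value: float) -> DensityField:
    return DensityField(grid, np.full(grid.n_nodes, float(value)))
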