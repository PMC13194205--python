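"""Between-season generation map and its iteration.

One generation maps the start-of-season larval density u through three
stages: the within-season survival semiflow (season solver), the local
birth function g(x, .), and non-local redistribution of offspring by
convolution with the adult dispersal kernel:

    Q[u] = K * g(., Phi_tau[u]).

Iterating Q produces the between-season population dynamics; its fixed
points are the candidate steady states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DivergenceError, DomainError, InvalidParameterError, ResolutionError
from .grid import DensityField, SpatialGrid
from .habitat import BirthSpec, KernelSpec, ModelSpec
from .season import _Conv, _SeasonStepper, _convolve


@dataclass(frozen=True)
class DiscreteKernel:
    """Dispersal kernel sampled on grid-aligned offsets.

    ``weights`` are density values per offset node, renormalized so the
    discrete integral sum(weights)*spacing equals 1 exactly.
    """

    offsets: np.ndarray
    weights: np.ndarray
    k_min: int
    spacing: float
    window_halfwidth: float
    raw_quadrature: float  # pre-normalization discrete integral

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Discrete convolution (K * v) with zero padding off the domain."""
        return _convolve(values, self.weights * self.spacing, self.k_min)

    @property
    def discrete_integral(self) -> float:
        return float(self.weights.sum() * self.spacing)

    @property
    def discrete_mean(self) -> float:
        return float(np.sum(self.offsets * self.weights) * self.spacing)


def discretize_kernel(kernel: KernelSpec, grid: SpatialGrid,
                      n_sd: float = 8.0) -> DiscreteKernel:
    """Sample the kernel density on grid offsets and renormalize.

    The window spans mean +/- n_sd*sd (so it always covers mean + 8*sd by
    default).  The grid must resolve the kernel: spacing < sd/2.
    """
    h = grid.spacing
    if not h < kernel.sd / 2.0:
        raise ResolutionError(
            f"grid spacing {h:.4g} too coarse for kernel sd {kernel.sd:.4g}"
        )
    k_min = int(np.floor((kernel.mean - n_sd * kernel.sd) / h))
    k_max = int(np.ceil((kernel.mean + n_sd * kernel.sd) / h))
    offsets = np.arange(k_min, k_max + 1) * h
    w = kernel.density(offsets)
    raw = float(w.sum() * h)
    w = w / raw
    return DiscreteKernel(
        offsets=offsets, weights=w, k_min=k_min, spacing=h,
        window_halfwidth=float(max(abs(offsets[0]), abs(offsets[-1]))),
        raw_quadrature=raw,
    )


def apply_birth(birth: BirthSpec, u: DensityField) -> DensityField:
    """Nodewise birth output g(x, u(x))."""
    vals = u.values
    if birth.family == "logistic_nonmonotone" and np.max(vals) > 1.0 + 1e-9:
        raise DomainError(
            "logistic_nonmonotone birth requires u <= 1 "
            f"(max {np.max(vals):.6g})"
        )
    out = birth.evaluate(u.grid.nodes, vals)
    return DensityField(u.grid, np.clip(out, 0.0, None))


class GenerationOperator:
    """Precomputed generation map Q for a fixed model, grid and dt."""

    def __init__(self, model: ModelSpec, grid: SpatialGrid,
                 dt: Optional[float] = None, boundary: str = "dirichlet"):
        self.model = model
        self.grid = grid
        self.dt = model.tau / 64.0 if dt is None else dt
        self.boundary = boundary
        self.stepper = _SeasonStepper(model, grid, self.dt, boundary)
        self.kernel = discretize_kernel(model.kernel, grid)
        self._kernel_conv = _Conv(self.kernel.weights * self.kernel.spacing,
                                  self.kernel.k_min, grid.n_nodes, boundary)
        self._x = grid.nodes

    def apply_values(self, values: np.ndarray) -> np.ndarray:
        v = self.stepper.run(values.copy())
        if (self.model.birth.family == "logistic_nonmonotone"
                and np.max(v) > 1.0 + 1e-9):
            raise DomainError("season output left [0,1] under non-monotone birth")
        b = np.clip(self.model.birth.evaluate(self._x, v), 0.0, None)
        return np.clip(self._kernel_conv(b), 0.0, None)

    def __call__(self, u: DensityField) -> DensityField:
        return DensityField(self.grid, self.apply_values(u.values))


def generation_step(model: ModelSpec, u: DensityField,
                    dt: Optional[float] = None,
                    boundary: str = "dirichlet") -> DensityField:
    """One application of the generation map Q."""
    return GenerationOperator(model, u.grid, dt, boundary)(u)


@dataclass
class GenerationTrajectory:
    """Iterates of the generation map with dense diagnostics.

    ``sup_norms``/``masses`` are recorded every generation (index n = 0 is
    the initial condition); full fields only every ``record_every``
    generations plus the final one.
    """

    model: ModelSpec
    grid: SpatialGrid
    start_fields: dict = field(repr=False)  # n -> DensityField
    sup_norms: np.ndarray = field(repr=False)
    masses: np.ndarray = field(repr=False)
    n_total: int = 0

    @property
    def final(self) -> DensityField:
        return self.start_fields[max(self.start_fields)]

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(self.n_total + 1),
                "sup_norm": self.sup_norms,
                "mass": self.masses,
            }
        )


def iterate_generations(model: ModelSpec, u0: DensityField, n_gens: int,
                        dt: Optional[float] = None,
                        record_every: int = 10,
                        boundary: str = "dirichlet") -> GenerationTrajectory:
    """Iterate the generation map n_gens times (deterministic)."""
    if n_gens < 1:
        raise InvalidParameterError("n_gens must be >= 1")
    op = GenerationOperator(model, u0.grid, dt, boundary)
    sup = np.empty(n_gens + 1)
    mass = np.empty(n_gens + 1)
    fields = {0: u0.copy()}
    v = u0.values.copy()
    sup[0] = float(np.max(v))
    mass[0] = float(np.trapezoid(v, dx=u0.grid.spacing))
    for n in range(1, n_gens + 1):
        v = op.apply_values(v)
        sup[n] = float(np.max(v))
        mass[n] = float(np.trapezoid(v, dx=u0.grid.spacing))
        if sup[n] > 1e6:
            raise DivergenceError(f"sup-norm exceeded 1e6 at generation {n}")
        if n % record_every == 0 or n == n_gens:
            fields[n] = DensityField(u0.grid, v.copy())
    return GenerationTrajectory(model, u0.grid, fields, sup, mass, n_gens)


@dataclass
class FixedPointReport:
    W: DensityField
    residual: float
    converged: bool
    n_iterations: int


def find_fixed_point(model: ModelSpec, u0: DensityField,
                     dt: Optional[float] = None, tol: float = 1e-8,
                     max_gens: int = 2000,
                     boundary: str = "dirichlet") -> FixedPointReport:
    """Iterate Q to a fixed point in sup-norm.

    Stops when successive iterates differ by less than ``tol`` in sup-norm
    or after ``max_gens`` generations; non-convergence is reported, not
    raised.  The zero state is always a fixed point, so in extinction
    regimes this converges to (numerically) zero.
    """
    if not tol > 0:
        raise InvalidParameterError("tol must be positive")
    op = GenerationOperator(model, u0.grid, dt, boundary)
    v = u0.values.copy()
    converged = False
    n = 0
    for n in range(1, max_gens + 1):
        w = op.apply_values(v)
        diff = float(np.max(np.abs(w - v)))
        v = w
        if diff < tol:
            converged = True
            break
    residual = float(np.max(np.abs(op.apply_values(v) - v)))
    return FixedPointReport(DensityField(u0.grid, v), residual, converged, n)
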