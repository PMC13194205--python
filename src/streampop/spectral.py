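"""Persistence threshold via the asymptotic spectral radius.

Linearizing the generation map at the extinction state gives the positive
linear operator

    L[phi] = K * ( eta(.) * P_tau[phi] ),

where P_tau propagates phi through the within-season linear equation with
coefficient theta(x) = d_u f(x,0), and eta(x) = d_u g(x,0) weights the
low-density fecundity before dispersal.  Restricting L to balls of radius
rho with a tent-shaped cutoff and letting rho grow yields a nondecreasing
sequence of spectral radii whose limit rho_L is the persistence threshold:
rho_L > 1 implies a unique globally attractive positive steady state,
rho_L < 1 implies extinction.

Numerically, rho_L is estimated by sweeping increasing truncation radii on
a fixed grid until the spectral radii plateau.  The operator can be
assembled as a dense matrix (structured product of convolution matrices
and diagonal factors) or applied matrix-free for power iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg as sla

from .errors import InvalidParameterError, MemoryGuardError
from .grid import SpatialGrid
from .habitat import KernelSpec, ModelSpec
from .generation import DiscreteKernel, discretize_kernel
from .season import _convolve, _n_steps, _sampled_gaussian

_DENSE_MAX_NODES = 8192
_DENSE_EIG_MAX_NODES = 1025


def zeta_cutoff(rho: float, x) -> np.ndarray:
    """Tent cutoff: 1 on |x| <= rho-1, 0 on |x| >= rho, linear between."""
    if not rho > 0:
        raise InvalidParameterError("rho must be positive")
    return np.clip(rho - np.abs(np.asarray(x, dtype=float)), 0.0, 1.0)


@dataclass(frozen=True)
class LinearizedModel:
    """The pair (eta, theta) plus transport parameters defining L."""

    eta: Callable
    theta: Callable
    D: float
    q: float
    tau: float
    kernel: KernelSpec

    @classmethod
    def from_model(cls, model: ModelSpec) -> "LinearizedModel":
        reaction, birth = model.reaction, model.birth
        return cls(
            eta=lambda x: birth.eta_values(np.asarray(x, dtype=float)),
            theta=lambda x: reaction.theta_values(np.asarray(x, dtype=float)),
            D=model.D, q=model.q, tau=model.tau, kernel=model.kernel,
        )

    def eta_values(self, x: np.ndarray) -> np.ndarray:
        v = np.asarray(self.eta(np.asarray(x, dtype=float)), dtype=float)
        return np.broadcast_to(v, np.shape(x)).astype(float)

    def theta_values(self, x: np.ndarray) -> np.ndarray:
        v = np.asarray(self.theta(np.asarray(x, dtype=float)), dtype=float)
        return np.broadcast_to(v, np.shape(x)).astype(float)


@dataclass
class OperatorMatrix:
    """Dense discretization of the linearized generation operator."""

    grid: SpatialGrid
    entries: np.ndarray = field(repr=False)
    assembly_metadata: dict = field(default_factory=dict)
    nodes: Optional[np.ndarray] = None  # positions of the rows/cols

    def __post_init__(self) -> None:
        if self.nodes is None:
            self.nodes = self.grid.nodes


class _LinearApplier:
    """Matrix-free application of L (and of its truncations)."""

    def __init__(self, lin: LinearizedModel, grid: SpatialGrid, dt: float):
        self.lin = lin
        self.grid = grid
        self.dt = dt
        self.n_sub = _n_steps(lin.tau, dt)
        self.k_min, self.w = _sampled_gaussian(
            lin.q * dt, np.sqrt(2.0 * lin.D * dt), grid.spacing
        )
        x = grid.nodes
        self.e_half = np.exp(lin.theta_values(x) * 0.5 * dt)
        self.eta = lin.eta_values(x)
        self.kernel: DiscreteKernel = discretize_kernel(lin.kernel, grid)

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = values
        for _ in range(self.n_sub):
            v = self.e_half * _convolve(self.e_half * v, self.w, self.k_min)
        return self.kernel.apply(self.eta * v)


def apply_linearized(lin: LinearizedModel, grid: SpatialGrid, dt: float,
                     values: np.ndarray) -> np.ndarray:
    """Composed application of L to nodal values (season propagation,
    eta-weighting, kernel convolution); the oracle the assembled matrix
    must agree with."""
    return _LinearApplier(lin, grid, dt).apply(np.asarray(values, dtype=float))


def _toeplitz_from_weights(n: int, w: np.ndarray, k_min: int) -> np.ndarray:
    """Dense matrix of the discrete convolution v -> w * v (zero padded)."""
    idx = np.arange(n)
    col = np.zeros(n)
    ci = idx - k_min
    m = (ci >= 0) & (ci < w.size)
    col[m] = w[ci[m]]
    row = np.zeros(n)
    ri = -idx - k_min
    m = (ri >= 0) & (ri < w.size)
    row[m] = w[ri[m]]
    return sla.toeplitz(col, row)


def assemble_operator(lin: LinearizedModel, grid: SpatialGrid,
                      dt: float) -> OperatorMatrix:
    """Assemble the dense operator C_K . diag(eta) . P.

    P is the product of the Strang splitting factors of the linear season
    propagator (diagonal exponentials and a transport convolution matrix),
    computed by binary exponentiation of the single-substep matrix; C_K is
    the discretized-kernel convolution matrix.
    """
    n = grid.n_nodes
    if n > _DENSE_MAX_NODES:
        raise MemoryGuardError(
            f"n_nodes={n} > {_DENSE_MAX_NODES}; use matrix-free power iteration"
        )
    ap = _LinearApplier(lin, grid, dt)
    T = _toeplitz_from_weights(n, ap.w, ap.k_min)
    m1 = (ap.e_half[:, None] * T) * ap.e_half[None, :]
    P = np.linalg.matrix_power(m1, ap.n_sub)
    CK = _toeplitz_from_weights(
        n, ap.kernel.weights * ap.kernel.spacing, ap.kernel.k_min
    )
    entries = CK @ (ap.eta[:, None] * P)
    return OperatorMatrix(
        grid, entries,
        assembly_metadata={
            "dt": dt, "n_substeps": ap.n_sub,
            "factorization": "kernel-convolution x diag(eta) x propagator",
        },
    )


def truncated_operator(M: OperatorMatrix, rho: float) -> OperatorMatrix:
    """Tent-truncate to the ball of radius rho: right-multiply by
    diag(zeta_rho) and restrict rows/columns to nodes with |x| <= rho."""
    if rho > M.grid.half_width + 1e-12:
        raise InvalidParameterError("truncation radius exceeds the domain")
    x = M.nodes
    zeta = zeta_cutoff(rho, x)
    keep = np.abs(x) <= rho + 1e-12
    entries = (M.entries * zeta[None, :])[np.ix_(keep, keep)]
    meta = dict(M.assembly_metadata, truncation_radius=rho)
    return OperatorMatrix(M.grid, entries, meta, nodes=x[keep])


def _power_radius(matvec: Callable, n: int, tol: float, max_iter: int,
                  stable_iters: int = 5):
    """Power iteration for the Perron root of a positive operator.

    Convergence requires the eigenvalue estimate to be stable over several
    consecutive iterations (a single small step can occur mid-transient
    for slowly converging operators)."""
    v = np.ones(n)
    lam = 0.0
    stable = 0
    for _ in range(max_iter):
        w = matvec(v)
        lam_new = float(np.max(np.abs(w)))
        if lam_new == 0.0:
            return 0.0, True
        v = w / lam_new
        if abs(lam_new - lam) <= tol * max(1.0, lam_new):
            stable += 1
            if stable >= stable_iters:
                return lam_new, True
        else:
            stable = 0
        lam = lam_new
    return lam, False


def spectral_radius(M, method: str = "dense_eig", tol: float = 1e-10,
                    max_iter: int = 10000) -> float:
    """Largest eigenvalue modulus of a dense operator matrix."""
    A = M.entries if isinstance(M, OperatorMatrix) else np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidParameterError("operator matrix must be square")
    if method == "dense_eig":
        return float(np.max(np.abs(np.linalg.eigvals(A))))
    if method == "power":
        lam, ok = _power_radius(lambda v: A @ v, A.shape[0], tol, max_iter)
        if not ok:
            warnings.warn("power iteration did not converge; falling back to "
                          "dense eigensolver", stacklevel=2)
            return float(np.max(np.abs(np.linalg.eigvals(A))))
        return lam
    raise InvalidParameterError(f"unknown method {method!r}")


@dataclass
class SpectralSweep:
    """Spectral radii of truncations at increasing radii."""

    radii: np.ndarray
    rho_values: np.ndarray
    rho_L_estimate: float
    plateaued: bool
    rel_change_tail: float
    settings: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"radius": self.radii, "rho": self.rho_values})

    def summary(self) -> dict:
        return {
            "rho_L_estimate": self.rho_L_estimate,
            "plateaued": self.plateaued,
            "rel_change_tail": self.rel_change_tail,
            "settings": self.settings,
        }


def periodic_spectral_radius(lin: LinearizedModel, grid: SpatialGrid,
                             dt: Optional[float] = None,
                             method: str = "auto",
                             power_tol: float = 1e-10,
                             max_iter: int = 20000) -> float:
    """Spectral radius of the linearized operator on the periodic domain.

    For a habitat whose coefficients are periodic with period dividing the
    domain width, the infinite-line linearized operator preserves the space
    of periodic functions and its growth rate there is the spectral radius
    of the circular (wrap-around) discretization.  This is the natural
    persistence threshold for periodic habitats, where the BB-type decay
    assumption behind the Dirichlet-truncated asymptotic spectral radius
    does not hold.
    """
    from .season import _Conv

    if dt is None:
        dt = auto_substep(lin, grid)
    ap = _LinearApplier(lin, grid, dt)
    conv_t = _Conv(ap.w, ap.k_min, grid.n_nodes, "periodic")
    conv_k = _Conv(ap.kernel.weights * ap.kernel.spacing, ap.kernel.k_min,
                   grid.n_nodes, "periodic")
    if method == "auto":
        method = "dense" if grid.n_nodes <= 2049 else "power"
    if method == "dense":
        m = grid.n_nodes - 1
        eye = np.eye(m)
        # circulant transport matrix from the wrapped kernel row
        kk = conv_t(np.r_[eye[0], eye[0][:1]])[:m]
        T = sla.circulant(kk)
        kkK = conv_k(np.r_[eye[0], eye[0][:1]])[:m]
        CK = sla.circulant(kkK)
        e = ap.e_half[:m]
        P = np.linalg.matrix_power((e[:, None] * T) * e[None, :], ap.n_sub)
        A = CK @ (ap.eta[:m][:, None] * P)
        return float(np.max(np.abs(np.linalg.eigvals(A))))

    def matvec(v):
        w = np.r_[v, v[:1]]
        for _ in range(ap.n_sub):
            w = ap.e_half * conv_t(ap.e_half * w)
        w = conv_k(ap.eta * w)
        return w[:-1]

    lam, ok = _power_radius(matvec, grid.n_nodes - 1, power_tol, max_iter)
    if not ok:
        warnings.warn("periodic power iteration did not fully converge; "
                      "estimate may be a lower bound", stacklevel=2)
    return lam


def default_radii(grid: SpatialGrid, n_radii: int = 8) -> np.ndarray:
    hi = 0.9 * grid.half_width
    lo = min(10.0, 0.45 * grid.half_width)
    return np.geomspace(lo, hi, n_radii)


def auto_substep(lin: LinearizedModel, grid: SpatialGrid,
                 max_substeps: int = 64) -> float:
    """Largest power-of-two substep count whose transport kernel is still
    resolved on this grid (sd >= 0.8 * spacing), capped at max_substeps."""
    K = max_substeps
    while K > 1 and np.sqrt(2.0 * lin.D * lin.tau / K) < 0.8 * grid.spacing:
        K //= 2
    return lin.tau / K


def estimate_rho_L(lin: LinearizedModel, grid: SpatialGrid,
                   dt: Optional[float] = None,
                   radii: Optional[Sequence[float]] = None,
                   plateau_tol: float = 1e-3,
                   method: str = "auto",
                   power_tol: float = 1e-10,
                   max_iter: int = 10000) -> SpectralSweep:
    """Estimate the asymptotic spectral radius rho_L by a radius sweep.

    The sweep is declared plateaued when the relative change of the
    spectral radius across the last three radii falls below
    ``plateau_tol``; the estimate is the value at the largest radius.
    """
    if dt is None:
        dt = auto_substep(lin, grid)
    if radii is None:
        radii = default_radii(grid)
    radii = np.asarray(radii, dtype=float)
    if radii.size < 3:
        raise InvalidParameterError("need at least 3 truncation radii")
    if np.any(np.diff(radii) <= 0):
        raise InvalidParameterError("radii must be strictly increasing")
    if radii[-1] > grid.half_width + 1e-12:
        raise InvalidParameterError("largest radius exceeds the domain")

    if method == "auto":
        method = "dense" if grid.n_nodes <= _DENSE_EIG_MAX_NODES else "power"

    values = np.empty(radii.size)
    if method == "dense":
        M = assemble_operator(lin, grid, dt)
        for i, rho in enumerate(radii):
            values[i] = spectral_radius(truncated_operator(M, rho))
    elif method == "power":
        ap = _LinearApplier(lin, grid, dt)
        x = grid.nodes
        for i, rho in enumerate(radii):
            keep = np.abs(x) <= rho + 1e-12
            zeta = zeta_cutoff(rho, x)[keep]
            idx = np.flatnonzero(keep)

            def matvec(v, idx=idx, zeta=zeta):
                full = np.zeros(grid.n_nodes)
                full[idx] = zeta * v
                return ap.apply(full)[idx]

            lam, ok = _power_radius(matvec, idx.size, power_tol, max_iter)
            if not ok:
                warnings.warn(
                    f"power iteration not fully converged at radius {rho:.3g}; "
                    "using last estimate", stacklevel=2)
            values[i] = lam
    else:
        raise InvalidParameterError(f"unknown method {method!r}")

    tail = values[-3:]
    scale = max(abs(values[-1]), 1e-300)
    rel = float(np.max(np.abs(np.diff(tail)))) / scale if scale > 0 else 0.0
    plateaued = bool(rel < plateau_tol) or bool(np.all(values == 0.0))
    if not plateaued:
        warnings.warn(
            f"spectral sweep did not plateau (tail relative change {rel:.3g})",
            stacklevel=2)
    return SpectralSweep(
        radii=radii, rho_values=values, rho_L_estimate=float(values[-1]),
        plateaued=plateaued, rel_change_tail=rel,
        settings={"dt": dt, "method": method, "plateau_tol": plateau_tol,
                  "n_nodes": grid.n_nodes, "half_width": grid.half_width},
    )
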