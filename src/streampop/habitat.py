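"""Model instances: habitat profiles, mortality/birth families, kernels.

The within-season mortality f(x,u) and between-season birth g(x,u) encode
spatial heterogeneity through piecewise-linear habitat profiles: a central
favorable "plateau" surrounded by unfavorable habitat (a BB-type
configuration), or a periodically repeating pattern of favorable patches.

Standing structural assumptions on f and g (used throughout the theory the
model rests on):

* f(x,0) = 0, f(x,u)/u nonincreasing in u, f(x,u) <= K*u for large u;
* g(x,0) = 0, g >= 0, g(x,u)/u nonincreasing in u, g(x,u) <= L*max(u, Nbar);
* a BB-type tail condition: limsup eta * exp(limsup theta * tau) < 1, where
  theta = d_u f(.,0) and eta = d_u g(.,0) are the linearizations at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import InvalidParameterError, UnsupportedProfileError

logger = logging.getLogger("streampop")

_warned_once: set = set()


def warn_once(key: str, message: str) -> None:
    """Log a modelling-gap decision at warning level, once per run."""
    if key not in _warned_once:
        _warned_once.add(key)
        logger.warning(message)


def reset_warnings() -> None:
    _warned_once.clear()


# ---------------------------------------------------------------------------
# habitat profiles


@dataclass(frozen=True)
class HabitatProfile:
    """Continuous spatial profile x -> value.

    ``kind`` is one of plateau_reproduction, plateau_mortality,
    periodic_reproduction, periodic_mortality, constant, custom.
    ``scale`` is the half-plateau length (the m or l of the piecewise
    definitions); periodic kinds have period 5*scale.
    """

    kind: str
    scale: float
    levels: tuple
    evaluator: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __call__(self, x) -> np.ndarray:
        return self.evaluator(np.asarray(x, dtype=float))

    @property
    def period(self) -> Optional[float]:
        if self.kind.startswith("periodic"):
            return 5.0 * self.scale
        return None

    def limsup_at_infinity(self) -> float:
        """limsup of the profile as |x| -> infinity."""
        return self._tail(np.max)

    def liminf_at_infinity(self) -> float:
        return self._tail(np.min)

    def _tail(self, reducer) -> float:
        if self.kind == "constant":
            return float(self.levels[0])
        if self.kind.startswith("plateau"):
            # constant outside [-2*scale, 2*scale]
            return float(self(np.array([2.5 * self.scale]))[0])
        if self.kind.startswith("periodic"):
            # for a periodic profile the limsup/liminf is the extremum
            # over one period
            xs = np.linspace(0.0, 5.0 * self.scale, 4001)
            return float(reducer(self(xs)))
        raise UnsupportedProfileError(
            f"profile kind {self.kind!r} has no computable tail behaviour"
        )


def constant_profile(value: float) -> HabitatProfile:
    v = float(value)
    return HabitatProfile(
        kind="constant", scale=1.0, levels=(v, v),
        evaluator=lambda x: np.full_like(np.asarray(x, dtype=float), v),
    )


def plateau_profile(role: str, scale: float) -> HabitatProfile:
    """Piecewise-linear plateau profile.

    reproduction: 1 outside [-2*scale, 2*scale], ramping linearly to a
    plateau of 2 on [-scale, scale] (favorable breeding core).
    mortality: 1 outside, ramping to 0 on [-scale, scale] (no
    location-dependent mortality in the favorable core).
    """
    if not scale > 0:
        raise InvalidParameterError("plateau scale must be positive")
    if role == "reproduction":
        fp, levels = (1.0, 2.0, 2.0, 1.0), (1.0, 2.0)
    elif role == "mortality":
        fp, levels = (1.0, 0.0, 0.0, 1.0), (0.0, 1.0)
    else:
        raise InvalidParameterError(f"unknown profile role {role!r}")
    s = float(scale)
    xp = np.array([-2 * s, -s, s, 2 * s])
    fp = np.asarray(fp)

    def ev(x, xp=xp, fp=fp):
        return np.interp(x, xp, fp)

    return HabitatProfile(f"plateau_{role}", s, levels, ev)


def periodic_profile(role: str, scale: float) -> HabitatProfile:
    """Continuous 5*scale-periodic analogue of the plateau profile.

    On each period the profile holds its favorable level on a patch of
    width 2*scale, ramps to the unfavorable level, holds it for one scale,
    and ramps back.  The printed ascending branches of the source piecewise
    definitions are discontinuous; the ramps used here are the unique
    affine branches making the profile continuous and periodic.
    """
    if not scale > 0:
        raise InvalidParameterError("periodic scale must be positive")
    if role == "reproduction":
        fp, levels = (2.0, 2.0, 1.0, 1.0, 2.0), (1.0, 2.0)
    elif role == "mortality":
        fp, levels = (0.0, 0.0, 1.0, 1.0, 0.0), (0.0, 1.0)
    else:
        raise InvalidParameterError(f"unknown profile role {role!r}")
    warn_once(
        "periodic-branch-correction",
        "periodic profile ascending branch uses the continuity-consistent "
        "affine ramp (the printed source branch is discontinuous)",
    )
    s = float(scale)
    xp = np.array([-s, s, 2 * s, 3 * s, 4 * s])
    fp = np.asarray(fp)

    def ev(x, xp=xp, fp=fp, s=s):
        # map to the fundamental period [-s, 4s)
        t = np.mod(np.asarray(x, dtype=float) + s, 5 * s) - s
        return np.interp(t, xp, fp)

    return HabitatProfile(f"periodic_{role}", s, levels, ev)


# ---------------------------------------------------------------------------
# reaction, birth, kernel, model specs


@dataclass(frozen=True)
class ReactionSpec:
    """Within-season mortality f(x,u).

    Families:

    * ``logistic_mortality``: f(x,u) = -alpha(x)*u - u**2 (the standard
      density-dependent larval mortality, alpha from ``alpha_profile``);
    * ``linear``: f(x,u) = theta(x)*u;
    * ``custom``: arbitrary callable ``f(x, u)`` with linearization theta.

    ``theta`` is the linearization d_u f(x, 0); ``bound_K`` and
    ``bound_Ntilde`` are the growth-bound constants (f(x,u) <= K*u for
    u >= Ntilde).
    """

    family: str
    alpha_profile: Optional[HabitatProfile] = None
    theta: Optional[Callable] = None
    f: Optional[Callable] = None
    bound_K: float = 0.0
    bound_Ntilde: float = 1.0

    def theta_values(self, x: np.ndarray) -> np.ndarray:
        if self.family == "logistic_mortality":
            return -self.alpha_profile(x)
        if self.theta is None:
            raise InvalidParameterError(f"reaction family {self.family!r} needs theta")
        return np.broadcast_to(
            np.asarray(self.theta(np.asarray(x, dtype=float)), dtype=float), np.shape(x)
        ).astype(float)

    def theta_limsup(self) -> float:
        """limsup of theta at spatial infinity."""
        if self.family == "logistic_mortality":
            return -self.alpha_profile.liminf_at_infinity()
        if isinstance(self.theta, HabitatProfile):
            return self.theta.limsup_at_infinity()
        if self.family == "linear" and self.theta is not None:
            v = np.asarray(self.theta(np.array([0.0, 1e6, -1e6])), dtype=float)
            v = np.broadcast_to(v, (3,))
            if np.ptp(v[1:]) < 1e-12:
                return float(v[1])
        raise UnsupportedProfileError("reaction has no computable tail behaviour")

    def evaluate(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        if self.family == "logistic_mortality":
            return -self.alpha_profile(x) * u - u**2
        if self.family == "linear":
            return self.theta_values(x) * u
        if self.family == "custom":
            return self.f(x, u)
        raise InvalidParameterError(f"unknown reaction family {self.family!r}")

    def validate(self, x_samples=None, u_lattice=None, tol=1e-10) -> None:
        """Check f(x,0)=0 and f(x,u)/u nonincreasing in u on a lattice."""
        x = np.asarray(x_samples if x_samples is not None else np.linspace(-60, 60, 41))
        u = np.asarray(u_lattice if u_lattice is not None else np.arange(0.1, 10.05, 0.1))
        if np.max(np.abs(self.evaluate(x, np.zeros_like(x)))) > tol:
            raise InvalidParameterError("f(x,0) must vanish")
        ratios = self.evaluate(x[:, None], u[None, :]) / u[None, :]
        if np.max(np.diff(ratios, axis=1)) > tol:
            raise InvalidParameterError("f(x,u)/u must be nonincreasing in u")


def logistic_mortality(alpha_profile: HabitatProfile, bound_K: float = 0.0,
                       bound_Ntilde: float = 1.0) -> ReactionSpec:
    return ReactionSpec("logistic_mortality", alpha_profile=alpha_profile,
                        bound_K=bound_K, bound_Ntilde=bound_Ntilde)


def linear_reaction(theta0: float) -> ReactionSpec:
    t0 = float(theta0)
    return ReactionSpec("linear", theta=lambda x: np.full_like(np.asarray(x, float), t0),
                        bound_K=t0, bound_Ntilde=1.0)


@dataclass(frozen=True)
class BirthSpec:
    """Between-season birth g(x,u).

    Families:

    * ``beverton_holt``: g(x,u) = r(x)*u/(1+u), monotone saturating births;
    * ``logistic_nonmonotone``: g(x,u) = r(x)*u*(1-u) on u in [0,1];
    * ``linear``: g(x,u) = eta(x)*u;
    * ``custom``: callable ``g(x, u)`` with linearization eta.

    ``eta`` is d_u g(x, 0); for the profile families eta(x) = r(x).
    ``bound_L``/``bound_Nbar`` are the constants of g(x,u) <= L*max(u, Nbar).
    """

    family: str
    r_profile: Optional[HabitatProfile] = None
    eta: Optional[Callable] = None
    g: Optional[Callable] = None
    bound_L: float = 2.0
    bound_Nbar: float = 1.0
    monotone_flag: bool = True

    def eta_values(self, x: np.ndarray) -> np.ndarray:
        if self.r_profile is not None:
            return self.r_profile(x)
        if self.eta is None:
            raise InvalidParameterError(f"birth family {self.family!r} needs eta")
        return np.broadcast_to(
            np.asarray(self.eta(np.asarray(x, dtype=float)), dtype=float), np.shape(x)
        ).astype(float)

    def eta_limsup(self) -> float:
        if self.r_profile is not None:
            return self.r_profile.limsup_at_infinity()
        if self.family == "linear" and self.eta is not None:
            v = np.broadcast_to(np.asarray(self.eta(np.array([0.0, 1e6, -1e6])), float), (3,))
            if np.ptp(v[1:]) < 1e-12:
                return float(v[1])
        raise UnsupportedProfileError("birth has no computable tail behaviour")

    def evaluate(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        if self.family == "beverton_holt":
            return self.r_profile(x) * u / (1.0 + u)
        if self.family == "logistic_nonmonotone":
            return self.r_profile(x) * u * (1.0 - u)
        if self.family == "linear":
            return self.eta_values(x) * u
        if self.family == "custom":
            return self.g(x, u)
        raise InvalidParameterError(f"unknown birth family {self.family!r}")

    def validate(self, x_samples=None, u_lattice=None, tol=1e-10) -> None:
        x = np.asarray(x_samples if x_samples is not None else np.linspace(-60, 60, 41))
        if self.family == "logistic_nonmonotone":
            u = np.arange(0.05, 1.0, 0.05)
            if self.monotone_flag:
                raise InvalidParameterError(
                    "logistic_nonmonotone birth must have monotone_flag=False")
        else:
            u = np.asarray(u_lattice if u_lattice is not None
                           else np.arange(0.1, 10.05, 0.1))
        vals = self.evaluate(x[:, None], u[None, :])
        if np.min(vals) < -tol:
            raise InvalidParameterError("g must be nonnegative on its range")
        if np.max(np.abs(self.evaluate(x, np.zeros_like(x)))) > tol:
            raise InvalidParameterError("g(x,0) must vanish")
        ratios = vals / u[None, :]
        if np.max(np.diff(ratios, axis=1)) > tol:
            raise InvalidParameterError("g(x,u)/u must be nonincreasing in u")


def beverton_holt(r_profile: HabitatProfile, bound_L: float = 2.0,
                  bound_Nbar: float = 1.0) -> BirthSpec:
    return BirthSpec("beverton_holt", r_profile=r_profile, bound_L=bound_L,
                     bound_Nbar=bound_Nbar, monotone_flag=True)


def logistic_nonmonotone(r_profile: HabitatProfile) -> BirthSpec:
    return BirthSpec("logistic_nonmonotone", r_profile=r_profile,
                     bound_L=2.0, bound_Nbar=1.0, monotone_flag=False)


def linear_birth(eta0: float) -> BirthSpec:
    e0 = float(eta0)
    return BirthSpec("linear", eta=lambda x: np.full_like(np.asarray(x, float), e0),
                     bound_L=max(e0, 1e-12), bound_Nbar=1.0)


@dataclass(frozen=True)
class KernelSpec:
    """Adult dispersal kernel (a probability density of displacements)."""

    family: str = "gaussian"
    mean: float = 0.0
    sd: float = 2.0

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise InvalidParameterError(f"unsupported kernel family {self.family!r}")
        if not self.sd > 0:
            raise InvalidParameterError("kernel sd must be positive")

    def density(self, offset) -> np.ndarray:
        z = (np.asarray(offset, dtype=float) - self.mean) / self.sd
        return np.exp(-0.5 * z * z) / (self.sd * np.sqrt(2.0 * np.pi))

    def validate(self) -> None:
        if self.density(0.0) <= 1e-300:
            warnings.warn(
                "kernel density vanishes at zero displacement; strong "
                "positivity of the generation map is not guaranteed",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one model instance.

    D: larval diffusivity (area/time); q: larval drift speed (length/time,
    e.g. stream flow); tau: season length (time); reaction/birth/kernel as
    above.
    """

    D: float
    q: float
    tau: float
    reaction: ReactionSpec
    birth: BirthSpec
    kernel: KernelSpec

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise InvalidParameterError("D must be positive")
        if not self.tau > 0:
            raise InvalidParameterError("tau must be positive")

    def validate(self) -> None:
        self.reaction.validate()
        self.birth.validate()
        self.kernel.validate()


# ---------------------------------------------------------------------------
# standing-assumption checks


def check_assumption_A(model: ModelSpec) -> dict:
    """BB-type tail condition: limsup eta * exp(limsup theta * tau) < 1.

    Returns ``{"lhs": value, "holds": flag, "eta_limsup":..., "theta_limsup":...}``.
    """
    eta_inf = model.birth.eta_limsup()
    theta_inf = model.reaction.theta_limsup()
    lhs = eta_inf * float(np.exp(theta_inf * model.tau))
    return {
        "lhs": lhs,
        "holds": bool(lhs < 1.0),
        "eta_limsup": eta_inf,
        "theta_limsup": theta_inf,
    }


def invariance_bound(K: float, M: float, Ntilde: float) -> float:
    """Invariant-region constant A_{K,M}: M/K if K > 0, else M*(Ntilde+1)/(K+M)."""
    if K > 0:
        return M / K
    if K + M <= 0:
        raise InvalidParameterError("for K <= 0 the bound requires K + M > 0")
    return M * (Ntilde + 1.0) / (K + M)


def check_LK_condition(model: ModelSpec) -> dict:
    """Check the positive-invariance condition L*exp(K*tau) <= 1.

    Emits a warning (not an error) when it fails: the standard scenario
    constants (K=0, L=2) violate it while the simulations remain
    well-behaved.
    """
    K = model.reaction.bound_K
    L = model.birth.bound_L
    value = L * float(np.exp(K * model.tau))
    holds = bool(value <= 1.0 + 1e-12)
    if not holds:
        warn_once(
            "LK-condition",
            f"positive-invariance condition L*exp(K*tau) <= 1 fails "
            f"(value {value:.4g}); proceeding anyway",
        )
    return {"value": value, "holds": holds}
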