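"""Lande-equation trait dynamics on arbitrary fitness functions.

The mean trait follows the mutation-scaled fitness gradient,

    dx/dt = F(x)^(-1) G grad F(x),

with ``G`` the (co)variance matrix of mutational effects.  In one
dimension ``G`` reduces to the mutational variance ``sigma_theta``.  The
``F^(-1)`` prefactor only reparameterises time (the velocity direction
equals ``G grad ln F``), but it is kept as written because published
trajectories use that clock.  A strongly negatively correlated kernel
(``rho`` near -1) makes motion along the tradeoff direction orders of
magnitude faster than motion off it, which is what separates the
fast "optimisation on the tradeoff" phase from the slow
"tradeoff-breaking" phase.

The integrator is deterministic: fixed-order Runge-Kutta 4 with the
step length chosen so each step moves the trait vector by roughly
``target_step`` (adaptive halving on overshoot).  At domain boundaries
the velocity component pointing outside the feasible box is projected
out rather than bounced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationKernel",
    "EvolutionaryTrajectory",
    "numeric_gradient",
    "integrate_lande",
    "integrate_lande_1d",
    "integrate_lande_2d",
    "detect_phases",
]


class FitnessDomainError(RuntimeError):
    """The fitness function became non-positive or non-finite along a run."""


@dataclass(frozen=True)
class MutationKernel:
    """Bivariate Gaussian kernel of mutational effects.

    ``sigma_s`` and ``sigma_b`` are the standard deviations of effects
    on the two traits and ``rho`` their correlation; the matrix
    ``G = [[s^2, rho*s*b], [rho*s*b, b^2]]`` is positive semidefinite
    for any ``|rho| <= 1``.
    """

    sigma_s: float
    sigma_b: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_s < 0 or self.sigma_b < 0:
            raise ValueError("mutational SDs must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")

    @property
    def G(self) -> np.ndarray:
        off = self.rho * self.sigma_s * self.sigma_b
        return np.array(
            [[self.sigma_s**2, off], [off, self.sigma_b**2]]
        )


@dataclass
class EvolutionaryTrajectory:
    """Time series of a Lande integration.

    ``traits`` has one row per recorded time; ``extras`` holds any
    additional per-step series (e.g. ``f2``, distance to a tradeoff
    line, stable type proportions).
    """

    times: np.ndarray
    traits: np.ndarray
    F_values: np.ndarray
    speed: np.ndarray
    extras: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    @property
    def f2_values(self) -> np.ndarray | None:
        return self.extras.get("f2")

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.times}
        ncol = self.traits.shape[1]
        names = ["trait_1", "trait_2"][:ncol] if ncol <= 2 else [
            f"trait_{i+1}" for i in range(ncol)
        ]
        for j, name in enumerate(names):
            d[name] = self.traits[:, j]
        d["F"] = self.F_values
        for key, val in self.extras.items():
            d[key] = val
        d["speed"] = self.speed
        return pd.DataFrame(d)


def numeric_gradient(
    fitness_fn: Callable[[np.ndarray], float],
    x: Sequence[float],
    h: float | None = None,
    domain: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Finite-difference gradient of a scalar fitness function.

    Central differences with step ``h = 1e-5 * (1 + |x_i|)`` per
    coordinate; one-sided differences where a probe would leave the
    ``domain`` box.  Raises if the fitness is non-finite at any probe.
    """
    x = np.asarray(x, dtype=float)
    grad = np.empty_like(x)
    for i in range(x.size):
        hi = h if h is not None else 1e-5 * (1.0 + abs(x[i]))
        lo_b, hi_b = (-np.inf, np.inf) if domain is None else domain[i]
        up = x.copy()
        dn = x.copy()
        up[i] = min(x[i] + hi, hi_b)
        dn[i] = max(x[i] - hi, lo_b)
        if up[i] == dn[i]:
            raise FitnessDomainError(f"degenerate domain for coordinate {i} at {x[i]}")
        fu, fd = fitness_fn(up), fitness_fn(dn)
        if not np.isfinite(fu):
            raise FitnessDomainError(f"non-finite fitness at probe {up.tolist()}")
        if not np.isfinite(fd):
            raise FitnessDomainError(f"non-finite fitness at probe {dn.tolist()}")
        grad[i] = (fu - fd) / (up[i] - dn[i])
    return grad


def _project_velocity(v: np.ndarray, x: np.ndarray, domain: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Zero the velocity components that push out of the feasible box."""
    v = v.copy()
    at_lo = (x <= domain[:, 0] + eps) & (v < 0)
    at_hi = (x >= domain[:, 1] - eps) & (v > 0)
    v[at_lo | at_hi] = 0.0
    return v


def integrate_lande(
    fitness_fn: Callable[[np.ndarray], float],
    x0: Sequence[float],
    G: np.ndarray,
    domain: Sequence[tuple[float, float]],
    t_max: float = 1e4,
    target_step: float = 1e-3,
    stop_tol: float = 1e-8,
    stop_count: int = 10,
    max_steps: int = 200_000,
    min_fitness: float = 1e-8,
    aux: dict[str, Callable[[np.ndarray], float]] | None = None,
) -> EvolutionaryTrajectory:
    """Integrate ``dx/dt = F(x)^(-1) G grad F(x)`` in a feasible box.

    The RK4 step size adapts so each step displaces the traits by about
    ``target_step`` (halved and retried on >2x overshoot, growth capped
    at 2x per step).  The run ends at ``t_max``, after ``stop_count``
    consecutive steps with speed below ``stop_tol``, or aborts with
    :class:`FitnessDomainError` if the fitness drops below
    ``min_fitness`` (the printed ``1/F`` prefactor is then undefined).

    ``aux`` maps column names to extra scalar functions of the traits
    recorded alongside ``F``.
    """
    x = np.asarray(x0, dtype=float)
    dom = np.asarray(domain, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    aux = aux or {}

    def velocity(xq: np.ndarray) -> np.ndarray:
        xq = np.clip(xq, dom[:, 0], dom[:, 1])
        F = fitness_fn(xq)
        if not np.isfinite(F) or F <= min_fitness:
            raise FitnessDomainError(
                f"fitness {F!r} at {xq.tolist()} below minimum {min_fitness}"
            )
        g = numeric_gradient(fitness_fn, xq, domain=dom)
        return _project_velocity((G @ g) / F, xq, dom)

    times = [0.0]
    traits = [x.copy()]
    F_series = [fitness_fn(x)]
    aux_series = {k: [fn(x)] for k, fn in aux.items()}
    v = velocity(x)
    speed = [float(np.linalg.norm(v))]

    t = 0.0
    dt = target_step / max(speed[0], stop_tol)
    slow_streak = 0
    converged = False
    message = "t_max reached"
    for _ in range(max_steps):
        if t >= t_max:
            break
        dt = min(dt, t_max - t)
        # RK4 stages with overshoot control: reject steps that displace
        # far beyond the target, reverse the flow direction (a sign the
        # step jumped across a fitness peak) or decrease F beyond
        # round-off — the exact flow is a fitness ascent.
        F_here = F_series[-1]
        while True:
            k1 = v
            k2 = velocity(x + 0.5 * dt * k1)
            k3 = velocity(x + 0.5 * dt * k2)
            k4 = velocity(x + dt * k3)
            step = (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            disp = float(np.linalg.norm(step))
            x_new = np.clip(x + step, dom[:, 0], dom[:, 1])
            v_new = velocity(x_new)
            F_new = fitness_fn(x_new)
            ok = disp <= 2.0 * target_step
            if ok and float(v_new @ v) < 0.0:
                ok = False
            if ok and F_new < F_here - 1e-12 * (1.0 + abs(F_here)):
                ok = False
            if ok or dt <= 1e-300:
                break
            dt *= 0.5
        if (
            disp < 0.1 * target_step
            and abs(F_new - F_here) < 1e-12 * (1.0 + abs(F_here))
        ):
            # displacement and fitness change both at the numerical noise
            # floor: the flow has reached an optimum and further "motion"
            # would only record finite-difference noise
            times.append(t + dt)
            traits.append(x.copy())
            F_series.append(F_here)
            for k, fn in aux.items():
                aux_series[k].append(aux_series[k][-1])
            speed.append(float(np.linalg.norm(v_new)))
            converged = True
            message = "fitness stalled at numerical precision"
            break
        x = x_new
        t += dt
        v = v_new
        sp = float(np.linalg.norm(v))
        times.append(t)
        traits.append(x.copy())
        F_series.append(F_new)
        for k, fn in aux.items():
            aux_series[k].append(fn(x))
        speed.append(sp)
        slow_streak = slow_streak + 1 if sp < stop_tol else 0
        if slow_streak >= stop_count:
            converged = True
            message = "velocity below stop tolerance"
            break
        # aim the next step at the target displacement, growth capped
        dt_next = target_step / max(sp, 1e-300)
        dt = min(dt_next, 2.0 * dt)
    else:
        message = "max_steps reached"
    if t >= t_max:
        converged = True

    return EvolutionaryTrajectory(
        times=np.asarray(times),
        traits=np.asarray(traits),
        F_values=np.asarray(F_series),
        speed=np.asarray(speed),
        extras={k: np.asarray(vals) for k, vals in aux_series.items()},
        converged=converged,
        message=message,
    )


def integrate_lande_1d(
    fitness_fn: Callable[[float], float],
    theta0: float,
    sigma_theta: float = 0.01,
    t_max: float = 1e4,
    domain: tuple[float, float] = (0.0, 1.0),
    aux: dict[str, Callable[[float], float]] | None = None,
    **kwargs,
) -> EvolutionaryTrajectory:
    """One-dimensional trait dynamics ``d theta/dt = sigma_theta F^(-1) dF/d theta``.

    ``sigma_theta`` is the mutational variance on the trait (it enters
    linearly, as printed).
    """
    if sigma_theta < 0:
        raise ValueError("sigma_theta must be >= 0")
    scalar_fn = lambda xv: fitness_fn(float(xv[0]))
    aux_vec = (
        {k: (lambda fn: (lambda xv: fn(float(xv[0]))))(fn) for k, fn in aux.items()}
        if aux
        else None
    )
    return integrate_lande(
        scalar_fn,
        [theta0],
        np.array([[sigma_theta]]),
        [domain],
        t_max=t_max,
        aux=aux_vec,
        **kwargs,
    )


def integrate_lande_2d(
    fitness_fn: Callable[[float, float], float],
    x0: Sequence[float],
    kernel: MutationKernel,
    domain: Sequence[tuple[float, float]],
    t_max: float = 1e4,
    aux: dict[str, Callable[[float, float], float]] | None = None,
    **kwargs,
) -> EvolutionaryTrajectory:
    """Two-dimensional trait dynamics with a correlated mutation kernel."""
    vec_fn = lambda xv: fitness_fn(float(xv[0]), float(xv[1]))
    aux_vec = (
        {k: (lambda fn: (lambda xv: fn(float(xv[0]), float(xv[1]))))(fn) for k, fn in aux.items()}
        if aux
        else None
    )
    return integrate_lande(
        vec_fn, x0, kernel.G, domain, t_max=t_max, aux=aux_vec, **kwargs
    )


def detect_phases(
    traj: EvolutionaryTrajectory, speed_quantile: float = 0.1
) -> tuple[float, float | None, float]:
    """Segment a trajectory into a fast and a slow phase.

    Returns ``(t0, t1, t2)`` where ``t1`` is the first time the speed
    falls below ``speed_quantile`` times its running maximum (``None``
    if it never does, i.e. a single phase), and ``t0``/``t2`` are the
    run endpoints.
    """
    if len(traj.times) < 10:
        raise ValueError("need at least 10 samples to segment phases")
    speed = traj.speed
    running_max = np.maximum.accumulate(speed)
    below = speed < speed_quantile * running_max
    t0 = float(traj.times[0])
    t2 = float(traj.times[-1])
    idx = np.nonzero(below)[0]
    t1 = float(traj.times[idx[0]]) if idx.size else None
    return t0, t1, t2
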