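"""Ecological scaffolding: germ/soma patch ecology and dispersal weight.

Particles grow inside resource-limited patches for a fixed window ``T``
and then disperse.  Within a patch, germ cells ``g`` consume resources
``r`` to produce new germ cells (fraction ``1 - q``) or soma cells ``s``
(fraction ``q``); soma cells do not reproduce but raise the patch's
dispersal output:

    dg/dt = beta (1-q) r g / N - g
    dr/dt = -beta r g / N - d r s
    ds/dt = beta q r g / N - s

from ``g(0) = 1``, ``r(0) = N``, ``s(0) = 0``.  The patch's weight in
the dispersal pool is ``w = (1 + rho * s(T)) * g(T)``, and since patch
generations are non-overlapping and reproduce once, ``w`` stands in for
the whole-life-cycle fitness, ``F = w``.  Both particle-level measures
collapse to the germ growth rate: ``f1 = f2 = beta``.

Evolution of ``(q, beta)`` under a Lande kernel with much smaller
mutational variance on ``q`` reproduces the scaffolding route to
tradeoff breaking: a fast phase lowering ``beta`` (restraint pays at
the patch level, so ``F`` rises while ``f2 = beta`` falls), then a slow
phase raising ``q`` (soma production) in which both rise together.

When ``d = 0`` the extended system conserves
``g + s + r + integral(g + s)`` exactly; the integral is carried as a
fourth state variable, so any Runge-Kutta scheme preserves the sum to
round-off (linear invariant) and the residual is a sharp correctness
check on the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .lande import EvolutionaryTrajectory, MutationKernel, integrate_lande_2d

__all__ = [
    "ScaffoldParams",
    "PatchState",
    "patch_rhs",
    "integrate_patch",
    "patch_weight",
    "scaffold_fitnesses",
    "evolve_scaffold",
]

try:  # optional compiled kernel for the nested ODE solves
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class ScaffoldParams:
    """Patch ecology and dispersal parameters.

    ``Npatch`` is the patch carrying capacity, ``T`` the growth-phase
    duration, ``d`` the rate at which soma cells consume resources and
    ``rho_soma`` the dispersal advantage per soma cell.  The two
    evolvable traits are the germ growth rate ``beta_trait`` and the
    soma allocation fraction ``q``.
    """

    Npatch: float = 1e6
    T: float = 30.0
    d: float = 0.0
    rho_soma: float = 0.01
    beta_trait: float = 1.8
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.Npatch <= 0 or self.T <= 0:
            raise ValueError("Npatch and T must be > 0")
        if self.d < 0 or self.rho_soma < 0 or self.beta_trait < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")


@dataclass(frozen=True)
class PatchState:
    """Within-patch densities at one time point."""

    g: float
    r: float
    s: float
    t: float = 0.0


def patch_rhs(state: PatchState, params: ScaffoldParams) -> tuple[float, float, float]:
    """Time derivatives ``(dg, dr, ds)`` of the within-patch ecology."""
    g, r, s = state.g, state.r, state.s
    N, beta, q, d = params.Npatch, params.beta_trait, params.q, params.d
    growth = beta * r * g / N
    dg = (1.0 - q) * growth - g
    dr = -growth - d * r * s
    ds = q * growth - s
    return dg, dr, ds


@_njit
def _rk4_patch(beta: float, q: float, N: float, d: float, T: float, dt: float):
    """RK4 of (g, r, s, I) with I' = g + s; returns the final state."""
    g, r, s, I = 1.0, N, 0.0, 0.0
    nsteps = int(np.ceil(T / dt))
    h = T / nsteps
    for _ in range(nsteps):
        g1 = (1.0 - q) * beta * r * g / N - g
        r1 = -beta * r * g / N - d * r * s
        s1 = q * beta * r * g / N - s
        i1 = g + s

        ga, ra, sa = g + 0.5 * h * g1, r + 0.5 * h * r1, s + 0.5 * h * s1
        g2 = (1.0 - q) * beta * ra * ga / N - ga
        r2 = -beta * ra * ga / N - d * ra * sa
        s2 = q * beta * ra * ga / N - sa
        i2 = ga + sa

        gb, rb, sb = g + 0.5 * h * g2, r + 0.5 * h * r2, s + 0.5 * h * s2
        g3 = (1.0 - q) * beta * rb * gb / N - gb
        r3 = -beta * rb * gb / N - d * rb * sb
        s3 = q * beta * rb * gb / N - sb
        i3 = gb + sb

        gc, rc, sc = g + h * g3, r + h * r3, s + h * s3
        g4 = (1.0 - q) * beta * rc * gc / N - gc
        r4 = -beta * rc * gc / N - d * rc * sc
        s4 = q * beta * rc * gc / N - sc
        i4 = gc + sc

        g += h / 6.0 * (g1 + 2.0 * g2 + 2.0 * g3 + g4)
        r += h / 6.0 * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        s += h / 6.0 * (s1 + 2.0 * s2 + 2.0 * s3 + s4)
        I += h / 6.0 * (i1 + 2.0 * i2 + 2.0 * i3 + i4)
    return g, r, s, I


def integrate_patch(
    params: ScaffoldParams,
    dt: float = 1e-3,
    return_trajectory: bool = False,
):
    """Integrate one patch generation from ``(g, r, s) = (1, N, 0)``.

    RK4 with fixed step ``dt`` up to ``t = T``.  Returns the terminal
    :class:`PatchState` plus the accumulated ``integral`` of ``g + s``
    (the bookkeeping term of the ``d = 0`` conservation law); with
    ``return_trajectory=True`` the full time series is returned as well
    (pure-Python path, intended for inspection at modest ``T/dt``).

    Tiny negative round-off values are clipped to zero; states below
    ``-1e-9`` abort, since the exact flow is non-negative.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not return_trajectory:
        g, r, s, I = _rk4_patch(
            params.beta_trait, params.q, params.Npatch, params.d, params.T, dt
        )
        final = _check_state(g, r, s, params.T)
        return final, I
    # trajectory path: plain Python RK4 over the same extended system
    nsteps = int(np.ceil(params.T / dt))
    h = params.T / nsteps
    y = np.array([1.0, params.Npatch, 0.0, 0.0])
    out = np.empty((nsteps + 1, 5))
    out[0] = [0.0, *y]

    def rhs(yv: np.ndarray) -> np.ndarray:
        g, r, s, _ = yv
        st = PatchState(g=g, r=r, s=s)
        dg, dr, ds = patch_rhs(st, params)
        return np.array([dg, dr, ds, g + s])

    for i in range(nsteps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = [(i + 1) * h, *y]
    final = _check_state(y[0], y[1], y[2], params.T)
    return final, y[3], out


def _check_state(g: float, r: float, s: float, t: float) -> PatchState:
    if not (np.isfinite(g) and np.isfinite(r) and np.isfinite(s)):
        raise FloatingPointError(f"non-finite patch state at t={t}")
    vals = []
    for v in (g, r, s):
        if v < -1e-9:
            raise FloatingPointError(f"negative patch state {v} at t={t}")
        vals.append(max(v, 0.0))
    return PatchState(g=vals[0], r=vals[1], s=vals[2], t=t)


def patch_weight(params: ScaffoldParams, dt: float = 1e-3) -> float:
    """Dispersal weight ``w = (1 + rho * s(T)) * g(T)`` of a patch."""
    final, _ = integrate_patch(params, dt=dt)
    return (1.0 + params.rho_soma * final.s) * final.g


def scaffold_fitnesses(params: ScaffoldParams, dt: float = 1e-3) -> tuple[float, float, float]:
    """``(f1, f2, F)`` for one parameter set.

    Within-collective and counterfactual particle fitness both equal the
    germ growth rate ``beta`` (at the start of a generation resources
    are unconsumed and soma absent); the collective fitness is the
    dispersal weight, ``F = w``.
    """
    return params.beta_trait, params.beta_trait, patch_weight(params, dt=dt)


def evolve_scaffold(
    params0: ScaffoldParams,
    kernel: MutationKernel | None = None,
    t_max: float = 300.0,
    dt_patch: float = 1e-3,
    beta_max: float = 5.0,
    cache_digits: int = 12,
    **kwargs,
) -> EvolutionaryTrajectory:
    """Lande dynamics of ``(q, beta)`` with fitness ``F = w``.

    Defaults to uncorrelated mutational SDs ``sigma_q = 0.001`` and
    ``sigma_beta = 0.1`` (mutations move the germ growth rate far more
    readily than the soma allocation).  Every fitness evaluation nests a
    full patch integration; results are memoised on the traits rounded
    to ``cache_digits`` significant digits.
    """
    kernel = kernel or MutationKernel(sigma_s=0.001, sigma_b=0.1, rho=0.0)
    cache: dict[tuple[float, float], float] = {}

    def F(q: float, beta: float) -> float:
        key = (round(float(q), cache_digits), round(float(beta), cache_digits))
        if key not in cache:
            p = replace(params0, q=min(max(q, 0.0), 1.0), beta_trait=max(beta, 0.0))
            cache[key] = patch_weight(p, dt=dt_patch)
        return cache[key]

    traj = integrate_lande_2d(
        F,
        [params0.q, params0.beta_trait],
        kernel,
        domain=[(0.0, 1.0), (0.0, beta_max)],
        t_max=t_max,
        aux={"f2": lambda q, beta: beta},
        **kwargs,
    )
    return traj
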