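"""Size-structured life cycles of particle collectives.

A population of *particles* (cells) is structured into *collectives*
(proto-multicellular groups) indexed by a size class ``i = 1..N``.  Per
time step a collective of class ``i`` grows one class with probability
``gamma_i``, shrinks with probability ``mu_i``, dies with probability
``delta_i``, stays put otherwise (``alpha_i = 1 - gamma_i - mu_i -
delta_i``), and sheds on average ``beta_i`` single-particle propagules.
The class densities follow the linear projection ``c(t+1) = A c(t)``;
the particle count is ``n(t) = sum_j k_j c_j(t)`` with ``k_j`` particles
per class (``k_j = 2**(j-1)`` when every particle divides once per class
transition).

Collective fitness is the Malthusian parameter ``F = ln(lambda)`` with
``lambda`` the dominant (Perron) eigenvalue of ``A``.  Three particle
fitness measures are provided:

``f1``
    within-collective growth rate, ignoring collective-level birth and
    death: ``ln(1 - mu_1 + (k_2 - 1) gamma_1)``;
``f2``
    counterfactual growth rate of a hypothetical mono-particle
    collective, ignoring within-collective events:
    ``ln(1 - delta_1 + beta_1)``;
``f3``
    growth rate of the whole particle lineage, counting every event.

The central identity of this module is ``f3 = ln(lambda) = F``: particle
and collective fitness coincide whenever they are computed over the same
set of events.  ``f1`` and ``f2`` generally differ from ``F`` and from
each other, which is why trends in them cannot be read as fitness
"transfer" between levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LifeCycle",
    "EigenResult",
    "CollectiveTrajectory",
    "FitnessReport",
    "default_k",
    "build_projection_matrix",
    "check_primitive",
    "dominant_eigenpair",
    "collective_fitness",
    "simulate",
    "particle_fitness_f1",
    "f1_branching",
    "particle_fitness_f2",
    "particle_fitness_f3",
    "fitness_report",
]


class InvalidParameterError(ValueError):
    """A life-cycle rate or structural parameter is out of range."""


class DegenerateSpectrumError(ValueError):
    """The projection matrix has no usable dominant eigenvalue."""


def default_k(N: int, rule: Literal["doubling", "linear"] = "doubling") -> np.ndarray:
    """Particle counts per size class.

    ``doubling`` gives ``k_j = 2**(j-1)`` (every particle divides once
    for the collective to advance one class); ``linear`` gives
    ``k_j = j`` (one particle added per class).
    """
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    j = np.arange(1, N + 1)
    if rule == "doubling":
        return np.asarray(2.0 ** (j - 1))
    if rule == "linear":
        return j.astype(float)
    raise InvalidParameterError(f"unknown k rule {rule!r}")


@dataclass(frozen=True)
class LifeCycle:
    """Per-class demographic rates of a collective life cycle.

    Parameters
    ----------
    gamma, mu, delta, beta
        Growth, shrinkage, death and propagule-production rates, one
        entry per size class.  ``gamma[N-1]`` must be 0 (no growth past
        the maximum size) and ``mu[0]`` must be 0 (class 1 cannot
        shrink).  For every class ``gamma + mu + delta <= 1`` so the
        staying fraction ``alpha`` is a probability.
    k
        Particles per size class, strictly increasing, ``k[0] >= 1``.
        Defaults to the doubling rule.
    """

    gamma: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    beta: np.ndarray
    k: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("gamma", "mu", "delta", "beta"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        N = self.N
        for name in ("mu", "delta", "beta"):
            if len(getattr(self, name)) != N:
                raise InvalidParameterError(f"{name} must have length {N}")
        k = default_k(N) if self.k is None else np.asarray(self.k, dtype=float)
        object.__setattr__(self, "k", k)
        if len(k) != N:
            raise InvalidParameterError(f"k must have length {N}")
        if k[0] < 1 or (N > 1 and np.any(np.diff(k) <= 0)):
            raise InvalidParameterError("k must be strictly increasing with k_1 >= 1")
        if np.any(self.gamma < 0) or np.any(self.mu < 0) or np.any(self.delta < 0):
            raise InvalidParameterError("rates must be non-negative")
        if np.any(self.beta < 0):
            raise InvalidParameterError("beta must be non-negative")
        if self.gamma[-1] != 0:
            raise InvalidParameterError("gamma_N must be 0 (no growth beyond class N)")
        if self.mu[0] != 0:
            raise InvalidParameterError("mu_1 must be 0 (class 1 cannot shrink)")
        sums = self.gamma + self.mu + self.delta
        if np.any(sums > 1 + 1e-12):
            bad = int(np.argmax(sums > 1 + 1e-12)) + 1
            raise InvalidParameterError(
                f"gamma + mu + delta = {sums[bad - 1]:.6g} > 1 in class {bad}"
            )

    @property
    def N(self) -> int:
        return len(self.gamma)

    @property
    def alpha(self) -> np.ndarray:
        """Staying fractions ``1 - delta - mu - gamma``."""
        return 1.0 - self.delta - self.mu - self.gamma

    @classmethod
    def from_dict(cls, d: dict) -> "LifeCycle":
        """Build from the JSON dictionary form.

        ``k`` may be a list or ``{"rule": "doubling"|"linear"}``.
        """
        d = dict(d)
        N = int(d.pop("N"))
        k = d.pop("k", None)
        if isinstance(k, dict):
            k = default_k(N, k.get("rule", "doubling"))
        lc = cls(
            gamma=d.pop("gamma"), mu=d.pop("mu"), delta=d.pop("delta"),
            beta=d.pop("beta"), k=k,
        )
        if d:
            raise InvalidParameterError(f"unknown LifeCycle keys: {sorted(d)}")
        if lc.N != N:
            raise InvalidParameterError(f"N={N} does not match rate vectors of length {lc.N}")
        return lc

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "gamma": self.gamma.tolist(),
            "mu": self.mu.tolist(),
            "delta": self.delta.tolist(),
            "beta": self.beta.tolist(),
            "k": self.k.tolist(),
        }


@dataclass(frozen=True)
class EigenResult:
    """Dominant eigenpair of a projection matrix."""

    lam: float
    w: np.ndarray
    converged: bool
    iterations: int


@dataclass(frozen=True)
class CollectiveTrajectory:
    """Iterated class densities ``c_i(t)`` and particle counts ``n(t)``."""

    times: np.ndarray
    c: np.ndarray  # shape (T+1, N)
    n: np.ndarray  # shape (T+1,)

    def to_frame(self):
        """Tabulate as columns ``t, c_1..c_N, n``."""
        import pandas as pd

        d = {"t": self.times}
        for j in range(self.c.shape[1]):
            d[f"c_{j + 1}"] = self.c[:, j]
        d["n"] = self.n
        return pd.DataFrame(d)


@dataclass(frozen=True)
class FitnessReport:
    """Collective fitness and the three particle-fitness measures."""

    F: float
    f1: float
    f2: float
    f3: float
    measures_differ: bool = field(default=True)

    def to_dict(self) -> dict:
        return {
            "F": self.F, "f1": self.f1, "f2": self.f2, "f3": self.f3,
            "measures_differ": self.measures_differ,
        }


def build_projection_matrix(lc: LifeCycle) -> np.ndarray:
    """Assemble the ``N x N`` projection matrix ``A``.

    ``A[i, j]`` is the flow from class ``j`` to class ``i`` (0-based
    indices here): the diagonal holds the staying fractions ``alpha``,
    the sub-diagonal growth ``gamma``, the super-diagonal shrinkage
    ``mu``, and the first row additionally receives the propagule rates
    ``beta`` of every class.  Overlapping contributions sum (e.g.
    ``A[0, 0] = alpha_1 + beta_1``).
    """
    N = lc.N
    alpha = lc.alpha
    A = np.zeros((N, N))
    A[np.arange(N), np.arange(N)] = alpha
    if N > 1:
        A[np.arange(1, N), np.arange(N - 1)] = lc.gamma[:-1]
        A[np.arange(N - 1), np.arange(1, N)] += lc.mu[1:]
    A[0, :] += lc.beta
    return A


def check_primitive(A: np.ndarray) -> bool:
    """Whether a non-negative square matrix is primitive.

    Irreducibility is tested via ``(I + A)**(N-1) > 0`` and aperiodicity
    via Wielandt's bound ``A**(N**2 - 2N + 2) > 0``.  Primitivity
    guarantees a unique dominant eigenpair with strictly positive
    eigenvector (Perron–Frobenius).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidParameterError("A must be square")
    if np.any(A < 0):
        raise InvalidParameterError("A must be non-negative")
    N = A.shape[0]
    B = (A > 0).astype(float)
    M = np.linalg.matrix_power(np.eye(N) + B, max(N - 1, 1))
    if not np.all(M > 0):
        return False
    # Wielandt exponent; boolean powers to avoid overflow
    P = np.eye(N, dtype=bool)
    Ab = A > 0
    for _ in range(N * N - 2 * N + 2):
        P = (P.astype(np.int64) @ Ab.astype(np.int64)) > 0
    return bool(np.all(P))


def dominant_eigenpair(
    A: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    method: Literal["power", "dense"] = "power",
) -> EigenResult:
    """Dominant eigenvalue and normalised stable structure of ``A``.

    Power iteration from a uniform start vector with relative tolerance
    ``tol`` on the eigenvalue; falls back to a dense eigensolver if it
    has not converged after ``max_iter`` iterations (or when
    ``method="dense"``).
    """
    A = np.asarray(A, dtype=float)
    if np.all(A == 0):
        raise DegenerateSpectrumError("zero matrix has no dominant eigenvalue")
    N = A.shape[0]
    if method == "power":
        v = np.full(N, 1.0 / N)
        lam = 0.0
        for it in range(1, max_iter + 1):
            u = A @ v
            s = u.sum()
            if s <= 0:  # mass left the support of the start vector
                break
            u /= s
            if abs(s - lam) <= tol * abs(s):
                # one extra confirmation step guards metastable plateaus
                lam, v = s, u
                u2 = A @ v
                s2 = u2.sum()
                if abs(s2 - lam) <= tol * abs(lam):
                    return EigenResult(lam=s2, w=u2 / s2, converged=True, iterations=it)
            lam, v = s, u
    # dense route
    vals, vecs = np.linalg.eig(A)
    idx = int(np.argmax(np.abs(vals)))
    lam = float(np.real(vals[idx]))
    w = np.real(vecs[:, idx])
    w = np.abs(w)
    w /= w.sum()
    return EigenResult(lam=lam, w=w, converged=True, iterations=0)


def collective_fitness(lc: LifeCycle, warn_nonprimitive: bool = True) -> float:
    """Collective fitness ``F = ln(lambda)``.

    ``lambda`` is the dominant eigenvalue of the projection matrix; a
    non-primitive matrix triggers a warning (the long-run growth rate is
    then not guaranteed to be structure-independent).
    """
    A = build_projection_matrix(lc)
    if warn_nonprimitive and not check_primitive(A):
        warnings.warn("projection matrix is not primitive; F may depend on initial structure")
    return float(np.log(dominant_eigenpair(A).lam))


def simulate(lc: LifeCycle, c0: Sequence[float], T: int) -> CollectiveTrajectory:
    """Iterate ``c(t+1) = A c(t)`` for ``T`` steps from ``c0``."""
    if T < 0:
        raise InvalidParameterError(f"T must be >= 0, got {T}")
    c0 = np.asarray(c0, dtype=float)
    if np.any(c0 < 0) or not np.any(c0 > 0):
        raise InvalidParameterError("c0 must be non-negative and not all zero")
    A = build_projection_matrix(lc)
    c = np.empty((T + 1, lc.N))
    c[0] = c0
    for t in range(T):
        c[t + 1] = A @ c[t]
    n = c @ lc.k
    return CollectiveTrajectory(times=np.arange(T + 1), c=c, n=n)


def particle_fitness_f1(
    lc: LifeCycle | None = None,
    *,
    mu1: float | None = None,
    gamma1: float | None = None,
    k2: float | None = None,
) -> float:
    """Within-collective particle fitness ``ln(1 - mu1 + (k2 - 1) gamma1)``.

    Only within-collective events count: a class-1 lineage loses a
    particle with probability ``mu1``, gains ``k2 - 1`` with probability
    ``gamma1``.  Accepts either a :class:`LifeCycle` (class-1 rates and
    ``k2`` are read off it) or the three parameters directly — the
    within-collective shrink rate need not equal the collective-level
    ``mu_1``, which is pinned to 0 in :class:`LifeCycle`.
    """
    if lc is not None:
        if lc.N < 2:
            raise InvalidParameterError("f1 requires N >= 2 (k2 undefined)")
        mu1 = float(lc.mu[0]) if mu1 is None else mu1
        gamma1 = float(lc.gamma[0]) if gamma1 is None else gamma1
        k2 = float(lc.k[1]) if k2 is None else k2
    if mu1 is None or gamma1 is None or k2 is None:
        raise InvalidParameterError("provide a LifeCycle or all of mu1, gamma1, k2")
    arg = 1.0 - mu1 + (k2 - 1.0) * gamma1
    if arg <= 0:
        raise ValueError(f"f1 undefined: 1 - mu1 + (k2-1)*gamma1 = {arg:.6g} <= 0")
    return float(np.log(arg))


def f1_branching(mu1: float, gamma1: float, k2: float) -> float:
    """Growth rate of the class-1 branching process.

    A Bienaymé–Galton–Watson lineage leaving 0, 1 or ``k2`` offspring
    with probabilities ``mu1``, ``(1-mu1)(1-gamma1)`` and
    ``(1-mu1)*gamma1`` has mean offspring
    ``(1-mu1)(1 + (k2-1) gamma1)``; the log of that mean is returned.
    It differs from :func:`particle_fitness_f1` by an ``O(mu1*gamma1)``
    term.
    """
    mean = (1.0 - mu1) * (1.0 + (k2 - 1.0) * gamma1)
    if mean <= 0:
        raise ValueError(f"branching mean offspring {mean:.6g} <= 0")
    return float(np.log(mean))


def particle_fitness_f2(lc: LifeCycle) -> float:
    """Counterfactual particle fitness ``ln(1 - delta1 + beta1)``.

    The growth rate particles would have as mono-particle collectives:
    only class-1 death and propagule production enter, so ``f2`` is
    independent of the growth rates ``gamma``.
    """
    arg = 1.0 - float(lc.delta[0]) + float(lc.beta[0])
    if arg <= 0:
        raise ValueError(f"f2 undefined: 1 - delta1 + beta1 = {arg:.6g} <= 0")
    return float(np.log(arg))


def particle_fitness_f3(
    lc: LifeCycle,
    method: Literal["eigen", "trajectory"] = "eigen",
    T: int = 2000,
    tol: float = 1e-6,
) -> float:
    """Whole-lineage particle fitness.

    ``eigen`` returns ``ln(lambda)`` directly.  ``trajectory`` iterates
    the projection (with per-step renormalisation so ``ln n(t)`` is
    exact for any horizon) and least-squares fits the slope of
    ``ln n(t)`` over the final half of the run.  Both count every event
    in the lineage, and for a primitive matrix they agree: ``f3 =
    ln(lambda) = F``.
    """
    A = build_projection_matrix(lc)
    if method == "eigen":
        return float(np.log(dominant_eigenpair(A).lam))
    if method != "trajectory":
        raise InvalidParameterError(f"unknown f3 method {method!r}")
    N = lc.N
    v = np.full(N, 1.0 / N)
    log_scale = 0.0
    log_n = np.empty(T + 1)
    log_n[0] = np.log(v @ lc.k)
    for t in range(T):
        v = A @ v
        s = v.sum()
        if s <= 0:
            raise DegenerateSpectrumError("population went extinct along the trajectory")
        v /= s
        log_scale += np.log(s)
        log_n[t + 1] = log_scale + np.log(v @ lc.k)
    tail = np.arange(T // 2, T + 1)
    slope = np.polyfit(tail.astype(float), log_n[tail], 1)[0]
    return float(slope)


def fitness_report(lc: LifeCycle, f3_method: Literal["eigen", "trajectory"] = "eigen") -> FitnessReport:
    """Bundle ``F``, ``f1``, ``f2`` and ``f3`` for one life cycle.

    ``measures_differ`` flags whether the three particle measures are
    mutually distinct (beyond 1e-9) — the usual case, since each counts
    a different set of events.
    """
    if lc.N < 2:
        raise InvalidParameterError("fitness_report requires N >= 2")
    A = build_projection_matrix(lc)
    if not check_primitive(A):
        raise InvalidParameterError("projection matrix is not primitive")
    F = float(np.log(dominant_eigenpair(A).lam))
    f1 = particle_fitness_f1(lc)
    f2 = particle_fitness_f2(lc)
    f3 = particle_fitness_f3(lc, method=f3_method)
    vals = (f1, f2, f3)
    differ = all(
        abs(vals[i] - vals[j]) > 1e-9 for i in range(3) for j in range(i + 1, 3)
    )
    return FitnessReport(F=F, f1=f1, f2=f2, f3=f3, measures_differ=differ)
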