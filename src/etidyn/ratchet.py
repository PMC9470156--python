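"""Ratcheting model: phenotype switching in an alternating environment.

A nascent multicellular type ``G`` and a unicellular type ``I`` switch
into each other with probability ``p`` per generation, in an
environment that alternates deterministically between ``ng``
generations favouring ``G`` and ``ni`` generations favouring ``I``.
Each generation every cell keeps itself and produces one offspring,
which switches type with probability ``p``; the type disfavoured by the
current environment pays a growth cost (``ci = cg - delta_c`` for ``G``
in ``E_I``, ``cg`` for ``I`` in ``E_G``).  With the cost discounting
newly produced cells of the disfavoured type, the per-generation
matrices acting on the column vector ``(G, I)`` are

    A_I = [[(1-ci)(1-p) + 1,  p (1-ci) ],
           [p,                1 + (1-p)]]        (environment E_I)

    A_G = [[1 + (1-p),        p        ],
           [p (1-cg),         (1-p)(1-cg) + 1]]  (environment E_G)

(``cost_convention="offspring"``; the ``"parent"`` convention attaches
the discount to the disfavoured parent's whole offspring production
instead).  The fitness gap ``delta_c`` grows as ratcheting mutations
accumulate: they help the collective state and penalise revertants.
One full environmental cycle is ``A = A_I**ni  A_G**ng``.

Fitness bookkeeping: ``F = ln(lambda(A))`` per cycle; the counterfactual
fitness ``f2 = ln(lambda(A_I))`` (life spent entirely in the
unicell-favouring environment) and the within-collective fitness
``f1 = ln(lambda(A_G))``, both per generation.  Per-generation
normalised variants divide by the epoch lengths.

Evolving ``(delta_c, p)`` with frequent mutations on ``p`` and rare
ones on ``delta_c`` yields three phases: switching first rises
(optimisation on the ancestral tradeoff), the fitness gap then ratchets
up slowly (tradeoff breaking), and switching finally falls again
(entrenchment of the multicellular state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lande import EvolutionaryTrajectory, MutationKernel, integrate_lande_2d

__all__ = [
    "RatchetParams",
    "build_epoch_matrices",
    "cycle_matrix",
    "ratchet_fitnesses",
    "stable_G_proportion",
    "evolve_ratchet",
]


@dataclass(frozen=True)
class RatchetParams:
    """Traits and environment schedule of the switching model.

    ``delta_c = cg - ci`` may exceed ``cg`` (then ``ci < 0``: life in
    ``E_I`` has become a net benefit for the ratcheted type's
    revertants' competitors); matrix entries must stay non-negative,
    which bounds ``delta_c >= cg - 1``.
    """

    cg: float = 0.1
    delta_c: float = 0.0
    p: float = 1e-5
    ng: int = 5
    ni: int = 5
    cost_convention: str = "offspring"

    def __post_init__(self) -> None:
        if self.cost_convention not in ("offspring", "parent"):
            raise ValueError(f"unknown cost_convention {self.cost_convention!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.ng < 1 or self.ni < 1:
            raise ValueError("ng and ni must be >= 1")
        if 1.0 - self.cg < 0:
            raise ValueError(f"1 - cg must be >= 0, got cg={self.cg}")
        if 1.0 - self.ci < 0:
            raise ValueError(
                f"1 - ci must be >= 0 (ci={self.ci}); requires delta_c >= cg - 1"
            )

    @property
    def ci(self) -> float:
        return self.cg - self.delta_c


def build_epoch_matrices(params: RatchetParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation matrices ``(A_I, A_G)`` acting on ``(G, I)``.

    In each environment the disfavoured type pays the growth cost.
    Under ``cost_convention="offspring"`` the cost discounts every newly
    produced cell of the disfavoured type (whoever its parent was);
    under ``"parent"`` it discounts the whole offspring production of
    disfavoured-type parents.  Both place ``ci`` on ``G`` in ``E_I`` and
    ``cg`` on ``I`` in ``E_G`` and give the same dynamics up to
    ``O(p * c)`` rearrangements of the switching flows.
    """
    p, cg, ci = params.p, params.cg, params.ci
    if params.cost_convention == "offspring":
        AI = np.array(
            [
                [(1.0 - ci) * (1.0 - p) + 1.0, p * (1.0 - ci)],
                [p, 1.0 + (1.0 - p)],
            ]
        )
        AG = np.array(
            [
                [1.0 + (1.0 - p), p],
                [p * (1.0 - cg), (1.0 - p) * (1.0 - cg) + 1.0],
            ]
        )
    else:  # parent fecundity pays
        AI = np.array(
            [
                [(1.0 - ci) * (1.0 - p) + 1.0, p],
                [p * (1.0 - ci), 1.0 + (1.0 - p)],
            ]
        )
        AG = np.array(
            [
                [1.0 + (1.0 - p), p * (1.0 - cg)],
                [p, (1.0 - p) * (1.0 - cg) + 1.0],
            ]
        )
    if np.any(AI < 0) or np.any(AG < 0):
        raise ValueError("epoch matrices have negative entries")
    return AI, AG


def cycle_matrix(params: RatchetParams) -> np.ndarray:
    """Full-cycle matrix ``A = A_I**ni  A_G**ng`` (``E_G`` epoch first)."""
    AI, AG = build_epoch_matrices(params)
    return np.linalg.matrix_power(AI, params.ni) @ np.linalg.matrix_power(AG, params.ng)


def _dominant(M: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eig(M)
    idx = int(np.argmax(np.abs(vals)))
    lam = float(np.real(vals[idx]))
    w = np.abs(np.real(vecs[:, idx]))
    return lam, w / w.sum()


def ratchet_fitnesses(params: RatchetParams) -> dict[str, float]:
    """Log dominant eigenvalues of the cycle and epoch matrices.

    ``F`` is per full cycle while ``f1``/``f2`` are per generation; the
    ``*_per_step`` entries put all three on the per-generation scale.
    """
    AI, AG = build_epoch_matrices(params)
    A = np.linalg.matrix_power(AI, params.ni) @ np.linalg.matrix_power(AG, params.ng)
    F = float(np.log(_dominant(A)[0]))
    f1 = float(np.log(_dominant(AG)[0]))
    f2 = float(np.log(_dominant(AI)[0]))
    steps = params.ng + params.ni
    return {
        "F": F,
        "f1": f1,
        "f2": f2,
        "F_per_step": F / steps,
        "f1_per_step": f1,
        "f2_per_step": f2,
    }


def stable_G_proportion(params: RatchetParams) -> float:
    """Fraction of type ``G`` in the dominant eigenvector of the cycle.

    Censused at the end of the full cycle (after the ``E_I`` epoch).
    With ``p = 0`` the types are decoupled and the structure is not
    unique; a warning-worthy degenerate case handled by returning the
    eigenvector of the larger diagonal product.
    """
    import warnings

    if params.p == 0:
        warnings.warn("p = 0: types are decoupled, stable structure is not unique")
    A = cycle_matrix(params)
    _, w = _dominant(A)
    return float(w[0] / w.sum())


def evolve_ratchet(
    params0: RatchetParams | None = None,
    kernel: MutationKernel | None = None,
    t_max: float = 5e9,
    stop_tol: float = 1e-14,
    **kwargs,
) -> EvolutionaryTrajectory:
    """Lande dynamics of ``(delta_c, p)`` with per-cycle ``F`` as fitness.

    Defaults follow the published run: start at ``(delta_c, p) =
    (0, 1e-5)`` with uncorrelated mutational SDs ``sigma_dc = 1e-4``
    and ``sigma_p = 0.2``.  ``delta_c`` is confined to
    ``[cg - 1, cg + 1]`` (entry non-negativity below, a per-generation
    doubling cap above) and ``p`` to ``[0, 1]``.  The stop tolerance is
    far below the generic default because the slow ratcheting phase
    itself moves at order ``sigma_dc**2``.

    Recorded extras: ``f1``, ``f2`` and the stable proportion of ``G``.
    """
    params0 = params0 or RatchetParams()
    kernel = kernel or MutationKernel(sigma_s=1e-4, sigma_b=0.2, rho=0.0)

    def at(dc: float, p: float) -> RatchetParams:
        return replace(params0, delta_c=dc, p=min(max(p, 0.0), 1.0))

    def F(dc: float, p: float) -> float:
        return ratchet_fitnesses(at(dc, p))["F"]

    def prop_G(dc: float, p: float) -> float:
        import warnings

        with warnings.catch_warnings():
            # p can legitimately clip to 0 at the entrenched endpoint
            warnings.simplefilter("ignore", UserWarning)
            return stable_G_proportion(at(dc, p))

    aux = {
        "f1": lambda dc, p: ratchet_fitnesses(at(dc, p))["f1"],
        "f2": lambda dc, p: ratchet_fitnesses(at(dc, p))["f2"],
        "prop_G": prop_G,
    }
    domain = [(params0.cg - 1.0, params0.cg + 1.0), (0.0, 1.0)]
    return integrate_lande_2d(
        F,
        [params0.delta_c, params0.p],
        kernel,
        domain=domain,
        t_max=t_max,
        stop_tol=stop_tol,
        aux=aux,
        **kwargs,
    )
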