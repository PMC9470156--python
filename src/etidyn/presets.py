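"""Named parameter presets for the published example runs.

Each preset bundles the printed parameter values of one worked example:

- ``fig5``: 1D growth/persistence tradeoff landscape and Lande run
  (N=30, eta=8, p1=0.1).
- ``fig7``: relaxed 2-trait tradeoff-breaking run (N=15, eta=8, p1=0.1)
  with a strongly anticorrelated mutation kernel (rho=-0.9).
- ``box2``: ecological scaffolding run (patch capacity 1e6, growth
  window T=30, d=0, soma dispersal advantage 0.01), traits (q, beta)
  from (0, 1.8).
- ``box3``: ratcheting run (cg=0.1, traits (delta_c, p) from (0, 1e-5),
  epoch lengths ng=ni=5).

Mutational step sizes that the sources leave unprinted (the 1D sigma,
the fig7 sigmas) only rescale time, not paths or endpoints.
"""

from __future__ import annotations

from .lande import MutationKernel
from .ratchet import RatchetParams
from .scaffolding import ScaffoldParams
from .tradeoff import TradeoffParams

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, dict] = {
    "fig5": {
        "model": "tradeoff",
        "params": TradeoffParams(N=30, eta=8.0, p1=0.1),
        "theta0": 0.0,
        "sigma_theta": 0.01,
        "grid": 1001,
    },
    "fig7": {
        "model": "tradeoff2d",
        "params": TradeoffParams(N=15, eta=8.0, p1=0.1),
        "kernel": MutationKernel(sigma_s=0.05, sigma_b=0.05, rho=-0.9),
        "start": (0.0, 1.0),
        "domain": ((0.0, 2.0), (0.0, 2.0)),
    },
    "box2": {
        "model": "scaffold",
        "params": ScaffoldParams(
            Npatch=1e6, T=30.0, d=0.0, rho_soma=0.01, q=0.0, beta_trait=1.8
        ),
        "kernel": MutationKernel(sigma_s=0.001, sigma_b=0.1, rho=0.0),
    },
    "box3": {
        "model": "ratchet",
        "params": RatchetParams(cg=0.1, delta_c=0.0, p=1e-5, ng=5, ni=5),
        "kernel": MutationKernel(sigma_s=1e-4, sigma_b=0.2, rho=0.0),
    },
}


def get_preset(name: str) -> dict:
    """Return a copy of a named preset; raises KeyError with options listed."""
    try:
        return dict(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
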