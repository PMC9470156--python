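# etidyn

Demographic and evolutionary models for studying **evolutionary
transitions in individuality (ETIs)** — the process by which particles
(cells) become parts of collectives (proto-multicellular organisms)
that are themselves units of selection.

The package is aimed at theoreticians and modellers who want to:

- keep multilevel fitness bookkeeping honest: compute collective fitness
  and the *three* inequivalent particle-fitness measures on the same
  size-structured life cycle, and see exactly when they must coincide
  and when they may diverge;
- integrate deterministic (Lande-equation) trait dynamics on any fitness
  function, with tradeoff constraints encoded in correlated mutation
  kernels;
- reproduce the canonical tradeoff, ecological-scaffolding and
  ratcheting scenarios for the origin of multicellularity;
- flag candidate *tradeoff-breaking* observations in empirical trait
  tables (standardisation, least-squares tradeoff lines, convex hulls,
  studentised-residual outliers).

## The model at its core

A population of collectives is structured by size class `i = 1..N`
(`k_i` particles per class, `k_i = 2^(i-1)` by default). Per time step a
class-`i` collective grows (`γ_i`), shrinks (`μ_i`), dies (`δ_i`) or
stays (`α_i = 1 − γ_i − μ_i − δ_i`), and sheds `β_i` single-particle
propagules. Densities follow `c(t+1) = A c(t)` with a non-negative
projection matrix `A`; when `A` is primitive, Perron–Frobenius gives a
dominant eigenvalue `λ` and stable structure `w`, and collective fitness
is the Malthusian parameter

```
F = ln λ.
```

Particle fitness can be computed three ways:

| measure | events counted | closed form |
|---------|----------------|-------------|
| `f1` | within-collective only | `ln(1 − μ₁ + (k₂−1) γ₁)` |
| `f2` | counterfactual mono-particle collective | `ln(1 − δ₁ + β₁)` |
| `f3` | every event in the lineage | `ln λ  (= F)` |

`f3 = ln λ = F` is an identity, not a coincidence: commensurably
computed particle and collective fitness are equal. Observed
"fitness decoupling" (F up, f2 down) therefore reflects a *tradeoff*
between traits whose optima differ between the ancestral and collective
context, not a transfer of fitness between levels.

Trait evolution follows the Lande equation

```
dθ̄/dt = σ_θ F(θ̄)⁻¹ dF/dθ          (1 trait)
d(s,b)/dt = F⁻¹ G ∇F(s,b)          (2 traits, mutation covariance G)
```

with `G = [[σ_s², ρσ_sσ_b], [ρσ_sσ_b, σ_b²]]`. A strong negative
mutational correlation (`ρ = −0.9`) makes motion along a tradeoff line
fast and motion off it slow — the two-phase signature of tradeoff
breaking. The ecological-scaffolding patch model (germ/soma/resource
ODE, dispersal weight `w = (1 + ρ s(T)) g(T)`) and the ratcheting
environment-switching matrix model are included as the two standard
alternative routes to the same observations.

## Worked example

```python
import etidyn as e

lc = e.LifeCycle(gamma=[0.2, 0.0], mu=[0.0, 0.1],
                 delta=[0.5, 0.3], beta=[0.2, 0.9])
print(e.build_projection_matrix(lc))
print(e.fitness_report(lc))
```

```
[[0.5 1. ]
 [0.2 0.6]]
FitnessReport(F=1.332267629550187e-15, f1=0.1823215567939546,
              f2=-0.35667494393873245, f3=1.332267629550187e-15,
              measures_differ=True)
```

This two-class collective is exactly stationary (`λ = 1`, so
`F = f3 = 0`), yet its within-collective particle fitness is positive
(`f1 = ln 1.2 ≈ 0.18`: class-1 lineages grow inside collectives) and
its counterfactual fitness is negative (`f2 = ln 0.7 ≈ −0.36`: the same
particles alone would decline). Three incommensurable numbers, one
organism — which is why trends in any single particle measure say
little about an ETI by themselves.

The growth/persistence tradeoff family shows the optimum split that
makes fitness-decoupling observations possible:

```python
params = e.TradeoffParams(N=30, eta=8.0, p1=0.1)
land = e.fitness_landscape(params, 1001)
print(e.argmax_trait(land, "f2"), e.argmax_trait(land, "F"))
```

```
0.0 0.34800000000000003
```

The counterfactual optimum sits at zero investment in collective
survival, the collective optimum at θ* ≈ 0.35; a Lande ascent from
θ = 0 (`e.evolve_tradeoff_1d(params)`) climbs F monotonically while f2
falls the whole way.

The same commands are available from a thin CLI, e.g.

```bash
etidyn tradeoff argmax --which F --n 30 --eta 8 --p1 0.1
etidyn ratchet --out traj.csv
etidyn observe --seed 1
```

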