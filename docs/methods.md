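# Methods

This note documents the models implemented in `etidyn`, the numerical
choices behind them, and what the shipped tests do and do not
demonstrate.

## Size-structured collective demography

Collectives are binned into size classes `1..N` with `k_i` particles
per class (doubling rule `k_i = 2^(i-1)` by default: every particle
divides once per class transition; a linear rule is available). The
per-step rates `γ_i` (growth), `μ_i` (shrinkage), `δ_i` (death) and
`β_i` (propagule production into class 1) define the projection matrix
`A` with `a_ij` the flow from class `j` to class `i`; staying fractions
`α_i = 1 − γ_i − μ_i − δ_i` must be probabilities, `γ_N = 0` and
`μ_1 = 0` are structural. The model is density-independent: particles
and collectives never compete, and there are no cheater/free-rider
dynamics.

**Eigen-analysis.** `dominant_eigenpair` runs power iteration from a
uniform start vector with relative tolerance `1e−12` on λ (max 100 000
iterations) and falls back to `numpy.linalg.eig` when not converged —
a deterministic, seed-free default with an exact backstop. Primitivity
is checked algebraically (irreducibility via `(I+A)^(N−1) > 0`,
aperiodicity via the Wielandt exponent `N²−2N+2`), not only through the
sufficient condition `0 < α_i < 1, β_i > 0`, which misses valid
primitive cycles.

**Fitness measures.** `F = ln λ`. The particle measures:

- `f1 = ln(1 − μ₁ + (k₂−1)γ₁)` counts only within-collective events.
  The class-1 lineage is also a Bienaymé–Galton–Watson process whose
  mean offspring is `(1−μ₁)(1+(k₂−1)γ₁)`; the two expressions differ by
  an `O(μ₁γ₁)` cross term. Both are exposed (`particle_fitness_f1`,
  `f1_branching`) and neither is privileged: they answer slightly
  different bookkeeping questions (additive vs multiplicative
  combination of loss and gain) and coincide whenever `μ₁γ₁ ≈ 0`.
  Because the collective-level model pins `μ_1 = 0`, `f1` also accepts
  free-standing `(μ₁, γ₁, k₂)` arguments so the within-collective
  shrink rate can be specified independently.
- `f2 = ln(1 − δ₁ + β₁)` is the counterfactual mono-particle growth
  rate; it uses `β₁` exactly as parameterised (no re-derivation of a
  "growth-free" fecundity), since the definition only ignores
  within-collective events, not the fecundity the focal model assigns
  to class 1.
- `f3` counts everything. The eigen route returns `ln λ` directly; the
  trajectory route iterates the projection with per-step
  renormalisation (so `ln n(t)` is exact at any horizon, no overflow)
  and least-squares fits the slope of `ln n(t)` over the final half of
  a default `T = 2000` steps — robust to transients for any primitive
  matrix with a reasonable spectral gap.

## The growth/persistence tradeoff family

A trait `θ ∈ [0,1]` splits investment into survival `s = θ` and growth
`b = 1 − θ`. Rates saturate exponentially with scaling factor `η`:
`p_i = 1 − e^{−ηs}` (`i ≥ 2`; class 1 keeps a fixed `p₁`),
`g_i = 1 − e^{−ηb}` (`g_N = 0`), propagule output `m_i = ηb·k_i`, and
`α_i = p_i(1−g_i)`, `γ_i = p_i g_i`, `μ_i = 0`. Class fertilities
follow the birth-flow construction,
`β_i = √p₁ · ((1+α_i)m_i + γ_i m_{i+1})/2`, averaging current and
next-class fecundity discounted by the square-root propagule survival.
The printed prefactor is typographically ambiguous; the alternative
`p₁·0.5` reading is available via `beta_convention="linear"` (it rescales
all `β_i` by `√p₁` and moves neither argmax in the reference setting).

Defaults `N=30, η=8, p₁=0.1` give `argmax f2 = 0` and
`argmax F ≈ 0.348` on a 1001-point grid: the optimum split that makes a
fitness-decoupling observation inevitable once selection drives θ from
the ancestral optimum toward θ*. The relaxed two-trait model applies
the same maps to free `(s, b)` on `[0, 2]²` — exponential rate maps stay
valid for any non-negative traits; the cap only bounds the integrator's
domain.

## Lande dynamics

Velocity `F(x)⁻¹ G ∇F(x)` with `G` the mutational covariance. The
`1/F` prefactor is implemented as printed even though it only rescales
time (the direction equals `G ∇ ln F`); runs abort informatively if
`F ≤ 1e−8`. Gradients are central differences with
`h = 1e−5·(1+|x|)`, one-sided at domain boundaries — a balance between
truncation and the round-off of fitness values computed through
eigen-solves or ODE integrations.

The integrator is fixed-order RK4 with an adaptive step *length*
target: `dt` is chosen so each step displaces the traits by about
`10⁻³` (in trait units), halving on overshoot and capping growth at 2×
per step. Three safeguards make the discrete flow respect the
gradient-ascent structure exactly where tests rely on it:

1. steps that displace more than twice the target are rejected;
2. steps that reverse the velocity direction (`v_new · v_old < 0`) are
   rejected — this is the discrete signature of jumping across a
   fitness peak, and rejecting it makes 1D trajectories monotone in θ;
3. steps that decrease `F` beyond round-off (`1e−12` relative) are
   rejected.

Runs stop at `t_max`, when the speed stays below `1e−8` for 10 steps,
or when both the step displacement and the fitness change fall to the
numerical noise floor ("stalled"): at that point further motion would
only record finite-difference noise, so the run ends without appending
it. Boundary handling projects the outward velocity component to zero
(no bounce): traits are hard-bounded investments.

Everything is deterministic — identical inputs give identical
trajectories bit for bit.

**Phase segmentation** (`detect_phases`) reports the first time the
speed drops below a quantile (default 0.1) of its running maximum; with
the `ρ = −0.9` kernel the fast/slow speed ratio is
`(1+ρ)/(1−ρ) ≈ 0.05`, safely below the threshold.

**Time scales.** The mutational step sizes for the 1D run (`σ_θ`) and
the 2D tradeoff run (`σ_s = σ_b`) are free time-scale choices: they
move no endpoint and bend no path (only `ρ` shapes the path). The
package defaults are `σ_θ = 0.01` and `σ_s = σ_b = 0.05`. Whether
published `σ` values denote SDs or variances is ambiguous in the
sources; `MutationKernel` treats them as SDs (entries `σ²` in `G`),
which only affects clocks and the strength of kernel anisotropy, not
the qualitative dynamics.

## Ecological scaffolding

Within a patch of capacity `N`, germ cells `g`, soma cells `s` and
resources `r` follow

```
g' = β(1−q) r g / N − g,   r' = −β r g / N − d r s,   s' = β q r g / N − s
```

from `(g, r, s)(0) = (1, N, 0)` over a growth window `T`. The patch's
dispersal weight is `w = (1 + ρ s(T)) g(T)`; because patch generations
are non-overlapping and reproduce once, `w` serves as the collective
fitness functional (`F = w`; using `ln w` would trace the same path on
a different clock). Both particle measures collapse to the germ growth
rate: `f1 = f2 = β`.

The integrator is fixed-step RK4 (`dt = 10⁻³` for `T = 30`), compiled
with numba when available (pure-Python fallback otherwise), and the
bookkeeping integral `∫(g+s)dτ` is carried as a fourth state variable:
with `d = 0` the sum `g + s + r + ∫(g+s)` is then a *linear* invariant
of the extended system, which Runge–Kutta schemes preserve exactly, so
the conservation residual stays at accumulation-of-round-off level
(~`1e−8` at `N = 10⁶`) and is a sharp sign-error detector for the
right-hand side. Negative round-off states are clipped at zero with an
abort below `−1e−9`. Fitness evaluations nested inside gradient calls
are memoised on the traits rounded to 12 significant digits.

The evolution run starts from `(q, β) = (0, 1.8)` with uncorrelated
`σ_q = 0.001 ≪ σ_β = 0.1` and defaults to a horizon of `t_max = 300`:
long enough to contain the fast β-descent (F up, f2 = β down) and a
clear stretch of the slow soma-recruiting phase (q up, F and f2 both
up), which is the structure of interest; full stationarity on the
curved (q, β) ridge lies far beyond it and adds nothing qualitative.

## Ratcheting in a switching environment

Two types — multicellular `G` and unicellular `I` — switch into each
other with probability `p` per generation while the environment
alternates deterministically (`ng` generations favouring `G`, then `ni`
favouring `I`; defaults `ng = ni = 5`, which the sources leave
unstated, so both are explicit parameters). Each generation every cell
keeps itself and adds one offspring; the type disfavoured by the
current environment pays a growth cost: `ci = cg − Δc` for `G` in
`E_I`, `cg` (fixed at 0.1) for `I` in `E_G`. Two cost conventions are
provided — the default discounts newly produced cells of the
disfavoured type, the alternative (`cost_convention="parent"`)
discounts the whole offspring production of disfavoured parents; they
differ only in `O(p·c)` placement of the switching flows.

Fitness bookkeeping: `F = ln λ(A_I^{ni} A_G^{ng})` per cycle,
`f1 = ln λ(A_G)` and `f2 = ln λ(A_I)` per generation (per-step
normalised variants are returned alongside). The stable `G` share is
read off the dominant eigenvector of the cycle matrix, censused after
the `E_I` epoch.

Evolution of `(Δc, p)` starts at `(0, 10⁻⁵)` with `σ_Δc = 10⁻⁴ ≪ σ_p
= 0.2`. `Δc` is confined to `[cg − 1, cg + 1]`: the lower bound keeps
matrix entries non-negative, the upper bound caps the ratcheted
advantage at one extra doubling per generation. Because the slow
ratcheting phase itself advances at order `σ_Δc² ≈ 10⁻⁸`, the run uses
a stop tolerance of `1e−14` and a long nominal horizon (`5×10⁹`; the
displacement-targeted stepper makes wall-clock cost proportional to
path length, not model time). The resulting trajectory shows the
three-phase structure: `p` rises (optimisation on the ancestral
tradeoff), `Δc` ratchets up (tradeoff breaking, with `f2` recovering),
`p` falls again (entrenchment), with the stable `G` share increasing
overall and `F` non-decreasing throughout.

## Tradeoff-breaking detection on trait tables

Tables of `(group, x, y)` observations are standardised by pooled
z-scoring (sample SD; the pooled convention matches plotting different
groups on common axes). Tradeoff lines are ordinary least squares of
`y` on `x`, pooled and per group; accessible phenotype ranges are
convex hulls per group (Andrew's monotone chain, counter-clockwise,
collinear edge points dropped). A row is flagged as a candidate
tradeoff breaker when its residual from the pooled line exceeds
`k_sd = 2` residual SDs *on the both-traits-high side* (positive
residual under a negative slope) — an explicit, testable operational
version of marking points that "depart notably" from the common
tradeoff pattern. Tables with residual SD at round-off level are
treated as perfectly collinear (no flags). Flags are invariant under
standardisation (OLS residuals are affinely equivariant).

**Synthetic tables.** The seeded generator strings groups along a
shared negative-slope line (group centres spaced on the line, points
jittered along it, Gaussian noise of SD 0.05 on `y`) and displaces
`n_breakers` rows perpendicular to the line toward the high/high
quadrant. The default displacement (0.5, i.e. ten noise SDs) emulates
the gross departures seen in real tradeoff-breaking observations and
keeps the planted rows far from the flagging threshold, so perfect
precision/recall is an implementation check, not a statistical
statement near the detection boundary. What passing recovery tests do
*not* show: performance on real tables with heavy-tailed noise,
group-specific slopes, or breakers near threshold — the flagger is a
screening device, not a calibrated test.

## Problem sizes and limitations

The shipped test suite uses the published parameter points directly
(30- and 15-class matrices, `N = 10⁶` patches, 1001-point landscapes);
scaled-down variants appear only where a property is
parameter-independent. Known limitations: no density dependence or
game-theoretic interactions in the collective model; no stochastic
individual-based evolution (Lande approximation only, so no branching
or drift); strictly periodic environments in the ratchet model; no
phylogenetic correction in the observation module.
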