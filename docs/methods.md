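# Methods

## Model

The map acts on dimensionless prey/predator densities `(x, y)`:

```
x' = x + r x e^(1-x) - α x y / (1 + x)
y' = y + α x y / (1 + x) - γ y
```

`r x e^(1-x)` is Ricker recruitment (near-exponential at low density,
over-compensatory at high density), `α x y/(1+x)` a Holling type II
predation term that saturates in prey density, and `γ y` predator
mortality. All three rates are per-generation and strictly positive. The
map is iterated over the reals with no clamping: biological admissibility
(`x, y ≥ 0`) is tracked as a flag on orbits, because clamping would alter
the bifurcation structure; coordinates beyond 1e6 in magnitude mark an
orbit divergent (data, not an exception).

Fixed points: extinction `p₀ = (0,0)` always; coexistence
`p₁ = (γ/(α-γ), r/(α-γ) e^((α-2γ)/(α-γ)))` iff `α > γ`. At p₁ the identity
`α x*/(1+x*) = γ` makes the Jacobian entry `J₂₂ = 1` exact, and with
`E = e^((α-2γ)/(α-γ))`:

```
trace = 2 - r E γ² / (α(α-γ))
det   = 1 + r E γ (γ² - γ + α² - 2αγ) / (α(α-γ))
```

Both are linear in `r`, which shapes the whole bifurcation analysis.

## Stability and criticality conventions

One characteristic-polynomial convention is used everywhere:
`R(ρ) = ρ² - trace·ρ + det`. The jury conditions for a 2-D map then read
LAS ⟺ `R(1) > 0`, `R(-1) > 0`, `det < 1`. Classification is computed from
the multiplier moduli directly (equivalent, better conditioned), with a
unit-circle tolerance of 1e-9 for analytic work and 1e-6 when feeding
numerical continuation; any modulus within tolerance of 1 is reported
non-hyperbolic regardless of the other multiplier.

Two corrections of printed source material are applied and surfaced in
the JSON reports:

* **Extinction point.** p₀'s multipliers are `{1 + r e, 1 - γ}`; since
  `1 + r e > 1` for every `r > 0`, p₀ is a saddle for `0 < γ < 2` (source
  for `γ > 2`), never stable. The often-printed stability inequality
  `r e (1-γ) < γ` contradicts this and is exposed as-printed for
  transparency only.
* **Flip criticality** at p₁ is `R(-1) = 0`, i.e.
  `4 + r E γ(γ² - 2γ + α² - 2αγ)/(α(α-γ)) = 0`, giving the closed form
  `r_c = -4α(α-γ) e^{-(α-2γ)/(α-γ)} / (γ(γ² - 2γ + α² - 2αγ))` whenever
  the slope coefficient is negative. (The alternative printed condition
  equals `R(1) = 0`, unsatisfiable for `r > 0`.) If `det = 1` at the root
  the second multiplier is also −1 (1:2 resonance, e.g. α = 2, γ = 1 where
  the root is r = 8): no generic flip exists and a domain error names the
  degeneracy.

Because `det - 1` at p₁ is `r` times a parameter-only factor, a
Neimark–Sacker bifurcation cannot be located in `r`: `det = 1` holds for
no positive `r`, or for *every* `r` on the degenerate surface
`γ² - γ + α² - 2αγ = 0` (e.g. α = 2, γ = 1, or α ≈ 0.847723 for γ = 0.3),
where the transversality derivative also vanishes. The NS machinery is
therefore exposed as a standalone computation at user-supplied
`(α, γ, r)` rather than tied to a solved critical rate.

## Neimark–Sacker normal form

At p₁ with a complex pair `ρ = η ± iζ` (`η = trace/2`, `ζ = √(det - η²)`,
`|ρ| = √det`), the shifted map's Taylor coefficients `B_ij` (through third
order; the linear ones are the Jacobian entries) are transformed with the
real eigenbasis `T = [[B₁₂, 0], [η - B₁₁, -ζ]]`, which brings the linear
part to the rotation `[[η, -ζ], [ζ, η]]`. The nonlinearity coefficients
`A_ij`, the complex combinations δ₁₁, δ₂₀, δ₀₂, δ₂₁, and the first
Lyapunov coefficient

```
χ = -Re[ (1-2ρ̄)ρ̄²/(1-ρ) · δ₁₁δ₂₀ ] - ½|δ₁₁|² - |δ₀₂|² + Re(ρ̄ δ₂₁)
```

are evaluated exactly. `χ < 0` ⇒ attracting invariant closed curve,
`χ > 0` ⇒ repelling. Strong resonances are excluded by requiring
`|ρ^m - 1| > 1e-6` for `m = 1..4`.

All closed forms were re-derived from the transformation itself (and
machine-verified symbolically during development) because the printed
versions in source treatments carry typos: the linear coefficients B₁₁ and
B₂₂ are printed off by +1 and +γ respectively (B₂₂ at p₁ is exactly 1);
A₁₁ and A₁₄ appear with flipped overall signs and A₂₂/A₂₄ with a flipped
`(η - B₁₁)` term; and the reduced δ₂₁ must read
`(3A₁₁ + A₂₄ + i(3A₂₁ - A₁₄))/8` — the `A₁₄` (from Ψ_XXY = 2A₁₄) is the
unique choice consistent with the general δ₂₁ definition, and the only one
under which χ is invariant when the conjugate multiplier is chosen
instead (a property the test suite checks at 1e-8). The undefined symbol
"l" in printed δ formulas is the imaginary unit.

## Flip (period-doubling) normal form

At `r = r_c + s` the analysis shifts coordinates to the *r-dependent*
fixed point. This frame choice matters: `x*` does not move with `r` and
`y*(r)` is linear in `r`, so the shifted map has no constant term, is
linear in `s`, and the center-manifold ansatz `Y = k₁X² + k₂Xs` holds with
`k₀ = k₃ = 0` exactly (a frozen-fixed-point frame leaves a constant O(s)
forcing that breaks `k₀ = 0`). The `s`-couplings are then simply the
r-derivatives of the Jacobian and quadratic Taylor coefficients at p₁.

With eigenbasis `M = [[B₁₂, B₁₂], [-1 - B₁₁, ρ₂ - B₁₁]]` (columns: the
eigenvectors for −1 and ρ₂; invertibility needs `B₁₂ ≠ 0`, `ρ₂ ≠ -1`,
both guarded), the standard substitution — transform, solve the manifold
invariance order by order, collect the X-equation — yields the reduced map

```
L(X) = -X + n₁X² + n₂Xs + n₃X²s + n₄Xs² + n₅X³ + O(4)
```

with `ϖ₁ = n₂` and `ϖ₂ = n₅ + n₁²` (identities that hold by construction
and are re-tested against independent code paths). The composition is
evaluated from closed-form monomial bookkeeping derived once and verified
symbolically; the long printed `n₃..n₅` expressions are not transcribed
(they contain unbalanced parentheses, and the printed `k₂`/`n₂` carry
spurious `B̃₁₈` terms). Three independent oracles arbitrate:

* `n₂ = dρ₁/dr` at the crossing, by implicit differentiation of the
  characteristic polynomial (agreement ~1e-9);
* `k₁, n₁, n₅` against a least-squares fit of the numerically restricted
  one-dimensional map on the fitted manifold (≤ 1e-3 relative);
* the sign of `ϖ₂` against direct simulation of the period-2 branch,
  including the amplitude law `d² ∝ (r - r_c)` (R² > 0.99).

For the α = 0.5, γ = 0.3 scenario: `r_c ≈ 3.925527`, `ρ₂ = 6/7`,
`k₁ ≈ -0.17062`, `n₁ ≈ 0.07723`, `n₂ ≈ -0.54868`, `n₅ ≈ 0.04073`,
`ϖ₂ ≈ 0.04670 > 0` — a supercritical flip with a stable period-2 branch,
as the simulations confirm.

Truncation: `s` is carried to first order. In the tracked frame the map
is exactly linear in `s`, so `k₃ = 0` and the `n₄ = ψ_Ys k₂` term are
exact rather than approximations.

## Lyapunov exponents, periods, diagrams

The maximal Lyapunov exponent uses tangent-vector propagation: a unit
vector (initial direction drawn from a seeded RNG; the estimate is
direction-independent to < 0.005) is pushed through the analytic Jacobian
along the orbit and renormalized each step; logs of the stretch factors
are averaged after the transient. This is exact for maps with analytic
Jacobians and avoids finite-difference shadowing error. At a stable fixed
point the estimate equals `log max|ρᵢ|`; on a period-k cycle it equals
`(1/k) log` spectral radius of the Jacobian product around the cycle —
both used as test oracles at 0.01 nats.

Period detection declares the smallest `k ≤ 64` such that every one of
the last `2k` post-transient points recurs after `k` steps within 1e-6
(max norm); otherwise the orbit is aperiodic. Diagram sweeps use a
uniform `r` grid with warm starting (each row seeded from the previous
row's final state) by default, following the stable branch as diagrams
conventionally do; cold starts are available. A row is labelled chaotic
when it is aperiodic *and* its MLE exceeds 0.01 (guarding marginal rows
near accumulation points and quasiperiodic rows, whose MLE is ~0).
Defaults: transient 10³, 200 samples/row, 600 grid points per unit `r`;
reported standalone MLE values use 10⁵ steps. The test suite scales these
to transients of 8×10³–4×10⁴ and ~240-point grids, which resolve every
doubling onset it asserts to within one grid step.

## What the scenarios actually do (and one discrepancy)

* **case3 (α = 0.5, γ = 0.3)**: p₁ is LAS for `r < r_c ≈ 3.9255`, loses
  stability in a supercritical flip, and a stable 2-cycle follows. Within
  `3 < r < 6` *nothing further happens on this branch*: the 2-cycle's
  multipliers stay inside the unit circle, cold starts from (0.33, 0.64)
  escape to infinity beyond `r ≈ 5.8`, and under warm continuation the
  2-cycle persists to `r ≈ 7.66` where it loses stability through a
  secondary Neimark–Sacker (torus) bifurcation; locking windows
  (including periods 8 and 16) and chaos (MLE up to ~0.19) follow at
  `r ≈ 8.1–8.6` before the attractor's basin collapses. Narratives that
  place a full period-doubling cascade to chaos for this scenario inside
  `3 < r < 6` do not survive recomputation.
* **case1 (α = 1, γ = 0.5)** is where that cascade actually lives:
  flip at `r_c = 16/3 ≈ 5.3333`, then doublings at ≈ 5.392 (4), 5.610 (8),
  5.624 (16), 5.629 (32), chaos with MLE up to ~0.07 at `r ≈ 5.630–5.635`,
  and basin escape at ≈ 5.636 — all inside `[5.0, 5.6789]`, reachable by
  warm-start continuation (cold starts escape past the flip). The cascade
  and chaos tests therefore run on this parameterization.
* **case2 (α = 2, γ = 1)** sits on the degenerate surface `det ≡ 1`: the
  p₁ multipliers lie on the unit circle for every `r`, no NS criticality
  in `r` exists (transversality 0), and closed invariant curves are
  observed directly. χ is computable there (e.g. χ ≈ +0.078 at r = 2,
  χ ≈ -0.057 at r = 0.30423); for χ < 0 parameter sets, orbits started 1%
  from p₁ stay on a bounded closed-curve-like attractor for 10⁵ steps
  (the basin on this surface is narrow: 5% offsets can escape).

## Numerical choices

* Fixed-point tolerance 1e-10 per coordinate (scaled by |y*| when y* is
  large); multiplier ordering: larger modulus first, positive imaginary
  part first in a conjugate pair.
* Bisection/Brent root finding for the numeric flip location (xtol 1e-8),
  required to agree with the closed form to 1e-8.
* Degeneracy guards: flip verdict "degenerate" when |ϖ₁| or |ϖ₂| < 1e-10;
  resonance tolerance 1e-6; divergence bound 1e6.
* Test oracles avoid high-order finite differences (roundoff-limited at
  ~1e-3 relative for cubic terms); Taylor coefficients are instead
  cross-checked against a degree-6 bivariate polynomial least-squares fit
  of map samples on a radius-1e-2 grid (~1e-6 relative).

## Limitations

* Only `r` is treated as the bifurcation parameter (no continuation in α
  or γ, no codimension-2 analysis).
* The invariant circle after an NS interaction is not continued
  rigorously; resonance tongues are not analyzed.
* The period-2 branch is observed by simulation, not continued; secondary
  flips get no normal forms of their own.
* Only the maximal Lyapunov exponent is computed, not the full spectrum.
* The scenarios are idealized constant-parameter settings; none of the
  conclusions transfer directly to ecological data with environmental
  variability or stochasticity.
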