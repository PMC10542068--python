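# Methods

## Transport model and assumptions

The film is treated as a plane sheet with uniform initial antioxidant load
releasing into a finite, perfectly stirred simulant. The assumptions are the
classical ones for this geometry:

1. no external mass-transfer resistance (no boundary layer on the liquid
   side) — the film surface is always in local equilibrium with the bath;
2. one-dimensional diffusion through the film thickness;
3. constant diffusivity `D` (no concentration or time dependence, no
   swelling-coupled transport, no moving boundary).

Under these assumptions the normalized simulant concentration
`C_S(t)/C_S,∞` is the eigenfunction series given in the README, with
eigenvalues `qₙ` solving `tan(q) = −αq` and
`α = V_S/(K_FS·V_F)` the effective simulant-to-film capacity ratio. `α`
controls both the equilibrium partitioning (the fraction of load ultimately
released is `α/(1+α)`) and the spectrum of the series weights.

**Thickness convention.** Both model variants consume a single
characteristic diffusion length `L`. A film wetted on both faces is
symmetric about its midplane, so `L` is half the measured thickness
(`exposure="two_sided"`, the default); a film with an impermeable backing
uses the full thickness (`"one_sided"`). Using one convention for both the
series and the erfc variant keeps them mutually consistent — they are two
expansions of the same solution and must agree in their common domain.

**Eigenvalue roots.** `tan(q) = −αq` has exactly one root per interval
`((k−½)π, kπ)`. The solver brackets each root in that closed interval using
the pole-free equivalent form `sin(q) + αq·cos(q) = 0` (which has guaranteed
opposite signs at the endpoints) and refines with Brent's method to machine
tolerance, followed by one Newton polish on the tan form wherever
`|cos q| > 1e-8`. The phrase "non-positive roots" sometimes attached to this
eigenvalue problem is read as the non-zero positive roots: `q = 0` is the
trivial root and the `qₙ` enter only as `qₙ²`.

**Truncation.** The default keeps 12 roots. The series weights
`Bₙ = 2α(1+α)/(1+α+α²qₙ²)` sum to 1 over the full spectrum, and the deficit
`1 − Σ₁ᴺ Bₙ` of a truncated sum is exactly the (spurious) value the
truncated series reports at `t = 0`. The deficit decays like
`2(1+α)/(απ²N)`, so convergence requires `N ≫ 1/α`: at `α = 5` the 12-root
deficit is 0.017, but at `α = 0.0147` it is 0.68. Truncated outputs are
clamped to the physical range `[0, 1]` (the raw value is available via
`clip=False`); note the raw truncated value can never be negative — partial
sums of positive weights keep it in `(0, 1]` — so the clamp's practical role
is bookkeeping, not rescue. Oracle comparisons in the tests use 200–2000
roots as stated per test.

**Model selection.** The erfc short-time form is exact while the depletion
layer has not reached the midplane (`Dt/L² ≪ 1`), which for small `α` covers
the entire approach to bath equilibrium (timescale `α²L²/D`). The package
follows the `α < 0.01 → erfc, otherwise series` rule, warns above
`α = 1000` (outside the range over which the 12-root series was validated),
and treats the boundary `α = 0.01` as series. The erfc form's large-time
asymptote is `1 + α`, not 1; values above 1 are flagged with a warning and
returned unmodified rather than silently truncated, because truncation would
hide a model-domain violation from the user.

## Fitting

The observed curve is normalized to `C_S(t)/C_S,∞` — by a preset equilibrium
concentration when one is known, otherwise by the mean of the last 3 points
(the release plateaus at late times). The loss is the sum of squared
residuals of the normalized ratios (the models are stated in ratio form, and
this makes the fit exactly invariant to the concentration scale). The single
unknown `log₁₀ D` is minimized over `[−18, −8]` by a deterministic coarse
grid (201 points) followed by bounded Brent refinement to 1e-10 in log
space; there is no random initialization, so identical inputs give
bit-identical results. `R²` is computed as `1 − SS_res/SS_tot` on the
normalized ratios and reported as-is (it may be negative).

Whether `α` should itself be estimated from the curve is genuinely open; the
package treats `α` as an input (given directly, or derived from `K_FS` and
the volumes), and offers a clearly-labelled two-parameter extension
(`fit_alpha=True`) that co-estimates `(D, α)` by a nested bounded search.
With the truncated series the `t = 0` level pins `α` and the decay pins `D`,
so the noiseless round trip recovers both; with noise the extension should
be treated as exploratory.

## PDE oracle

The analytical forms are cross-checked against a direct numerical solution
of Fick's second law on the half-sheet `[0, L]` with a zero-flux midplane, a
partition condition `C_F(L,t) = K_FS·C_S(t)` at the interface, and the bath
mass balance closing the system — exactly the boundary conditions under
which the series is the exact solution. The discretization is
vertex-centered finite volumes: the interface node's half-cell is merged
with the bath unknown, which makes total mass conservation exact up to
linear-solver round-off (measured drift ~1e-11, tolerance 1e-6, enforced at
run time). Time stepping is implicit Euler on a geometric substep schedule
(first step 1e-10 of the final time, 2% growth), which resolves the
early-time boundary layer; the output times are merged into the schedule so
no interpolation is used. With 401 nodes the solver agrees with a 200-root
series to < 2e-3 at every positive output time across `α ∈ {0.05..50}`;
spatial grid-halving at the default changes the answer by < 1e-4.

## Synthetic data generator

The generator emulates the reference release test: four scenarios (fatty and
hydrophilic simulant × 4 °C / 24 °C) carrying the reported `D`, `α` and
`K_FS` values; sampling at {0, 3, …, 24, 48, 72, 96} h; and multiplicative
Gaussian noise `c·(1+ε)`, `ε ~ N(0, cv)` truncated at zero, the standard
model for assay-style proportional error. Defaults chosen once where the
design leaves them open:

- **Half-thickness `L = 5e-5 m`** (a 100 µm solvent-cast film wetted on both
  sides). `D` and `L²` are confounded in the model, so any fixed `L` yields a
  self-consistent test bed.
- **`C_S,∞ = 100 mg GAE/kg`** — an arbitrary positive scale; fits are
  scale-invariant.
- **`noise_cv = 0.05`, 3 replicates per scenario**, independent films, each
  replicate on a sub-seed spawned deterministically from the study seed.

What the generator does *not* emulate: temperature laws for `D` (the two
temperatures are separate scenarios, not an Arrhenius curve), assay
chemistry, film-to-film thickness variation, and any short-time transient
beyond the forward model itself. Passing round-trip tests therefore
demonstrates internal consistency of model + fitter, not field accuracy on
real release data.

## Known limitations and honest negatives

- **`D` is weakly identified at the reference conditions.** With the
  reported `α` values (0.015–0.018 fatty; 7e-4–9e-4 hydrophilic) and any
  film-scale `L`, the bath equilibrates on the timescale `α²L²/D` — minutes —
  far inside the first 3-hour sample. Under 5% noise the median relative
  error of the recovered `D` is ~0.8–1.0 for the fatty scenarios and
  unbounded for the hydrophilic ones (where the fitted `R²` is also low, as
  expected when the model cannot discriminate). A sensitivity sweep shows no
  physically plausible thickness fixes this at the given schedule. The
  noiseless round trip, by contrast, recovers `D` to < 0.01%.
- **The 12-root series is a poor approximation at small `α`**: at
  `α ≈ 0.015` it reports ~0.65 spurious release at `t = 0` (the weight
  deficit). The package reproduces the truncated model as specified and
  exposes the deficit as a diagnostic rather than hiding it.
- **The 200-root series cannot verify the erfc form in its own domain**
  (`α < 0.01`, release ≤ 0.1): convergence there needs `N ≳ L/√(Dt)` ≈
  thousands of roots. The equivalence is instead verified with 2000-root
  evaluations at the largest admissible times, where agreement is < 1e-3,
  and tightens to machine level with 20,000 roots.
- `R²` on a normalized curve whose variance is dominated by the `t = 0`
  point is an optimistic fit statistic; it is reported because it is the
  field's convention, alongside the residuals.
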