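# filmrelease

Release-kinetics modelling of an antioxidant migrating from a polymer
food-packaging film into a liquid food simulant of finite volume.

Active films (here: a zein/gellan-gum film carrying rosemary oleoresin,
quantified as gallic-acid equivalents, GAE) protect food by slowly releasing
an antioxidant into the product. Designing such a film requires the
diffusion coefficient `D` of the antioxidant in the film matrix, estimated
by fitting a transport model to a measured release curve. This package
provides the forward models, the fitting machinery, an independent numerical
oracle, and a synthetic-data generator that emulates a standard release test
(fatty 95%-ethanol and hydrophilic 10%-ethanol simulants, at 4 °C and 24 °C,
sampled every 3 h for a day and then daily for three days).

## Model

A plane sheet of half-thickness `L`, uniformly loaded, releases into a
well-stirred simulant of finite volume. With the volume ratio
`α = V_S / (K_FS · V_F)` (where `K_FS = C_F,∞ / C_S,∞` is the film–simulant
partition coefficient), the normalized simulant concentration is

    C_S(t) / C_S,∞ = 1 − Σₙ [ 2α(1+α) / (1 + α + α² qₙ²) ] · exp(−D qₙ² t / L²)

with eigenvalues `qₙ` the positive roots of `tan(q) = −α q` (the k-th root
lies in `((k−½)π, kπ)`). By default 12 roots are retained. For very low
migration (`α < 0.01`) the series converges too slowly at practical
truncations and the short-time form

    C_S(t) / C_S,∞ = (1+α) · [ 1 − e^ω · erfc(√ω) ],   ω = D t / (α² L²)

is used instead (evaluated through the scaled complementary error function,
so large `ω` cannot overflow). `D` is estimated by a deterministic bounded
search over `log₁₀ D ∈ [−18, −8]` minimizing the sum of squared residuals of
the normalized curve, with goodness of fit `R² = 1 − SS_res/SS_tot`. A
conservative finite-volume solver for the underlying PDE (Fick's second law
with a partition boundary condition and a finite-bath mass balance) serves
as an independent cross-check of the analytical forms.

## Worked example

```python
import numpy as np
from filmrelease import (REFERENCE_SCENARIOS, DiffusionEstimator,
                         generate_release_curve, scenario_geometry)

sc = REFERENCE_SCENARIOS["fatty_24C"]          # D_true = 21.140e-14 m^2/s
curve = generate_release_curve(sc, seed=42)    # noisy synthetic release test

est = DiffusionEstimator(geometry=scenario_geometry(sc),
                         alpha=sc.alpha_true, C_S_inf=sc.C_S_inf)
est.fit(curve.times, curve.concentrations)
print(f"D = {est.D_ * 1e14:.3f} x 10^-14 m^2/s "
      f"({est.model_used_.value} model, R^2 = {est.r_squared_:.3f})")
```

prints

```
D = 0.725 x 10^-14 m^2/s (series model, R^2 = 0.831)
```

The fitted `D` is far from the generating value and `R²` is low: at this
scenario's volume ratio (α ≈ 0.018) the film–simulant system equilibrates
well before the first 3-hour sample, so a noisy curve carries almost no
information about `D`. The noiseless round trip recovers the generating
value to better than 0.01% (see the test suite); quantifying this
identifiability gap honestly is part of what the package is for.

The same pipeline is scriptable from the shell:

```sh
filmrelease simulate --seed 9 --scenario fatty_24C --out curves.csv
filmrelease fit --input curves.csv --alpha 0.0181 --out report.csv
filmrelease validate            # series vs PDE-oracle agreement
```

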