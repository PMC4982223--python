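# gliodiff

Deterministic and stochastic modeling of drug-induced glioma
differentiation: how signaling noise reshapes the response of a glioma
cell population to a differentiation-inducing drug.

## The problem

Cholera toxin (CT) and other cAMP elevators can drive glioma cells to
differentiate into astrocyte-like cells. The decision runs through a
small signaling network: CT activates PKA, which phosphorylates CREB,
inhibits PI3K/AKT (thereby activating GSK3β and triggering cyclin D1
degradation), and switches on the IL6/JAK2/STAT3 axis. The
differentiation marker GFAP rises only once cyclin D1 — which sustains
itself through a Hill-type positive feedback loop — has been degraded.
That feedback loop makes the cyclin D1 subsystem a bistable "one-way
switch", and the drug response of the whole network ultrasensitive:
nothing happens below a threshold dose, and full commitment just above
it.

`gliodiff` implements this ten-species model (PKA, CREB, PI3K, AKT,
pGSK3β, IL6, JAK2, STAT3, cyclin D1, GFAP; time in hours, activation
levels normalized, CT in ng/ml) in three regimes:

* **ODE** — the deterministic rate equations;
* **ANM** — an additive-noise SDE, `dY = F(t,Y) dt + σ dW`, with a
  per-species noise amplitude quoted as a percentage of signal range;
* **CLE** — a chemical Langevin equation whose noise terms are square
  roots of the 20 production/degradation channel rates scaled by
  `1/√V` (intrinsic noise, `V` = molecules per protein pool), plus
  extrinsic variability that rescales every kinetic parameter as
  `P_j (1 + λ ε)`.

Both SDE regimes are integrated with full-truncation Euler–Maruyama.

On top of the simulators sit the analyses:

* **Ultrasensitivity** — the apparent Hill coefficient
  `H = ln 81 / ln(EC90/EC10)` of the 48-h dose response, with EC
  quantiles refined by bisection against the ODE (switch-like curves
  with `H ≈ 40` have `EC90/EC10 ≈ 1.12` and cannot be resolved on a
  fixed dose grid);
* **Parameter sensitivity** — time-averaged relative GFAP sensitivities
  `S_ij = Σ|S_ij(t_l)|/L` under +5% perturbations of each of the 39
  kinetic constants;
* **Differentiation potential** — `D(t) = ∫ u(x) p_GFAP(x,t) dx`, the
  fraction of cells whose GFAP exceeds the threshold `x_c = 0.8`,
  estimated as an indicator mean over simulated cell ensembles;
* **Interventions** — cyclin D1 feedback inhibition (scaling K6a, n2 or
  V6) and its effect on `D` across a 2-D grid of intrinsic × extrinsic
  noise strengths.

## Worked example

```python
import numpy as np
from gliodiff import (
    default_parameters, basal_steady_state, dose_response,
    ec_quantile, apparent_hill, ANMNoiseSpec,
)
from gliodiff.population import potential_series

params = default_parameters()
resting = basal_steady_state(params)

# 48-h dose response of the differentiation marker
doses = np.unique(np.r_[np.linspace(0, 10, 21), np.linspace(5.5, 7.5, 41)])
curve = dose_response(params, doses, "GFAP", t_read=48.0, initial=resting)
print(f"EC10 = {ec_quantile(curve, 0.1):.2f} ng/ml")
print(f"EC90 = {ec_quantile(curve, 0.9):.2f} ng/ml")
print(f"apparent Hill coefficient H = {apparent_hill(curve):.1f}")

# differentiation potential of a noisy population, CT = 10 ng/ml
for pct in (0.1, 10.0):
    series = potential_series(
        "anm", params, 10.0, ANMNoiseSpec(percent=pct), 48.0,
        cells_per_replicate=100, replicates=20, seed=2024,
    )
    mean, sd = series.at(48.0)
    print(f"sigma = {pct:>4}%:  D(48 h) = {mean:.3f} +/- {sd:.3f}")
```

prints

```
EC10 = 6.11 ng/ml
EC90 = 6.78 ng/ml
apparent Hill coefficient H = 42.4
sigma =  0.1%:  D(48 h) = 1.000 +/- 0.000
sigma = 10.0%:  D(48 h) = 0.630 +/- 0.047
```

The GFAP response switches inside a 6–7 ng/ml dose window with an
apparent Hill coefficient in the low forties — far steeper than any
plausible single binding step, the signature of the bistable cyclin D1
switch. At 48 h, a quiet population (σ = 0.1%) differentiates
completely, while 10% additive noise leaves over a third of the cells
undifferentiated: noise itself degrades drug efficacy.

A command-line interface mirrors the library
(`gliodiff simulate-ode`, `dose-response`, `sensitivity`,
`simulate-anm`, `simulate-cle`, `potential`, `intervene`, `calibrate`,
`preset <name>`); see `gliodiff --help`.

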