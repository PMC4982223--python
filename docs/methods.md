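# Methods

## Model

Ten species in fixed order — PKA, CREB, PI3K, AKT, pGSK3β, IL6, JAK2,
STAT3, cyclin D1, GFAP — evolve under mass-action degradation and
Michaelis–Menten/Hill production terms. The drug input CT (ng/ml)
drives PKA through `a1 + V1·CT^n1/(K1 + CT^n1)`; PKA activates CREB and
IL6→JAK2→STAT3, and represses PI3K through `1/(1 + PKA/K3)`. AKT
phosphorylates GSK3β; the active pool is the difference
`aGSK3β = GSK3βT − pGSK3β` (nowhere else defined, so the package fixes
this identity). Cyclin D1 obeys

    d[CD]/dt = V6·CD^n2/(K6a^n2 + CD^n2) − d6·(aGSK3β/(K6b+aGSK3β))·CD,

a positive-feedback birth term against a degradation slope
`g = d6·aGSK3β/(K6b+aGSK3β)` controlled from upstream. GFAP production
is gated by `f0 = ((C − CD)/C)^+`: the differentiation program can only
run once cyclin D1 falls below the ceiling C. Two denominator
conventions coexist deliberately: the feedback term uses `K^n + S^n`,
while the CT input and the aGSK3β→GFAP term use `K + S^n` (K then
carries the units of `S^n`).

With Hill exponent n2 > 1 the cyclin D1 subsystem has a stable root at
0 and, for `g` below a fold threshold `g* ∝ V6/K6a`, a second stable
root — the one-way switch. The untreated cell rests on the high branch;
the drug raises `g` through `g*`, the high state disappears, cyclin D1
collapses, the gate opens, GFAP rises.

## Default parameters and calibration

The 39 kinetic constants shipped as defaults were produced by an
anchor-based calibration (`gliodiff.synthetic.calibrate_default_parameters`),
not by fitting raw data. Anchors: apparent Hill coefficients ≈ 40
(cyclin D1) and ≈ 43 (GFAP) for the 48-h dose response; GFAP's
normalized EC10 ≥ 6 and EC90 ≤ 7 ng/ml; bistable cyclin D1 at CT = 0;
monostable-low at CT = 10 ng/ml. The measured defaults give
H(cyclin D1) = 42.5, H(GFAP) = 42.4, EC10 = 6.11, EC90 = 6.78 ng/ml.

Design choices behind the calibrated structure, made on mechanism:

* **Basal degradation sits at ~0.95·g\*.** This keeps the pre-threshold
  decline of the high cyclin D1 branch (which sets EC10) inside the
  6 ng/ml boundary while preserving a comfortable bistable basin.
* **The dose→degradation map is a power-law foot**: n1 = 5 with the
  input half-point far above the working range (K1^(1/n1) ≈ 13 ng/ml),
  so `g(CT)` accelerates through 6–10 ng/ml. A saturating input would
  stall the collapse just above threshold and push EC90 past 7.
* **A slow cyclin clock (V6 = 0.4 h⁻¹)** spreads collapse times across
  the 6.3–6.9 ng/ml band so the 48-h read-out resolves the window; at
  10 ng/ml the switch completes in roughly 20 h.
* **GFAP production arms are dose-saturated** (small K2, K10a, K10b,
  K10c): above threshold the response is set by the cyclin D1 gate
  alone, which is what makes both species' apparent Hill coefficients
  nearly equal.
* **The gate ceiling C sits ~12% above the basal cyclin D1 state**,
  giving a small nonzero basal GFAP. An exact knife-edge (C equal to
  the basal state) makes the relative sensitivity of GFAP to C
  divergent and is not biologically meaningful.
* **The AKT→GSK3β transfer operates in its linear regime (K5 = 5)**, so
  perturbations of the total pool GSK3βT propagate proportionally
  rather than with leverage; the pool size is a conserved quantity, not
  a kinetic knob, and should not masquerade as the top sensitivity.
* **GFAP settles near 0.9 at saturating dose**, above the
  differentiation threshold x_c = 0.8 with a finite margin, so that
  realistic noise amplitudes move a measurable fraction of cells across
  the threshold. A large margin would make the potential insensitive to
  any noise; no margin would destroy differentiation entirely.

A supplement-style parameter file (flat YAML/JSON with the 39 symbol
names) and an initial-state file can be loaded verbatim and take
precedence over the calibrated set.

## Stochastic regimes

**ANM.** Euler–Maruyama on `dY = F dt + σ dW`, per-species amplitude
`σ_k = (p/100)·scale_k` with reference scale 1 (species are
normalized); scales are overridable. Default dt = 0.01 h. Negative
excursions are clamped to zero after every step (concentrations cannot
be negative) and pGSK3β is capped at the total pool; clamp events are
counted and reported on the ensemble.

**CLE.** Each equation splits into production and degradation channels
(their difference equals the deterministic drift to machine precision —
tested). The noise term per species is
`(1/√V)(√prod·ξ₁ − √deg·ξ₂)√dt` with independent standard normals per
channel and step. Square-root arguments are clamped at zero. The GFAP
degradation noise uses `√(d10·GFAP)` like every other channel; a
`verbatim_gfap_noise` flag reproduces, for comparison, a variant with
the noise proportional to `d10·GFAP` itself.

**Extrinsic noise.** Every parameter is rescaled `P_j(1 + λ ε)`,
ε ~ N(0,1) independently across the 39 slots; rates are clamped at 0,
Hill exponents at 1, pool sizes at a small positive floor. The default
mode draws ε **once per trajectory** (static): a per-step redraw
contributes only O(λ√dt) to the integrated dynamics and vanishes in the
dt → 0 limit, so only persistent cell-to-cell variability can produce
the extrinsic-noise effects the analyses measure. White (per-step) mode
remains available and demonstrably produces ~no endpoint spread
(tested).

**Seeding.** Ensembles are vectorized across cells, but every cell owns
an independent generator spawned from the master seed, so a cell's law
does not depend on ensemble size, and runs are bit-reproducible.

## Analyses

**EC quantiles and apparent Hill.** Responses at 48 h are normalized
between the zero-dose baseline and the extreme response of the sweep
(decreasing curves as fractional decrease — the standard convention).
Quantiles are bracketed on the dose grid and refined by bisection
against fresh ODE solves to a dose tolerance of 0.001 ng/ml; a
non-monotone normalized response beyond tolerance is refused rather
than silently interpolated. `H = ln 81/ln(EC90/EC10)` recovers the
exponent of exact Hill curves to 0.1% (property-tested) and equals 2
exactly for a linear ramp.

**Sensitivity.** One-sided +5% perturbations (central differences
behind a flag), relative finite differences on an L = 100 point grid
over 48 h, averaged as Σ|S(t_l)|/L; grid points where the baseline
output is below 1e−9 are masked and their count reported. The default
evaluation dose is 6.5 ng/ml, inside the switch window: at a saturating
dose every cell differentiates regardless of ±5% parameter changes and
the ranking degenerates, while near threshold the cyclin D1 feedback
parameters dominate (shipped defaults: d6 first, K6a second, with the
conserved pool GSK3βT third). A stochastic (ANM-based) mode with
repeats and across-repeat mean/sd is available.

**Differentiation potential.** D(t) is the fraction of cells with
GFAP strictly above x_c = 0.8. The indicator mean is exact for the
empirical measure, so no density estimate enters the statistic;
histograms/KDE are display-only. Replicated series simulate independent
finite ensembles (default 20 replicates × 100 cells, matching repeated
finite-population experiments) and report per-replicate curves, mean
and sd.

**Interventions.** Feedback inhibition multiplies K6a (up) or n2/V6
(down); "0.2-fold decrease" is read as ×0.2. An n2 intervention that
would push the Hill exponent below 1 is warned about and clamped. The
noise-grid scan evaluates D(48 h) over a log grid of intrinsic
(1/√V) × extrinsic (λ) strengths from 1e−3 to 1e−1, wild-type versus
K6a×10, with common random numbers across the two surfaces.

## Synthetic data

The generator emulates quantified 48-h dose-response observations:
model read-outs plus i.i.d. Gaussian observation noise truncated at
zero (no error model is claimed for real immunoblot data). It does not
emulate dose-dependent error, replicate correlation structure, or
measurement saturation — recovery tests on it therefore show
identifiability of the model's parameters from ideal data, not
robustness to real assay artifacts. Parameter fitting is bounded
least squares over a chosen free subset; the recovery test
demonstrates that the sensitive pair (K6a, d6) is identifiable to 1%
from noiseless data starting ±20% off.

## Numerical choices and problem sizes

LSODA with rtol 1e−8/atol 1e−10 for ODE work (the fold region is
locally stiff); steady states by long integration to drift norm
< 1e−9, with the feed-forward upstream settled before placing cyclin D1
on its high branch (otherwise the equilibration transient spuriously
fires the switch). Root scanning uses a dense sign-change sweep plus
bisection and is cross-checked against brute-force enumeration on
randomized parameters. The test and acceptance runs use 20 × 100-cell
ANM ensembles per noise level, 4 × 4 noise grids with 3 × 100-cell
replicates per point, and dt = 0.01 h — sizes chosen so the full
analysis reruns in minutes on a single core while keeping Monte-Carlo
standard errors on D below ~0.05.

## Limitations

* The default parameter set is a calibrated construction reproducing
  the system's documented dose-response and switch behavior; individual
  rate constants are not measurements.
* No transcription/mRNA layer (cyclin D1 regulation is treated as
  post-translational) and no spatial effects.
* The CLE uses a single shared system size V for all species
  (per-species V is a config extension, off by default); no exact
  stochastic simulation (Gillespie) or higher-order SDE schemes.
* Full-truncation clamping introduces a small boundary bias at strong
  noise; clamp counts are logged so affected runs are identifiable.
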