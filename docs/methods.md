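# Methods

## The exchange model

The core model is a reversible ligand-exchange scheme at a single binding
site,

    M(X) + Py   ⇌  M(Py)     (k_on, k_off)
    M(X) + PyL  ⇌  M(PyL)    (same k_on, k_off)

with three assumptions:

1. **No kinetic isotope effect.** The labelled and unlabelled ligand share
   `k_on` and `k_off`. The label (ring deuteration) is remote from the donor
   atom, so this is chemically safe, and it is what makes the relative signal
   a clean kinetic observable.
2. **Well-mixed, explicitly depleted ligand pools.** Free-ligand
   concentrations change as the host binds and releases. This is what lets
   the simulator address small-excess regimes, where the textbook analytic
   solution does not apply. Writing B for bound and F for free ligand, the
   relaxation rate of the label composition of the bound pool is
   `k_off·(1 + B/F)`; the familiar `k_MS = k_off` is the F ≫ B limit.
3. **Mechanism-agnostic first step.** The scheme does not distinguish
   dissociative from associative substitution; only the dissociation rate is
   identified at large excess.

The host is assumed pre-equilibrated with the unlabelled ligand before the
observation window (phase I at steady state); the initial condition is the
exact 1:1-binding quadratic root rather than a burn-in integration. The
labelled pool steps up instantaneously at `t_L`. A `mixing_tau` parameter
(default 0 s) feeds the label in exponentially instead, for instruments where
the addition dead time is not negligible; it is off by default because the
experiments the package targets resolve rates well below the mixing
timescale.

**Numerics.** `scipy.integrate.solve_ivp` with LSODA, relative tolerance
1e-8, absolute tolerance 1e-12 × host concentration. The problem is stiff:
`k_on·[Py]` (tens per second) and `k_off` (1e-4 per second) differ by ~5–8
orders of magnitude. Integration is piecewise across addition events so the
concentration steps are exact. Host mass balance is checked to 1e-9 relative
at every output point and raises on violation.

## Two-site (bis-ligand) complexes

Hosts with an inner (cavity) and an outer site are modelled with 9 explicit
complex states (each site vacant/unlabelled/labelled) plus the two pools, so
both `k_on` and `k_off` of each site are honoured and vacancies are not
assumed away. Sites exchange independently and draw from the same pools; the
pre-equilibrium is solved as a self-consistent independent-site occupancy
(Brent root find on the free-ligand concentration).

The observable classes are the fully occupied label combinations PP, PL
(both mixed states summed — they are isobaric), LL. At equal pool fractions
the equilibrium is binomial (0.25/0.50/0.25 at f_label = 0.5).

Renormalizing PP and LL together (excluding PL) isolates the slow inner-site
exchange when the outer site is much faster: once the outer site has
equilibrated, PP/(PP+LL) equals the inner-site unlabelled fraction exactly,
and a first-order fit recovers the inner `k_off`. This identity holds **only**
in that separated-timescale regime. For comparable site rates the renormalized
trace is provably not single-exponential (with per-site unlabelled fraction
x(t), PP/(PP+LL) − ½ = e^(−kt)/(1+e^(−2kt)) at equal rates, and a constrained
first-order fit biases low by ~40%); the package therefore makes no rate
claim there, and the tests pin the correct product-form behaviour instead.

## The DRL observable and the fit

Within a host group the fractions are intensity/(group total) per time point.
For a two-species group the two fractions are exact complements; both are fit
globally with shared parameters,

    p_unlab(t) = (1 − f_eq) + f_eq · exp(−k·(t − t_L)),  p_lab = 1 − p_unlab,

which is symmetric in the isotopologues and pins p(t_L) = 1. Defaults: `f_eq`
fixed to the known labelled fraction of the stock (floatable for imperfect
ratios), `t_L` from metadata (floatable on request). Optimization is
Levenberg–Marquardt (lmfit), rate bounded at 0, starting value from a
half-decay heuristic.

**Standard errors.** Because the two fractions of a group are exact
complements, the second trace duplicates every residual with opposite sign:
it symmetrizes the fit but adds no information, and the naive least-squares
covariance is deflated by exactly 2. The reported `stderr` multiplies the
optimizer's value by √2 whenever the fitted traces sum identically to 1,
restoring calibrated intervals (validated by simulation: ~95% coverage at
nominal 95%).

**Degenerate data.** Post-addition traces with peak-to-peak amplitude below
1e-6 raise a `DegenerateDataError` (rate unidentifiable) instead of returning
an arbitrary number. In competitive (multi-host) fits each host is fitted
independently with the shared time base; failures are collected per host and
do not abort the rest.

**Quantitation envelope.** Rates above 0.5 s⁻¹ are flagged `too_fast`: such
exchanges complete during labelled-ligand addition and infusion, so the fit
is qualitative. Independently, fits whose sampling starts later than ~1/k
after `t_L` (fewer than 3 points inside the first 1/k) are flagged
`undersampled` — a sampling problem, not a magnitude problem.

## Synthetic data

The generator emulates what the detector sees: intensity =
scale × response factor × concentration (response factor defaults to 1;
isotopologues ionize identically), degraded by

- a **common-mode spray factor** per time point, lognormal with unit mean
  (default relative SD 0.10, typical ESI infusion stability), shared by all
  species — which is exactly why it cancels in the relative observable;
- **additive baseline noise** (absolute units, detector floor at zero);
- optional **shot noise** with variance ∝ intensity.

All randomness flows from one `numpy` Generator seeded by the `NoiseModel`,
so datasets are bit-reproducible. Isotope envelopes are computed at nominal
(unit) mass resolution by per-element multinomial convolution of a fixed
published abundance table compiled into the package (reproducibility over
configurability); deuteration is an explicit `D` element, with no H/D
scrambling. Fine isotopic structure is deliberately not modelled — envelope
overlap at Δm = 5 (a light ion's M+5 line under the D5 partner's
monoisotopic peak) is all the workflow needs, and the overlap correction
solves the resulting diagonally-dominant mixing system by non-negative least
squares per time point.

What the generator does **not** emulate: profile-mode peak shapes, detector
saturation, retention/mobility structure, slow sensitivity drift that is not
common-mode, and chemical interference beyond optional channel cross-talk (a
fixed fraction of a bis-complex channel moved into a 1:1 channel, standing in
for post-IMS fragmentation). Passing the recovery tests therefore shows the
estimator chain is correct and calibrated under these noise classes, not that
every real-instrument artefact is survivable.

## Eyring analysis

Linear regression of ln(k/T) on 1/T; ΔH‡ = −slope·R, ΔS‡ = R·(intercept −
ln(k_B/h)). Constants are CODATA-2018 exact values with
R = 1.98720425864083 cal mol⁻¹ K⁻¹, so outputs are bit-reproducible. Reports
keep the field's mixed units (kcal for ΔH‡/ΔG‡, cal for ΔS‡); computation is
in cal throughout. When every point carries a replicate SD the fit is
inverse-variance weighted after a delta-method transform
(var[ln(k/T)] = (sd/k)²) and the parameter covariance is the unscaled
(AᵀWA)⁻¹; otherwise ordinary least squares with residual-variance scaling.
Uncertainties are 1·SE; ΔG‡(T) propagates the full 2×2 covariance and is
most precise near the (harmonic) mean experimental temperature. The inverse,
k(T) = (k_B·T/h)·exp(−ΔG‡/RT) with transmission coefficient 1, has its
exponent clipped at ±600 to degrade gracefully for absurd parameters.

## Problem sizes and default grids

`predict_kms` samples 1 point/s over 5/k_off after `t_L` and fits only
post-addition points — dense enough that discretization contributes < 0.1%
at the rates of interest. The simulation-based recovery study in the test
suite uses 600 points over 5/k_off with 10% drift and 1% full-scale additive
noise, 100 seeds in the acceptance tier and 25 in the unit tier; these sizes
resolve a 5% accuracy question with comfortable margin while keeping the
whole suite in a few seconds.

A deliberate interpretation in the recovery study: the estimand of the
first-order fit is `k_MS`, which at 100+100 equivalents sits ~0.5% above
`k_off` (the finite-excess `1 + B/F` factor the model itself predicts).
Accuracy is asserted against true `k_off` (bias ≪ the 5% band), but
confidence-interval coverage is assessed against the noise-free `k_MS` for
the same conditions — coverage of an interval is a statement about its
estimand, and mixing in the pseudo-first-order approximation error would
conflate two different error sources.

## Known limitations

- Association rates are not extractable from large-excess DRL data (the
  observable is insensitive to `k_on` by design); the package does not offer
  small-excess mechanistic fitting of `k_on`.
- Trans-ligand effects (different outer ligands modulating the inner rate)
  are not parameterized; measured rates in mixed-speciation samples are
  averages.
- The mzML reader expects centroided spectra; there is no mzML writer
  (peak-list CSV is the interchange format).
- The quantitation limit is a protocol constant, not derived from the
  configured mixing time.
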