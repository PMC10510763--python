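# drlkit

Delayed reactant labelling (DRL) is a mass-spectrometric way to measure
solution-phase ligand-exchange kinetics: a metal complex is pre-equilibrated
with its ligand, an isotopologue of that ligand (e.g. pyridine-D5) is added
after a delay, and the relative ESI-MS intensities of the labelled and
unlabelled complexes are followed in time. Because the isotopologues ionize
identically, the normalized intensity ratio tracks the solution
concentrations directly; the exchange appears as an exponential approach to a
plateau set by the labelled fraction of the ligand pool.

`drlkit` is a toolkit for everyone who runs or models such experiments
(coordination and host–guest chemists, MS method developers). It covers the
whole workflow:

- **kinetics** — mechanistic simulation of the exchange scheme
  `M(X) + Py ⇌ M(Py)` (association `k_on`, dissociation `k_off`) with explicit
  free-ligand pools, a two-site variant for bis-ligand complexes with
  inequivalent sites, and prediction of the MS-observed rate `k_MS` for any
  concentration regime;
- **synthetic** — realistic noisy datasets from known ground truth
  (common-mode spray drift, additive/shot noise, nominal-mass isotope
  envelopes, centroided peak-list rendering);
- **traces** — XIC extraction, isotope-envelope overlap correction
  (non-negative unmixing), within-group normalization, and the bis-complex
  renormalization that isolates the slow cavity-site exchange;
- **fitting** — global pseudo-first-order fits of both complementary
  fractions with shared parameters, competitive multi-host fitting, and
  quantitation-limit checks (default ceiling 0.5 s⁻¹);
- **eyring** — activation parameters ΔH‡, ΔS‡ (with covariance) from
  temperature-resolved rates via ln(k/T) vs 1/T regression, and ΔG‡(T) with
  propagated uncertainty.

Under pseudo-first-order conditions (large ligand excess) the unlabelled
bound fraction follows

    p(t) = (1 − f_label) + f_label · exp(−k_MS · (t − t_L)),

and `k_MS = k_off` exactly in the infinite-excess limit. At finite excess the
model predicts `k_MS = k_off · (1 + B/F)` (bound over free ligand pool), the
inverse concentration dependence the mechanistic simulator reproduces.

The fitting and Eyring components are scikit-learn style estimators
(`FirstOrderExchange`, `EyringRegression`) and compose with sklearn
pipelines; the functional wrappers (`fit_first_order`, `eyring_fit`, …) are
one-liners over them.

## Worked example

```python
from drlkit import (RateConstants, scan_kms_vs_equivalents,
                    ActivationParameters, RateAtTemperature,
                    eyring_rate, eyring_fit, gibbs_at)

rates = RateConstants(k_on=5.0e4, k_off=5.4e-4)
print(scan_kms_vs_equivalents(rates, [5, 25, 100, 200, 1000]).to_string(index=False))
```

```
 equivalents     k_ms       stderr
           5 0.000675 3.937544e-09
          25 0.000563 2.979058e-10
         100 0.000545 6.382500e-11
         200 0.000543 3.121275e-11
        1000 0.000541 6.243909e-12
```

`k_MS` falls monotonically with ligand excess and levels off at `k_off`
(5.4 × 10⁻⁴ s⁻¹): with 100+ equivalents the fitted MS rate *is* the solution
dissociation rate constant to better than 1%, which is why quantitative DRL
runs use a large excess.

```python
truth = ActivationParameters(dH=39.1, dS=58.2)   # kcal/mol, cal/mol/K
points = [RateAtTemperature(T, eyring_rate(truth, T)) for T in (303.15, 308.15, 313.15)]
fit = eyring_fit(points)
dg, _ = gibbs_at(fit, 298.15)
print(f"dH = {fit.dH:.4f} kcal/mol, dS = {fit.dS:.4f} cal/mol/K, "
      f"dG(298.15 K) = {dg:.4f} kcal/mol")
```

```
dH = 39.1000 kcal/mol, dS = 58.2000 cal/mol/K, dG(298.15 K) = 21.7477 kcal/mol
```

A dissociative exchange shows up as a large positive ΔS‡; ΔG‡ ≈ 21.7 kcal/mol
at 25 °C corresponds to a dissociation half-life of tens of minutes.

## Command line

```bash
drl simulate config.yaml -o rundir --seed 1   # synthetic dataset + truth sidecar
drl extract  config.yaml peaks.csv -o traces.csv
drl fit      config.yaml traces.csv -o report.json
drl eyring   rates.csv -o eyring.json
drl scan     config.yaml -e 5,25,100,200 -o scan.csv
```

Exit codes: 0 success, 2 validation error, 3 numerical failure. See
`src/drlkit/config.py` for the YAML schema.

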