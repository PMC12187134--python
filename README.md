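# lc8bridge

Quantitative models of how the dynein light chain LC8 cross-links the
C-terminal region of 53BP1 into higher-order assemblies. 53BP1's
oligomerization domain forms a trimer, and each chain carries up to three
LC8-recognition (QT) motifs; an LC8 homodimer binds two client chains in
its two symmetric grooves, either within one trimer (*intratrimer*) or
across two trimers (*bridging*), producing a dimer-of-trimers. The package
is for structural biochemists analyzing isothermal titration calorimetry
(ITC) and SEC-MALS data on such multivalent hub–client systems, and for
anyone who wants a tested, self-contained implementation of the underlying
binding models.

It provides:

- **Forward ITC models** — per-injection heats for the one-set-of-sites
  (Wiseman) model,
  `Q = (n·M_t·ΔH·V₀/2)·[1 + r + s − √((1+r+s)² − 4r)]` with
  `r = X_t/(n·M_t)`, `s = 1/(n·K_a·M_t)`, and for a three-event
  sequential-binding-sites model of the bridged hexamer evaluated through
  its binding polynomial, in both titration directions.
- **Inverse fitting** — least-squares estimation of (N, K_d, ΔH) and of the
  constrained sequential parameters (k₁ = k₂, h₁ = h₂, k₁ > k₃, h₁ < h₃ via
  smooth reparametrization), with standard errors, derived
  ΔG = RT·ln K_d and −TΔS = ΔG − ΔH, and inverse-variance aggregation of
  replicates: ŷ = Σ(yᵢ/σᵢ²)/Σ(1/σᵢ²), σ̂ = 1/Σ(1/σᵢ²).
- **Mass bookkeeping** — expected masses of every trimer/bridged complex
  (1:q and 2:3q stoichiometries) and nearest-composition assignment for
  measured SEC-MALS masses.
- **Mass-action speciation** — equilibrium populations of free trimer,
  trimer complexes and partially-to-fully bridged dimer-of-trimers from two
  per-event dissociation constants, with weight fractions and
  weight-average mass for interpreting SEC-MALS/AUC observations.
- **Synthetic data** — seeded VP-ITC-like titration generator with known
  ground truth, so every stage is testable without instrument files.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Generate three noisy replicates of a QT2-like titration (N = 1.2,
K_d = 1.2 µM, ΔH = −10.6 kcal/mol; 20 µM cell, 300 µM syringe, 28 × 10 µL),
fit each, and aggregate:

```python
from lc8bridge import (ThermoParams, SyntheticSpec, make_schedule,
                       gen_replicates, fit_oss, aggregate_inverse_variance)

truth = ThermoParams(n_sites=1.2, kd=1.2e-6, dh=-10.6)
spec = SyntheticSpec(truth, make_schedule(20e-6, 300e-6),
                     noise_sigma=0.1, n_replicates=3, seed=7)
fits = [fit_oss(iso) for iso in gen_replicates(spec)]
kd, err = aggregate_inverse_variance(
    [f.params["kd"] * 1e6 for f in fits],
    [f.std_errors["kd"] * 1e6 for f in fits], conventional=True)
print(f"Kd = {kd:.3f} +/- {err:.3f} uM")
```

prints

```
Kd = 1.212 +/- 0.008 uM
```

— the aggregated dissociation constant in µM with its weighted standard
error, recovering the generating 1.2 µM from 0.1 µcal-noise data. The
scripts in `examples/` walk through each capability the same way
(expected-mass tables, two-phase vs sigmoidal isotherm shapes, the
constrained sequential fit recovering the 0.3 µM intratrimer / 1.1 µM
bridging affinity pair, and speciation along an LC8 titration); each
prints its results with a line on what they mean.

A thin CLI wraps the same functions:

```sh
lc8bridge masses --q all              # expected complex masses per q
lc8bridge simulate-itc --preset qt2-od --replicates 3 --seed 7 --out sim
lc8bridge fit-itc sim.rep1.tsv --model oss
lc8bridge speciate --q 3 --total-lc8-um 40
lc8bridge run --config pipeline.yaml --out report.json
```

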