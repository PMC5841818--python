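# fuelswitch

Thermodynamically constrained modeling of whole-body fuel selection during
exercise: why can some phenotypes keep burning fat as work intensifies while
others switch to carbohydrate and exhaust early?

`fuelswitch` implements a compartmentalized model of central catabolism —
glycolysis, the glycerol-3-phosphate shuttle, the TCA cycle, mitochondrial
fatty-acid transport and the β-oxidation spiral, oxidative phosphorylation
and the bioenergetic buffers — with **98 species and 87 reactions** across
extracellular, cytosolic and mitochondrial compartments. It is aimed at
systems physiologists studying substrate selection (the high- vs
low-capacity runner phenotypes being the motivating contrast), and at
anyone who wants a worked, tested example of combining constraint-based and
kinetic modeling under purely thermodynamic rate laws.

Two model layers share one network:

* **Constraint-based layer** — at each time point of a graded-exercise
  protocol, solve `S·J = 0` for all 87 fluxes with the six exchange
  columns pinned to measured boundary fluxes (O₂, CO₂, carbohydrate, FA),
  maximizing mitochondrial ATP production subject to loop-law constraints.
  The ATPase flux extracted from this solve, fitted to a polynomial in
  time, becomes the demand that drives the kinetic layer.
* **Kinetic layer** — a stiff 98-state ODE system
  `dC/dt = P⁻¹·S·J(C)` where every flux follows the generalized
  thermodynamic rate law

  ```
  J_k = X_k · Ct_k · (1 − e^{ΔG′_k/RT}) / (1 + e^{(ΔG′_k − ΔG′⁰_k)/RT}),
  Ct_k = Π C_i^μᵢ + Π C_i^νᵢ
  ```

  so mass balance and the second law are the only kinetic assumptions. The
  86 enzyme activities `X` (every reaction except the driven ATPase) are
  the adjustable parameters.

On top sit the analyses: hypothesis fitting (is the low-capacity phenotype
a mitochondrial-density deficit, an FA-oxidation deficit, or minimally
both?), parameter ensembles and activity-ratio distributions, sensitivity
ranking of fuel selection, normalized-exercise (%VO2max) protocols, and a
fatty-acid-oxidation capacity experiment. Everything runs on synthetic
data with known ground truth generated by the package itself — see
`docs/methods.md` for the model description and its limitations.

## Worked example

Build the canonical resting state, derive the exercise demand from the
constraint-based layer, and compare the two phenotypes:

```python
from fuelswitch.pipeline import build_reference_state, demand_curve_for, run_protocol
from fuelswitch.synthetic_data import HCR_LIKE, genotype_factor_map
from dataclasses import replace

ref = build_reference_state()                      # exact resting steady state
spec = replace(HCR_LIKE, noise_gas=0.0, noise_lactate=0.0)
demand, boundary, fluxes = demand_curve_for(ref, spec)

hcr = run_protocol(ref, demand, t_end=50.0)        # high-capacity phenotype
lcr = run_protocol(ref, demand, t_end=50.0,        # 50% mito, 5x FA-transport cut
                   factors=genotype_factor_map(ref.net, 0.5, 5.0))

print(f"HCR: {hcr.status}, RQ {hcr.rq[0]:.3f} -> {hcr.rq[-1]:.3f}, "
      f"JO2 {hcr.jo2[0]:.2e} -> {hcr.jo2[-1]:.2e} mol/min/kg")
print(f"LCR: {lcr.status} at t = {lcr.failure_time:.1f} min")
```

prints

```
HCR: ok, RQ 0.800 -> 0.794, JO2 9.49e-04 -> 4.44e-03 mol/min/kg
LCR: demand_not_met at t = 15.0 min
```

The high-capacity parameterization completes the 50-minute ramp with oxygen
uptake rising ~5-fold and the respiratory quotient holding near 0.8 (fat
oxidation sustained). The same demand applied to the low-capacity
parameterization — every mitochondrial capacity halved and the carnitine
shuttle cut a further 5-fold — shifts fuel use toward carbohydrate
(RQ → 1) and collapses at 15 minutes, just past that phenotype's 14-minute
exhaustion: the model's "unable to meet ATP demand" failure mode.

Fitting the three hypotheses to synthetic low-capacity observations
recovers the generating transform:

```
minimal_combined : error 0.93, mito_fraction 0.48, fa_transport_factor 5.0
fao_scale_only   : error 5.02
mito_scale_only  : error 58.1
```

— the combined minimal difference (density + transport) fits far better
than either single mechanism, and the recovered factors sit within a few
percent of the generating 0.5 and 5.0.

A CLI mirrors the stages (`fuelswitch synth | cba | simulate | fit |
sensitivity | capacity | protocol | all`); `fuelswitch all --out results/`
runs the scaled-down end-to-end pipeline and writes a checksummed artifact
manifest.

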