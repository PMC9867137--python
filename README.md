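# fractalpk

Fractal-kinetic compartment models and population pharmacokinetics in
Python.

Classical compartment PK assumes well-mixed (homogeneous) spaces, so every
transfer between pools is first-order with a constant rate coefficient.
Many real absorption and distribution processes — transdermal patches,
depot injections, drug trapped in heterogeneous tissue — violate that
assumption. Under fractal-like kinetics the rate coefficient becomes an
*instantaneous* rate that decays with time elapsed since dosing,

```
k(t) = θ / t^h ,      0 ≤ h ≤ 1,
```

where θ is the rate coefficient at elapsed time 1 and *h* is the
heterogeneity exponent; *h* = 0 recovers Fick-type (classical) kinetics.
`fractalpk` lets you place this exponent on any micro-constant of a 1- or
2-compartment model — absorption (Ka), elimination (Ke) or the
distribution rates (Kcp, Kpc) — and supplies everything needed to study
the consequences:

- **Simulation** — event-aware ODE integration (dose superposition, dose
  fractionation into fast/slow pathways, transit-chain absorption with
  Stirling's approximation, per-dose fractal-clock reset), plus the full
  sweep design (three model scenarios × three Ka/CL pairings × *h* from 0
  to 1 in steps of 0.05).
- **Population estimation** — log-normal inter-individual variability
  θᵢ = θ·exp(ηᵢ) with η ~ N(0, Ω), additive/proportional residual error,
  and a Laplace approximation of the marginal likelihood with interaction
  (the open equivalent of FOCEI), including saddle-point resets and
  parameter perturbation to confirm minima. The estimated *h* is
  constrained to [0, 1].
- **Synthetic populations** — a seeded generator that emulates sparse-to-
  rich longitudinal designs and emits NONMEM-dialect datasets
  (ID, TIME, AMT, DV, EVID, CMT, MDV).
- **Diagnostics** — OFV/AIC/AICc (`AIC = OFV + 2k`,
  `AICc = AIC + 2k(k+1)/(n−k−1)`), likelihood-ratio significance at the
  χ² 95th percentile (3.84 / 5.99 for 1 / 2 df), GOF residual tables
  (PRED/IPRED/IWRES/CWRES), prediction-corrected VPC and NPDE.

The estimation layer follows the scikit-learn estimator protocol
(`PopulationPKEstimator(...).fit(data)` with `theta_`, `ofv_`, `ebes_`,
… fitted attributes); `fit`, `robustify` and `generate_population` are
functional wrappers.

## Worked example

```python
import numpy as np
from fractalpk import (DoseEvent, ModelSpec, PKParameters, simulate_profile,
                       detect_regimes, criteria, lrt_significant)

params = PKParameters(Ka=0.3, CL=0.033, V1=10.0)
times = np.arange(0.0, 400.5, 0.5)
dose = [DoseEvent(time=0.0, amount=100.0)]

classical = simulate_profile(ModelSpec(n_compartments=1), params, dose, times)
fractal = simulate_profile(
    ModelSpec(n_compartments=1, fractal_on={"Ke": 0.5}), params, dose, times
)

for label, prof in [("classical", classical), ("fractal Ke, h=0.5", fractal)]:
    reg = detect_regimes(times, prof["conc"], dose=100.0, v1=10.0)
    print(f"{label:18s}  Cmax {reg.c_max:.3f} mcg/L at {reg.t_max:.1f} h, "
          f"central fraction left at 400 h: {reg.fraction_remaining:.3f}")

base = criteria(1443.70, 12, 383)          # OFV, parameters, observations
frac = criteria(1410.08, 13, 383, comparator=base)
print(f"base    AIC {base.aic:.2f}  AICc {base.aicc:.2f}")
print(f"fractal AIC {frac.aic:.2f}  AICc {frac.aicc:.2f}  dOFV {frac.delta_ofv:.2f}")
print("significant:", lrt_significant(frac.delta_ofv, 1).significant)
```

prints

```
classical           Cmax 9.511 mcg/L at 15.0 h, central fraction left at 400 h: 0.270
fractal Ke, h=0.5   Cmax 9.789 mcg/L at 20.0 h, central fraction left at 400 h: 0.886
base    AIC 1467.70  AICc 1468.54
fractal AIC 1436.08  AICc 1437.07  dOFV -33.62
significant: True
```

The fractal elimination rate decays as drug ages in the body, so 89% of
the absorbed dose is still in the central compartment at 400 h — the
"trapping" regime — versus 27% classically. The criteria block shows a
model comparison where adding the single heterogeneity exponent drops the
OFV by 33.62, far beyond the 3.84 one-parameter significance threshold.

A command-line interface mirrors the library
(`fractalpk simulate|grid|genpop|fit|diagnose|vpc|npde`); every stochastic
subcommand takes an explicit `--seed` and echoes it in its output
metadata. See `docs/methods.md` for the model, estimation algorithm and
design choices.

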