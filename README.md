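# smtdyn — sulfate–methane transition dynamics in methane-charged sediments

`smtdyn` is a Python toolkit for interpreting porewater geochemistry and
microbial data from methane-charged marine sediments, built around the
kind of Arctic gas-hydrate-mound setting where the methane supply to the
seafloor changes on human timescales. It couples three things:

1. a **1-D diffusion–reaction model** of porewater sulfate and methane
   in a 60-m sediment column, with anaerobic oxidation of methane (AOM)
   as the only reaction,
2. a **profile classifier** that reads the shape of a measured sulfate
   profile as a record of methane-supply history — steady, transitional,
   recently increasing, or actively seeping — and dates flux increases
   by matching model runtime to the observations, and
3. the **microbial response layer**: because the sulfate–methane
   transition (SMT) migrates upward at a known model-derived rate,
   depth below the present AOM peak maps onto time since the peak
   passed, turning functional-gene depth profiles (*mcrA* for anaerobic
   methanotrophs, *dsrAB* for sulfate reducers) into population
   dynamics — doubling times, community lag times, per-cell AOM rates —
   and community diversity into a function of distance from the front.

It is aimed at biogeochemists and geomicrobiologists who have porewater
solute tables, ddPCR gene-count tables, and/or amplicon (ASV) count
tables from sediment cores and want a reproducible, tested pipeline
from raw tables to methane-dynamics states and microbial rates.

## The model

Both solutes obey a diagenetic diffusion–reaction equation on
0 ≤ z ≤ L = 60 m (positive down):

    ∂(φC)/∂t = ∂/∂z( φ Ds ∂C/∂z ) − φ R,      R = k [SO₄²⁻][CH₄]

with porosity φ = 0.7, effective diffusivities Ds = D₀/θ² and
tortuosity θ² = 1 − ln φ² (D₀ at ~2 °C: 0.018 m² yr⁻¹ for sulfate,
0.028 for methane). Sulfate and methane take seawater Dirichlet values
at the seafloor (28 and 0 mM); sulfate has a no-flux base; methane is
held at a reservoir concentration at a configurable source depth (a
dissolved-gas front sustained by free gas / hydrate below). The
bimolecular constant k and the forcing levels are calibrated (see
`smtdyn/calibration_report.json`) so that:

* a **steady** supply run for 40 kyr puts the SMT at ~1 m with peak AOM
  ~10 nmol cm⁻³ d⁻¹ and a residual SMT creep of a few 10⁻³ cm yr⁻¹;
* a **recent flux increase** (a rising gas front stepping in after a
  weak-supply spin-up) shoals the SMT at ~10 cm yr⁻¹ with peak AOM
  above 100 nmol cm⁻³ d⁻¹;
* a **transitional** (moderate) increase shoals the SMT at ~0.4 cm yr⁻¹.

Numerics: backward-Euler finite volumes (discretely conservative to
round-off) with Strang splitting; the local reaction ODE pair is
integrated exactly via the invariant [SO₄]−[CH₄], so 1:1 stoichiometry
and positivity hold by construction. See `docs/methods.md`.

## Worked example

Generate a synthetic core experiencing a methane-flux increase that
began 15 years ago, then classify it and date the onset:

```python
import numpy as np
from smtdyn import PorewaterStateModel
from smtdyn.synth import SynthSpec, synth_porewater

spec = SynthSpec(state="increasing",
                 depths_cm=tuple(np.arange(10., 301., 10.)),
                 onset_age=15.0, seed=42)
profile, truth = synth_porewater(spec)
res = PorewaterStateModel(profile).fit()
print(res.summary())
```

```
 Methane-dynamics state: core SYN-increasing-42
================================================

------------------------------------------------
methane state                         increasing
SMT depth (cmbsf)      219.2 (sulfate-threshold)
linear R2 above SMT                       0.9358
gradient break (cmbsf)                     185.0
onset age (yr)               14.9 (rmse 0.43 mM)
------------------------------------------------
```

Reading the table: the sulfate profile is concave-up (it steepens
abruptly below a gradient break at 185 cm, hence the low linear R²),
which classifies the core as *increasing*; the first sulfate crossing
of 0.5 mM puts the SMT at 219 cm; and the least-squares match of model
runtime to the observed profile dates the onset of the flux increase to
14.9 years before sampling — the generating truth was 15.0 years, with
a true SMT of 217 cm.

With the model-derived shoaling rate (10 cm yr⁻¹ for this state), gene
profiles become time series: a *mcrA* maximum 10 cm below the
present-day AOM peak implies a ~1-year community lag, and a downcore
*mcrA* increase by a factor r over Δz cm implies a doubling time
t_d = (Δz/v)·ln 2/ln r (in days with a 365.25-d year); see
`smtdyn.microbes`.

A CLI mirrors the library: `smtdyn simulate|classify|dynamics|
diversity|synth|calibrate|run` (exit codes: 0 ok, 2 validation error,
3 model/fit failure).

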