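# Methods

This note documents the model, its numerics, the calibration, the
synthetic-data generators, and the design choices made where the design
was genuinely open. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; none is asserted from memory.

## 1. The reduced reactive-transport model

### Governing equations

Porewater sulfate S and methane M in a 60-m column (the approximate
base of the gas hydrate stability zone at the target setting) obey

    ∂(φC)/∂t = ∂z(φ Ds ∂z C) − φ R,     R = k·S·M,

with AOM the only reaction and 1:1 SO₄:CH₄ stoichiometry. The reduced
network deliberately omits gas-phase transport, bubble irrigation,
bioturbation, advection, sulfide reoxidation, organoclastic sulfate
reduction and carbonate precipitation: the target phenomenology is the
shape and motion of the sulfate profile and the AOM front, for which
diffusion + bimolecular AOM is the minimal closure.

Parameters (defaults):

| symbol | meaning | default | units |
|---|---|---|---|
| L | column length | 60 | m |
| Δz | cell size | 0.01 | m |
| φ | porosity | 0.7 | – |
| θ² | tortuosity, 1 − ln φ² | 1.713 | – |
| D₀(SO₄) | free-solution diffusivity, ~2 °C | 0.018 | m² yr⁻¹ |
| D₀(CH₄) | free-solution diffusivity, ~2 °C | 0.028 | m² yr⁻¹ |
| k | AOM rate constant (calibrated) | 33.68 | mM⁻¹ yr⁻¹ |
| S_sw | seafloor sulfate | 28 | mM |

Concentrations are in mM = mol m⁻³, so R is in mol m⁻³ yr⁻¹;
conversion to the literature unit nmol cm⁻³ d⁻¹ multiplies by
1000/365.25 = 2.7379 (365.25-day year throughout).

### Boundary forcing and scenarios

Sulfate: Dirichlet 28 mM at the seafloor, no-flux at the base.
Methane: Dirichlet 0 mM at the seafloor and a reservoir concentration
C_bot applied at a source depth z_src — the top of a dissolved-methane
pool sustained by free gas or hydrate. Cells at or below z_src are held
at C_bot; methane consumed there is replenished by the source and
booked as boundary influx. A scenario may step the forcing once at
t_step (new concentration, new source depth), and after the step the
source front may ascend linearly — an advancing free-gas front — never
above 0.5 m depth.

Three scenario factories (`smtdyn.defaults`) encode the methane-supply
states. All share the column, k, and a 40-kyr spin-up from seawater
initial conditions (S = 28, M = 0 everywhere):

* **steady** — C_bot = 1719 mM at 60 m for 40 kyr. The concentration
  is an *effective* reservoir value: delivering a near-seafloor SMT
  through a 60-m diffusive path requires a bottom concentration far
  above in-situ solubility, and the value should be read as
  parameterizing gas/hydrate-sustained supply, not as a dissolved
  concentration anyone would measure. The 40-kyr state is quasi-steady:
  the SMT still creeps upward at 3.8×10⁻³ cm yr⁻¹ (measured between
  the 30- and 40-kyr snapshots), decelerating monotonically — exact
  stationarity is only asymptotic (the full-column diffusion time is
  ~10⁵ yr).
* **increasing** — spin-up with a weak base supply (400 mM at 60 m,
  pre-step SMT at 4.1 m), then a gas front carrying 400 mM arrives at
  4.3 m and ascends at 0.106 m yr⁻¹. A *static* stepped source cannot
  sustain decadal ~10 cm yr⁻¹ shoaling: the SMT runs away from a fixed
  source and decelerates to ~4–5 cm yr⁻¹ within two decades (measured),
  so the ascending front is a structural necessity, not a tuning
  nicety.
* **transitional** — same spin-up; a static front at 4.5 m carrying
  16.6 mM. The front sits at the same arrival depth as the increasing
  scenario but ~25× weaker, producing the documented morphology of
  transitional cores: a long linear upper segment over a ~1.5× steeper
  basal segment with the gradient break near 2.5 mbsf.

### Numerics

Backward-Euler finite volumes on cell centers with half-cell Dirichlet
conductances at the boundaries. The scheme is discretely conservative:
over a 40-kyr run the relative budget residual per solute (storage
change vs boundary fluxes minus reaction) is < 10⁻⁸ (tests assert the
0.1 % requirement with orders of magnitude to spare).

The reaction is combined by Strang splitting, and the local ODE pair
dS/dt = dM/dt = −kSM is integrated **exactly** over each half step
using the invariant d = S − M: with r = M/S, r(t) = r(0)·e^(−k d t) and
S(t) = d/(1 − r(t)) (harmonic decay in the symmetric limit). This
choice — in place of a semi-implicit linearization — makes the step
unconditionally positive and enforces cumulative 1:1 stoichiometry to
round-off (asserted at 10⁻⁹ relative), at any Δt.

Time stepping: Δt = 10 yr during spin-up, 0.05 yr after a boundary step
(0.2 yr for the slow transitional front). One subtlety is load-bearing:
at a Δt exceeding the local reaction time 1/(kC), splitting leaves the
thin reaction-zone overlap depleted between substeps, so the pointwise
diagnostic R = kSM evaluated on a coarse-Δt state underestimates the
true rate field even though the *dynamics* (front position, consumed
mass) are transport-controlled and accurate. The stepper therefore
re-equilibrates the front with Δt = 0.005 yr for one year before every
saved snapshot (front relaxation time w²/Ds ≲ 0.5 yr); SMT depths are
insensitive to this refinement, only the rate field needs it.

Grid: Δz = 0.01 m resolves the calibrated reaction front (half-peak
width a few cm in the steady state). The 40-kyr SMT depth moves < 0.1
mm under Δz halving (the test requires < 1 cm).

The SMT is defined in model space as the linearly-interpolated S = M
crossing (falling back to a 0.5 mM sulfate criterion when the profiles
do not cross); observationally (`geochem.estimate_smt_depth`) as the
first downward crossing of 0.5 mM sulfate, with the depth of steepest
alkalinity increase (±30 cm) as fallback. Both are reported when they
differ.

### Calibration

Four supply-side parameters have no direct observational constraint
and are pinned by nested bracketed root-finds (`smtdyn.calibrate`),
each on a monotone response:

| knob | pinned to | achieved |
|---|---|---|
| C_bot (steady) | 40-kyr SMT at 1 m | 0.999 m |
| k | steady peak AOM 10 nmol cm⁻³ d⁻¹ | 10.02 |
| front ascent w | increasing shoaling 10 cm yr⁻¹ | 9.99 |
| C_mid (transitional) | shoaling 0.4 cm yr⁻¹ | 0.400 |

Emergent, *not* calibrated: the steady late-time creep (3.8×10⁻³
cm yr⁻¹ against a 7×10⁻³ benchmark, −46 %), the increasing-scenario
peak AOM (119 against ~200 nmol cm⁻³ d⁻¹, −41 %) and its
depth-integrated flux (1.45 mol m⁻² yr⁻¹). The shipped
`calibration_report.json` lists every benchmark with its residual.

**Known limitation — the steady-state flux.** At quasi-steady state the
depth-integrated AOM equals the downward sulfate flux, which pure
diffusion caps at φ·Ds·S_sw/z_SMT ≈ 0.22 mol m⁻² yr⁻¹ for an SMT at
1 m (0.41 even at 0.5 m). A steady-state flux of ~1.3 mol m⁻² yr⁻¹ is
therefore unreachable jointly with a ~1-m SMT under this transport
parameterization — the corresponding benchmark test is expected to
fail and is kept failing rather than weakened. Notably the
*flux-increase* scenario does deliver ~1.4 mol m⁻² yr⁻¹, because there
the sulfate reservoir is being consumed in place rather than
resupplied by diffusion.

Measurement protocol for the headline rates (a reporting convention,
fixed in `defaults`): steady late-time rate between the 30- and 40-kyr
snapshots; increasing rate over post-step years 15–25 of a 25-yr run;
transitional rate over post-step years 50–150 of a 150-yr run.

## 2. Profile classification and onset dating

`classify_methane_state` applies a fixed rule cascade; all numeric
thresholds are package constants:

1. **seep** — sulfate > 20 mM persisting below 10 cmbsf while methane
   > 1 mM occurs above 30 cmbsf, or sulfate increasing downcore by
   > 2 mM (irrigation/advection signatures). Seep profiles are never
   onset-dated: advective transport is outside the diffusive scheme.
2. **increasing** — statistically significant concave-up curvature
   (t-test on the quadratic coefficient of sulfate ~ depth, p < 0.05;
   the coefficient is negative when sulfate loss accelerates downward)
   *and* an abrupt gradient change: post-break steepening ratio ≥ 3,
   or no detectable break at all.
3. **transitional** — a two-segment break (splitting must cut the
   residual sum of squares by > 50 %) under a linear upper segment
   (R² ≥ 0.95) with a moderate steepening ratio ≥ 1.3.
4. **steady** otherwise.

The steepening-ratio discriminator is needed because both step states
produce significant quadratic curvature under realistic noise; the
noise-free ratios of the three model states are well separated
(steady 0.96, transitional 1.5, increasing 5.0). The upper-segment
linearity gate sits at 0.95 rather than higher because, with 0.5 mM
sulfate noise on an upper segment spanning ~12 mM, the *expected* R²
of a perfectly linear segment is already ≈ 0.98 — a stricter gate
rejects genuine two-slope profiles at the data's own noise floor.

`fit_onset_time` dates a flux increase by simulating the scenario once
with snapshots on a candidate elapsed-time grid, interpolating modeled
sulfate to the observation depths, and refining the RMSE-minimizing
grid time with a local parabola. It refuses scenarios whose modeled
dynamic range falls below 90 % of the observed range. On synthetic
transitional profiles with 1 mM noise the median recovery error of a
100-yr onset is below 10 % (20 seeds); at zero noise recovery is exact
to the grid refinement.

The statsmodels-style wrapper `PorewaterStateModel` /
`PorewaterStateResults` packages classification, SMT estimate, shape
diagnostics and the onset fit behind `fit()` and `summary()`.

## 3. Microbial dynamics (space-for-time substitution)

With the AOM peak at depth z₀ today and shoaling at v (cm yr⁻¹), a
horizon at depth z experienced the peak (z − z₀)/v years before
sampling (negative: not yet). On that clock:

* **doubling time** from a downcore abundance increase toward the
  front: t_d = Δt·ln2 / ln(N_deep/N_shallow), Δt = Δz/v in days. The
  deeper horizon has been exposed longer, so growth requires
  N_deep > N_shallow; `implied_abundance_ratio` is the exact inverse
  (round-trip tested to 10⁻¹² relative). A regression variant fits
  ln N against depth over a growth limb and is the noise-tolerant
  estimator of choice.
* **community lag** = (depth of the mcrA maximum − AOM-peak depth)/v;
  positive when the population peaks after the front has passed; a
  boundary maximum triggers an unresolved-peak warning.
* **per-cell AOM rate** = volumetric rate / cell density, with cell
  density = copies g⁻¹ × wet bulk density / copies-per-genome (one
  mcrA per methanotroph genome; wet bulk density default 1.7 g cm⁻³,
  a typical glaciomarine value — the conversion underlying published
  per-cell figures is not stated anywhere we could verify, so this
  module implements the defined formula and makes no claim of
  reproducing any particular printed average).
* **rate–abundance coupling**: OLS of log₁₀(copies) on log₁₀(rate)
  with censored pairs excluded and counted.

Counts at or below the ddPCR detection floor (10³ copies g⁻¹) are
censored, never exact zeros; rate and regression computations exclude
them by default and refuse them loudly otherwise.

## 4. Diversity statistics

Shannon H = −Σ pᵢ ln pᵢ (natural log, nats) on raw counts after a
minimum-read filter (8931 reads, the blank/low-coverage cutoff); no
rarefaction, since the filter — not a rarefaction depth — is the stated
convention. Samples are placed on a signed offset axis (positive above
the present-day AOM peak) and H is regressed on offset within a window
(default ±40 cm, a package choice) per group; peak depths come from
the model, or from the steepest sulfate gradient for seep cores.
Redox-zone assignment: below-SMT beneath the SMT; nonlinear-SR between
the gradient break and the SMT for recently-impacted states;
linear-SR otherwise; unzoned without an SMT.

## 5. Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed) — byte-identical on
repetition — and return a truth record alongside the data.

**Porewater** (`synth_porewater`): sulfate/methane sampled from the
scenario truth at chosen depths with truncated-Gaussian noise (default
0.5 mM, ion-chromatography-scale scatter). Alkalinity is attached by
stoichiometric heuristic (2 meq per mmol sulfate consumed, seawater
baseline 2.3 meq/L) and sulfide as a Gaussian bump at the SMT with
amplitude 500 µM per unit integrated AOM — these are emulation
companions, not model outputs. Seep profiles are rule-generated
(near-seawater sulfate over the upper 10 cm, methane near 30 mM).
Default sampling designs used in the benchmark suite reflect field
practice: 10–15 cm spacing over 1–4 m of recovery.

**Gene profiles** (`synth_gene_profiles`): the growth clock at each
depth is its cumulative exposure to the half-peak AOM band translating
along the front trajectory (shifted into the rate-peak frame), shifted
by the community lag: N = N_bg·2^(G/t_d), capped at a carrying value,
with exponential post-exposure decay — fast for mcrA (160-d halving,
reproducing a several-order bust within a few years) and slow for
dsrAB (1200 d, keeping its dynamic range under an order of magnitude).
Defaults: t_d = 200 d, background 10⁵ copies g⁻¹, lognormal noise 0.2
in log₁₀. The emulation column for gene dynamics uses k = 0.05
(half-peak width ~31 cm) because the observed gene profiles and the
10–33.5-cm doubling-time intervals presuppose a front tens of cm wide;
the calibrated k reproduces printed peak rates but compresses the
front to a few cm, which is the model's width, not the microbial
record's. Median doubling-time recovery error at default noise: 7.9 %
over 20 seeds (≤ 15 % required).

**ASV tables** (`synth_asv_table`): 46 taxa (40 background with
lognormal base concentrations, 3 ANME, 3 SRB). Per sample, Dirichlet
concentrations scale with proximity f = exp(−(offset/15 cm)²) to the
front in high-flux states — ANME boosted ×(1+80f), SRB ×(1+57f),
background shrunk ×(1−0.6f) — then multinomial counts at 20 000 reads.
Near the peak, ANME reach ~45 % of reads and Shannon H drops by ~1
nat; steady-state communities are offset-independent (regression slope
insignificant in ≥ 90 % of seeds).

What passing these tests shows about real data — and what it does not:
the pipeline provably recovers states, onset ages, doubling times and
diversity trends *under the stated noise model* (independent Gaussian/
lognormal measurement error around the reduced model's truth). Real
cores add structure the generators do not emulate: porosity and
lithology variation, advective events, degassing artifacts in methane,
compaction, patchy biogeography, and extraction biases in counts.
Recovery rates here are therefore upper bounds on field performance.

## 6. Degenerate inputs and tie-breaks

* Exact-equality sulfate-threshold crossings return the sampled depth.
* Steepest-gradient and mcrA-maximum ties break to the shallowest.
* A perfectly linear profile reports no gradient break (round-off
  residuals are not splittable evidence).
* Missing methane values are allowed (gas escapes during recovery) and
  never used for SMT picking.
* Negative concentrations below 10⁻¹² mM are clipped; anything larger
  aborts the step.
* Titration series outside the 7–10-reading field convention warn but
  proceed; titrations not passing equivalence raise.
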