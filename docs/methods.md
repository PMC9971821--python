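# Methods

## Model structure and assumptions

The model describes a single oral dose of DPHP in an adult male.  Absorption
is deliberately richer than a standard one-compartment gut because the
biomonitoring signals demand it: only a minority of the dose is absorbed at
all (the remainder is booked to faeces at ingestion), a small lymphatic
fraction bypasses the liver entirely and appears late in blood, and the gut
is split into two sequential lumen sections separated by a transit delay so
that uptake can show two phases.  DPHP undergoes enterohepatic
recirculation: a first-order liver→bile flux with a transit compartment
(mean residence `bile_delay`) returning to the second gut section.

Distribution is flow-limited.  Tissue uptake is driven by `fu · C_art` (only
the unbound fraction of either chemical distributes or is metabolised);
tissue return and hepatic metabolism use the venous-equilibrium
concentration `C_i / P_i`.  Plasma and red blood cells are lumped into one
blood compartment: the measured quantity is total blood concentration, so
the plasma/RBC split never enters the dynamics.  A consequence worth
stating: the plasma partition coefficients (`Pbab`, `PbaM`) and the
gut-tissue partitions (`Pgub`, `PguM`) are carried as named parameters —
they belong to the calibration vector — but touch no differential equation;
their sensitivity is exactly zero in this structure.

MPHP is produced in gut section 1 (rate `ln 2 / T½_gut · 60 · MPYgu/MPYgu°`)
and in the liver (clearance scaled from the in-vitro substrate-depletion
half-life: `CLint = (ln2/T½) · 1000/C_protein · MPY · m_liver`, µL/min
converted to L/h).  Two escape fractions reproduce the sharp early MPHP
blood peak: `Escape_gu` of gut-absorbed MPHP binds in blood and skips
first-pass extraction, and `Escape_Li` of liver-formed MPHP evades immediate
metabolism.  `Escape_Li` applies to the DPHP-derived formation flux only;
systemically recirculating MPHP re-entering the liver sees the full
clearance.  Metabolised MPHP feeds the OH-MPHP and cx-MPHP pools by the
fractions `FracMetab_MOH`/`FracMetab_cx` (the remainder is an explicit
"other metabolite" sink so the molar balance closes); the secondary
metabolites have no tissue distribution, only first-order urinary loss, and
kidney MPHP is eliminated to urine first order.  Mass is converted at each
metabolic step by molecular-weight ratio (446.67, 306.40, 322.40,
336.38 g/mol for DPHP, MPHP, OH-MPHP, cx-MPHP from the molecular formulas);
the internal audit works in moles and holds to machine precision.

Structural choices that the prose description left open, decided here:

- Stomach uptake (`BELLYPERM`) and lymphatic release go directly to venous
  blood; the `GIPERM1`/`GIPERM2` gut streams go to the portal circulation
  and hence through the liver.  Portal routing is what makes the liver the
  dominant site of DPHP metabolism; routing those streams to venous blood
  instead would largely abolish first-pass loss.  This is the single most
  consequential structural ambiguity in the source description.
- The gut DPHP→MPHP rate is taken as the in-vivo gut half-life scaled
  multiplicatively by `MPYgu` around its default — both quantities are
  calibrated and their interplay is not otherwise identifiable.
- Lags (`Gutlag`, `Lymphlag`) are hard time switches on first-order
  transfer, smoothed over `hs_width = 0.01 h` for integrator stability (the
  width is configuration).  They are not transit-compartment chains.
- Cardiac output scales as `QC = QCC · BW^0.75`.  Linear-in-BW scaling of
  the tabulated coefficient (14) would give a ~1000 L/h cardiac output.
- Tissue density is 1 kg/L; slowly/rapidly perfused volumes come from their
  tabulated fractions, not from a remainder; flow fractions are *not*
  renormalised (they sum to 0.996 at defaults) — venous return is computed
  as the sum of tissue outflows, so any allocation is mass-consistent.
- Non-tabulated plumbing constants, exposed in configuration: gastric
  emptying `k_st_gut = 2 h⁻¹`, gut transit `k_transit = 1 h⁻¹`, MPHP gut
  absorption `k_abs_MPHP_gut = 2 h⁻¹`, `bile_delay = 1 h`, in-vitro
  incubation protein concentration 1 mg/mL (calibration of `MPY` absorbs its
  uncertainty).

## Parameters and priors

Defaults live in `src/dphpkin/data/defaults.yaml` (percent entries as
printed in the physiological tables; the loader converts to fractions).
Priors for uncertainty analysis combine three groups (54 parameters in
total):

- anatomy/physiology (body weight, eight volume fractions, cardiac output,
  seven flow fractions): normal/lognormal, truncated at the 5th–95th
  percentiles, the convention of the population generator they derive from;
- metabolism, binding, biliary transfer: half-normal or normal truncated at
  zero, plus the two uniform binding fractions;
- uptake, routing, elimination and partition parameters published only as a
  median and 95% interval: back-fitted by inverting each family's quantile
  function (`fit_prior_from_summary`), with fraction-valued parameters
  clipped to [0, 1].  The remaining tissue partition coefficients follow the
  same uniform-around-default pattern (0.05×–1.95×) that the printed
  back-fits exhibit.

The source analysis reports varying 61 parameters; its full list is not
printed, so the count here is the package's own (54) and the Morris run
count is derived from it as `r(k+1)`.

Calibration priors are the back-fitted summary columns (globals and one
independent copy of the 16 local parameters per volunteer — four copies, not
a hyper-parameterised population model), with half-normal(1) priors on the
five error SDs.  One printed local summary (kidney volume fraction,
0.0058 (0.0028, 0.007)) is internally inconsistent with every family tried
and is specified directly as N(0.0058, 0.0015) truncated at zero.
Back-fitted normals are truncated at zero: every calibrated quantity is
physically non-negative and the analytic quantile shift is negligible.

## Error model and sampler

Each of the five observation streams is a normal distribution truncated at
zero around the model prediction:
`log φ((y−μ)/σ) − log σ − log Φ(μ/σ)`.  Blood predictions are read at the
sample times from the solver grid; urinary predictions are interval-average
deposition rates (cumulative-amount differences over the inter-void
interval), exactly matching the data transform.

The sampler is adaptive random-walk Metropolis-within-Gibbs.  **One
iteration proposes one randomly chosen component**, not a full sweep: with
87 components (18 globals + 4×16 locals + 5 SDs) per-volunteer prediction
caching makes a local update cost one ODE solve, a global update four, and
an error-SD update none, so a 20,000-iteration chain needs roughly 3×10⁴
solves rather than 10⁷.  Step sizes adapt per component during a discarded
warm-up (default a quarter of the run) by Robbins–Monro towards 30%
acceptance.  The production budget mirrors the source analysis (150,000
iterations, every 10th retained); tests and examples use scaled-down chains.

Thermodynamic integration uses the power ladder `t_i = (i/10)⁵` by default
(rungs concentrated near the prior, where the expected log likelihood
changes fastest) and the trapezoid rule over per-rung mean log likelihood.
On a conjugate toy the 21-rung ladder is within 0.1 nat of the quadrature
evidence; the default 11-rung ladder carries a discretisation bias of about
0.1 nat.

Posterior summaries are empirical 50/2.5/97.5 percentiles; the central curve
of a credible band is the simulation at the retained draw with the highest
log posterior, and bands are pointwise 2.5/97.5 percentiles over draws on a
0–48 h grid at 0.05-h steps.  A calibration caveat for interpreting the
bands: pointwise coverage of a true curve is a property in expectation over
data realisations.  Within one noisy dataset the band's errors are strongly
correlated in time — one high-noise stream displaces a whole fitted curve —
so the fraction of true-curve points covered in a single replicate is
erratic unless the posterior is converged and well identified; the band
verification therefore runs on a reduced free-parameter calibration where
those conditions hold.

## Synthetic-volunteer generator

The generator runs the model at a chosen truth (by default the calibrated
central estimates, global and per-volunteer) under the study design — blood
at 0.25–24 h, urine voids at 1–46 h, the six tabulated body weights and
doses — and adds zero-truncated normal noise on the calibration observables
at the calibrated residual SDs.  Void volumes are log-normal with median
0.15 L and geometric SD 1.5: operational constants (the study reports
none), and results quoted against published values never depend on them
because noise is injected on the deposition-rate scale and back-propagated
to concentrations.  What the generator does *not* emulate: secondary uptake
events after food intake (it produces them only if you inject them, as the
consistency-screen tests do), creatinine variation, assay detection limits,
and any model-structure error — so parameter-recovery results certify the
inference machinery, not the model's fidelity to real volunteers.

The consistency screen flags a volunteer when the OH- or cx-MPHP deposition
series has a local maximum after 12 h reaching 50% of the series peak; both
constants are operational choices exposed as arguments.

## Numerics

The ODE system (25 states) is integrated by an adaptive Cash-Karp RK4(5)
pair compiled with numba, with cubic-Hermite interpolation onto the output
grid; default tolerances rtol 1e-6, atol 1e-9 mg.  A solve over 0–48 h takes
well under a millisecond, which is what makes 10⁴–10⁵-solve analyses
practical on one core.  Correctness guards: halving the tolerances moves
blood MPHP by <0.1% everywhere; the molar balance over all compartments,
urine, faeces and the metabolite sink stays at machine precision; a
distribution-free configuration reproduces the one-compartment analytic
solution to 0.1%.  States can undershoot zero only at the absolute-tolerance
scale.  Step-size collapse or a non-finite state raises a diagnostic naming
the failure time; during MCMC a failed simulation scores −∞ and the proposal
is rejected.

## Problem sizes used in the shipped analyses

The uncertainty analysis uses the full 500-point design (100 maximin
candidates).  Test chains use 3,000–40,000 single-component iterations; the
parameter-recovery check uses five replicates of a 40,000-iteration chain on
four synthetic volunteers, started at the data-generating values with the
adaptation target at 0.4 (the component-wise near-optimum).  Starting at a
high-density point makes a scaled-down chain measure interval calibration
rather than burn-in length; a 100,000-iteration chain started the same way
covers all checked truths, so the residual coverage shortfall of short
chains is effective-sample-size noise in the interval endpoints, not bias.  Morris screening defaults to 4 levels and
5 trajectories (r(k+1) = 275 runs at k = 54), with each prior clipped to its
(0.005, 0.995) quantile range so grid endpoints stay inside open supports.

## Known limitations

- Metabolism is clearance-based; there is no saturation mechanism, so the
  escape fractions are valid at the study dose and cannot be extrapolated
  to other dose levels.
- oxo-MPHP (a further metabolite of OH-MPHP) is not modelled; OH-/cx-MPHP
  have no tissue distribution.
- The plasma and gut-wall partition coefficients are structurally inert
  (see above); calibrating them simply returns their priors.
- A single oral dose at t = 0; no dermal/inhalation routes, no repeated or
  secondary uptake, no rat model.
- One chain, no cross-chain convergence diagnostics beyond acceptance rates
  and trace export.
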