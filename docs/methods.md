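# Methods

## Tracer-kinetic models

All models map an arterial plasma concentration c_a(t) to a tissue
concentration c_t(t). The four compartment models are defined by linear ODE
systems in the tissue sub-compartment concentrations; `perfkit` evaluates
their closed-form solutions and keeps a stiff numerical integrator
(scipy's LSODA at rtol 1e-10) purely as an independent test oracle.

**1CP** — a single plasma compartment with inflow F_p·c_a and outflow
F_p·c_p: residue R(t) = e^(−t/T_p), T_p = v_p/F_p.

**2CUM (uptake)** — plasma plus an irreversible sink with influx PS·c_p and
no backflux: R(t) = E + (1−E)·e^(−t/T_p) with T_p = v_p/(F_p+PS) and
E = PS/(F_p+PS). R does not decay to zero; R(∞) = E.

**2CFM (filtration)** — plasma with inflow F_p·c_a and outflow
(F_p+F_t)·c_p feeding a tubular compartment v_t·dc′/dt = F_t(c_p − c′),
parameterized by the tubular flow F_t and the tubular mean transit time
T_t = v_t/F_t:
R(t) = e^(−t/T_p) + E·T_t/(T_t−T_p)·(e^(−t/T_t) − e^(−t/T_p)),
T_p = v_p/(F_p+F_t), E = F_t/(F_p+F_t).

**2CXM (exchange)** — plasma ⇄ interstitium:
v_p·dc_p/dt = F_p(c_a−c_p) + PS(c_e−c_p), v_e·dc_e/dt = PS(c_p−c_e). The
residue is the bi-exponential from the analytic eigen-decomposition of the
2×2 system; the mode weights are computed in a form free of the removable
singularity at PS = 0, so the 1CP limit is exact.

**ETM (extended Tofts)** — closed form
c_t = v_p·c_a + K^trans ∫₀ᵗ c_a(u)·e^(−k_ep(t−u)) du with
k_ep = K^trans/v_e.

Internally flows (F_p, F_t, PS, K^trans) are fractional rates in 1/s,
volumes are dimensionless fractions and times are in seconds; the display
conversion (×6000 to ml/min/100 ml, ×100 to ml/100 ml) happens only in the
derived-parameter step. This avoids the unit mixing that arises when flows
in ml/min/100 ml meet transit times in seconds. Derived ratios with a zero
denominator (e.g. interstitial MTT = v_e/PS at PS = 0) are reported as NaN
and flagged, never raised.

## Exponential convolution

All convolutional models reduce to convolutions with normalized
exponential kernels (1/T)e^(−t/T). These are evaluated by the exact
per-interval recursion for a piecewise-linear input,

y_{i+1} = y_i·e^(−Δ/T) + a_{i+1}·(1−e^(−Δ/T)) − m_i·(T − (T+Δ)e^(−Δ/T)),

written with `expm1` to avoid cancellation for Δ ≪ T. The recursion is
exact for piecewise-linear input, works on non-uniform grids (each interval
uses its own Δ), and remains stable when T approaches the frame spacing —
properties a rectangle-rule or FFT convolution does not share on 100-point
clinical grids.

Coalescent time constants (2CFM with T_t → T_p; the double eigenvalue of
the 2CXM) switch to the analytic limiting form (t/T)e^(−t/T) when the
relative difference falls below 1e-8, avoiding catastrophic cancellation.
The corresponding convolution uses the identity
(t/T)e^(−t/T) = T·(f⊗f)(t) with f = (1/T)e^(−t/T), i.e. the exponential
recursion applied twice.

## Signal preparation

The baseline S0 is the mean of the first `baseline_n` samples of a curve.
Normalization offers relative enhancement (S−S0)/S0 (default), subtraction
S−S0, or none. ROI curves are formed by averaging the enclosed voxels'
signal first and normalizing the average; the alternative (normalize per
voxel, then average) differs only when baselines vary strongly within an
ROI, and a single convention keeps AIF and tissue amplitudes consistent.
The arterial ROI yields blood concentration; plasma concentration is
c_a = c_a,b/(1−Hct_a) with Hct_a = 0.45 by default (a subject-specific
value should be used when available). The tissue haematocrit Hct_t is
carried in the configuration for completeness but enters no equation.
All time-point and slice indices are 0-based with inclusive ranges;
trimming re-zeroes the time vector.

## Fitting

The solver is scipy's trust-region-reflective least-squares method — a
box-constrained Levenberg–Marquardt-type algorithm — minimizing the
unweighted sum of squared residuals. Defaults: 200 iterations, cost and
step tolerances 1e-10, bounds [0, ∞) for rates and [0, 1] for volume
fractions, physiologic mid-range initial values (F_p = 0.01 s⁻¹,
v_p = 0.05, v_e = 0.2, PS = F_t = K^trans = 0.002 s⁻¹, T_t = 120 s).
Parameters flagged fixed are held bit-exactly; optional seeded random
restarts (default 0) perturb the initials by ±50%. Fits never raise on
non-convergence — the iteration budget exhausting is reported through the
`converged` flag. Parameters that the model divides by (v_p, v_e, T_t) are
nudged to 1e-12 for evaluation only when the optimizer probes the zero
boundary; returned values are the optimizer's own.

χ² is the unweighted SSR (no noise-variance weighting). Model comparison
uses the small-sample corrected AIC, AICc = n ln(χ²/n) + 2k +
2k(k+1)/(n−k−1) (plain AIC is also reported); rankings annotate each model
with the relative information loss exp((AICc_i − AICc_min)/2), which is 1
for the best model and ≥ 1 otherwise — note this is the reciprocal of the
conventional Akaike weight ratio, a convention stated in the report.

Two numerically perfect fits of nested models would otherwise be ranked by
meaningless sub-machine-precision residuals, so the ranking applies a
χ² floor of n·(10⁻⁸·max|data|)²: models whose SSR both fall below it are
tied and ordered by free-parameter count, then model name. The floor is far
below any realistic noise level and does not affect ranking of imperfect
fits.

## Parametric maps

Map mode fits every voxel inside a user-supplied rectangle propagated
through the slice stack, each voxel normalized against its own leading
samples (ROI-mode semantics applied voxelwise). Voxels outside the box are
NaN; in-box voxels whose preparation or fit fails (e.g. zero-signal
background under relative enhancement) are recorded as unconverged with
zero-valued parameters so every in-box map is finite. Fits are independent
per voxel, making results invariant to evaluation order and to restriction
onto sub-boxes. Map export writes a lossless array with a JSON sidecar of
units and bounding box, plus DICOM secondary-capture series using a
rescale-slope/intercept encoding of the physical units.

## DICOM timing

Per-frame timing is derived per vendor dialect: Siemens from per-volume
Acquisition Time (0008,0032) TM strings, differenced, with +24 h applied at
a midnight rollover; GE and Philips single-frame from Trigger Time
(0018,1060) in ms; Philips multiframe from Content Time (0008,0033)
differences with Acquisition Time (0008,0032) as fallback (the record notes
which was used); Bruker 2D from Repetition Time (0018,0080) × the acquired
images per volume (0018,1310 — for a 4-value acquisition matrix, the
nonzero phase-encode entry). Missing tags raise an error naming the tag,
since no model calculation is possible without timing. Non-uniform time
vectors are preserved end to end. Mixed-orientation series are split by
orientation and the caller selects one. The synthetic-series writer stores
voxel values as 64-bit float pixel data, so phantom round trips are exact;
it never writes patient-identifying content.

## Phantom

The generator emulates a clinical bolus study: 100 time points at 1.5 s; a
blood AIF with bolus arrival at 10 s, 5 s linear upslope, and biexponential
washout (80% at τ = 15 s, 20% at τ = 300 s), scaled so the plasma peak is
≈ 5 a.u. after Hct correction (a gamma-variate shape is also available);
tissue curves forward-simulated with parameters deliberately away from the
fitter's default initials; additive i.i.d. Gaussian noise on concentration
(the simplest model consistent with unweighted least squares). The
reference object is one 8 × 4 slice whose upper two rows carry the blood
AIF and lower two rows the tissue (optionally two regions with different
flow), plus an optional constant signal offset for exercising baseline
subtraction. Every artifact regenerates bit-identically from its JSON truth
manifest and seed.

What the phantom does *not* emulate: T1-to-concentration conversion and
water exchange (curves are concentration surrogates directly), AIF
dispersion/delay, partial-volume and inflow artifacts in the vessel, Rician
signal statistics, and spatial noise correlation. Passing tests therefore
validate the numerics and the pipeline plumbing, not robustness to these
real-data effects.

## Validation problem sizes

The validation battery (tests and `scripts/acceptance.py`) uses the
100-point reference grid, 100 seeded replicates for the noisy recovery and
model-selection rates, 20001-point quadrature grids out to 50 time
constants for the conservation integrals, and dt/100 fine grids for the
convolution and ETM quadrature oracles — sizes at which every oracle
comparison is converged well below its tolerance while the whole battery
runs in well under a minute per section.

## Known limitations

- No AIF delay/dispersion correction; the AIF is used as measured.
- No uncertainty estimates on fitted parameters (no bootstrap/posterior).
- Deterministic local optimization: pathological starts could in principle
  reach local minima; the seeded-restart option is the mitigation.
- The ROI "average-then-normalize" convention is fixed (see above).
- DICOM reading targets well-formed dynamic series; exotic private-tag
  timing schemes beyond the four dialects are not interpreted.
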