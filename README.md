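# perfkit

Quantitative perfusion analysis for dynamic contrast-enhanced MRI (DCE-MRI).
`perfkit` fits tracer-kinetic compartment models to concentration–time curves
by bounded nonlinear least squares, compares models with the corrected Akaike
information criterion, computes voxelwise parametric maps inside a
user-chosen bounding box, derives per-frame timing from the vendor-specific
DICOM headers of Siemens, GE, Philips and Bruker scanners, and writes an
audit-grade report of every setting that influenced a result.

It is aimed at MR physicists and imaging scientists who need a scriptable,
reproducible alternative to interactive perfusion plugins — for batch
processing, phantom validation, and method comparison studies.

## Models

A tissue concentration curve c_t(t) is related to the arterial plasma
concentration c_a(t) (the AIF, measured in blood as c_a,b and converted via
c_a = c_a,b / (1 − Hct_a), default Hct_a = 0.45) through a residue function
R(t):

    c_t(t) = F_p · (R ⊗ c_a)(t)

| model | free parameters | description |
|-------|-----------------|-------------|
| 1CP   | F_p, v_p        | one plasma compartment |
| 2CUM  | F_p, v_p, PS    | plasma + irreversible uptake |
| 2CFM  | F_p, v_p, F_t, T_t | plasma + tubular compartment (filtration) |
| 2CXM  | F_p, v_p, PS, v_e  | plasma ⇄ interstitium exchange |
| ETM   | K^trans, v_e, v_p  | extended Tofts: c_t = v_p c_a + K^trans ∫ c_a e^(−k_ep(t−u)) du |

Residues are the closed-form solutions of the underlying two-compartment ODE
systems (bi-exponentials, with analytic limits at coalescent time
constants); convolutions use an exact per-interval recursion for
piecewise-linear input, stable on non-uniform grids and for time constants
near the frame spacing. Fitted parameters are reported in the customary
display units (flows, PS and K^trans in ml/min/100 ml, volumes in
ml/100 ml, transit times in s, extraction fraction E = PS/(F_p+PS) in %,
K^trans = E·F_p, and for the ETM, PS = K^trans by definition).

Goodness of fit is the unweighted chi-square plus the corrected AIC,
AICc = n ln(χ²/n) + 2k + 2k(k+1)/(n−k−1); when several models are compared,
each is annotated with the relative information loss
exp((AICc_i − AICc_min)/2) (1 = best-ranked model).

## Worked example

Every input can be generated by the built-in phantom: an 8 × 4-pixel slice
with 100 time points whose upper half holds the arterial blood curve and
whose lower half holds tissue simulated from known parameters
(here a two-compartment exchange tissue with F_p = 90, v_p = 8 ml/100 ml,
PS = 18 ml/min/100 ml, v_e = 25 ml/100 ml, plus 1% Gaussian noise):

```python
from perfkit import *
from perfkit.phantom import default_truth, make_reference_object

vol, truth = make_reference_object(default_truth("2CXM", noise_sd=0.01, seed=7))
prep = PrepConfig(normalization="none")
aif_roi = RoiMask("AIF", slice_index=0, rect=(0, 0, 7, 1))
tissue_roi = RoiMask("tissue", slice_index=0, rect=(0, 2, 7, 3))
aif = blood_to_plasma(prepare_curve(roi_mean_curve(vol, aif_roi), prep), prep.hct_a)
tissue = prepare_curve(roi_mean_curve(vol, tissue_roi), prep)

est = KineticCurveFit(model="2CXM").fit(tissue, aif)
for name, value in est.derived_.values.items():
    print(f"{name:22s} {value:10.3f} {est.derived_.units[name]}")
print(f"{'final chi-square':22s} {est.chi2_:10.5f}")
print(f"{'corrected AIC':22s} {est.aicc_:10.1f}")
```

prints

```
plasma_flow                90.326 ml/min/100 ml
plasma_mtt                  4.393 s
plasma_volume               7.942 ml/100 ml
extraction_fraction        16.726 %
ps                         18.142 ml/min/100 ml
ktrans                     15.108 ml/min/100 ml
interstitial_mtt           82.766 s
interstitial_volume        25.026 ml/100 ml
final chi-square          0.00074
corrected AIC             -1173.4
```

— the generating parameters recovered to within the 1% noise level. Ranking
the candidate models on the same curve,

```python
for r in compare_models(tissue, aif, FitConfig(), ("1CP", "2CUM", "2CXM", "ETM")):
    print(f"{r.model:5s} AICc={r.aicc:9.1f}  info loss={r.info_loss:.3g}")
```

```
2CXM  AICc=  -1173.4  info loss=1
ETM   AICc=   -797.8  info loss=3.6e+81
2CUM  AICc=   -792.6  info loss=5.03e+82
1CP   AICc=   -651.1  info loss=2.62e+113
```

correctly selects the generating exchange model.

The same analyses run from the shell:

```
perfkit simulate-phantom --model 2CXM --out ph/ --dicom-dialect siemens
perfkit fit-roi --input ph/phantom.npz --model 2CXM --normalization none \
    --aif-roi 0:0:0:7:1 --tissue-roi 0:0:2:7:3 --out results/ --prefix demo
perfkit fit-maps --input ph/phantom.npz --model 2CFM --normalization none \
    --aif-roi 0:0:0:7:1 --bbox 0:2:7:3 --out results/ --prefix maps
perfkit extract-timing --input ph/dicom_siemens
```

Each run writes a parameter table (CSV), fit plots, parametric maps
(`.npz` + JSON sidecar + DICOM secondary capture) and a report
(rendered PNG + machine-readable JSON twin listing the model, baseline,
normalization, haematocrit, every initial value and bound, χ² and AICc).

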