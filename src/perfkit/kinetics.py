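"""Tracer-kinetic compartment models for DCE-MRI.

Five models map an arterial plasma concentration c_a(t) to a tissue
concentration c_t(t):

====== ============================== ==============================
model  free parameters (internal)     structure
====== ============================== ==============================
1CP    Fp, vp                         single plasma compartment
2CUM   Fp, vp, PS                     plasma + irreversible uptake
2CFM   Fp, vp, Ft, Tt                 plasma + tubular (filtration)
2CXM   Fp, vp, PS, ve                 plasma <-> interstitium exchange
ETM    Ktrans, ve, vp                 extended Tofts
====== ============================== ==============================

Internal units: flows (Fp, Ft, PS, Ktrans) are fractional rates in 1/s
(fraction of tissue volume per second), volumes (vp, ve) are dimensionless
fractions, mean transit times (Tt) in seconds.  Conversion to the customary
display units (ml/min/100 ml, ml/100 ml, %, s) happens only in
:func:`derive_parameters`.

The compartment models are defined by their residue functions R(t) -- the
fraction of an instantaneous bolus still inside the tissue at time t -- with
c_t = Fp * (R (*) c_a).  The residues here are the closed-form solutions of
the underlying two-compartment ODE systems:

* 2CXM:  vp dc_p/dt = Fp (c_a - c_p) + PS (c_e - c_p);
         ve dc_e/dt = PS (c_p - c_e);  c_t = vp c_p + ve c_e
* 2CUM:  the same with the backflux term PS c_e removed
* 2CFM:  vp dc_p/dt = Fp c_a - (Fp + Ft) c_p;
         vt dc_t'/dt = Ft (c_p - c_t') with Tt = vt / Ft
* ETM:   c_t = vp c_a + Ktrans int_0^t c_a(u) exp(-kep (t - u)) du,
         kep = Ktrans / ve.

Convolutions with exponential kernels use an exact per-interval recursion
for piecewise-linear input (:func:`exp_conv`), which stays stable when the
time constant approaches the grid spacing and supports non-uniform grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import TimeGrid, TimeSeriesCurve
from .errors import InvalidParameterError

MODELS = ("1CP", "2CUM", "2CFM", "2CXM", "ETM")

#: free-parameter names per model, in canonical order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "1CP": ("Fp", "vp"),
    "2CUM": ("Fp", "vp", "PS"),
    "2CFM": ("Fp", "vp", "Ft", "Tt"),
    "2CXM": ("Fp", "vp", "PS", "ve"),
    "ETM": ("Ktrans", "ve", "vp"),
}

#: relative difference below which two time constants are treated as equal
_COALESCENT_RTOL = 1e-8
#: smallest admissible time constant in seconds (guards boundary evaluations)
_TINY_T = 1e-12

# display-unit conversion factors from internal units
RATE_TO_DISPLAY = 6000.0  # 1/s -> ml/min/100 ml
VOLUME_TO_DISPLAY = 100.0  # fraction -> ml/100 ml


def _check_model(model: str) -> str:
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {MODELS}")
    return model


@dataclass
class KineticParams:
    """One model's free-parameter vector with fixed flags and box bounds.

    ``values``, ``fixed``, ``lower`` and ``upper`` are aligned with
    ``PARAM_NAMES[model]``.
    """

    model: str
    values: np.ndarray
    fixed: np.ndarray = field(default=None)
    lower: np.ndarray = field(default=None)
    upper: np.ndarray = field(default=None)

    def __post_init__(self):
        _check_model(self.model)
        names = PARAM_NAMES[self.model]
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if v.size != len(names):
            raise InvalidParameterError(
                f"{self.model} takes {len(names)} parameters {names}, got {v.size}"
            )
        self.values = v
        self.fixed = (
            np.zeros(v.size, dtype=bool)
            if self.fixed is None
            else np.atleast_1d(np.asarray(self.fixed, dtype=bool))
        )
        self.lower = (
            np.zeros(v.size)
            if self.lower is None
            else np.atleast_1d(np.asarray(self.lower, dtype=float))
        )
        self.upper = (
            np.full(v.size, np.inf)
            if self.upper is None
            else np.atleast_1d(np.asarray(self.upper, dtype=float))
        )
        if self.fixed.size != v.size or self.lower.size != v.size or self.upper.size != v.size:
            raise InvalidParameterError("fixed/lower/upper must match the value count")
        if np.any(self.lower > self.upper):
            raise InvalidParameterError("lower bounds exceed upper bounds")
        if np.any(v < self.lower - 1e-300) or np.any(v > self.upper + 1e-300):
            raise InvalidParameterError("parameter values lie outside their bounds")

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model]

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    @property
    def n_free(self) -> int:
        return int((~self.fixed).sum())

    def replace_values(self, values) -> "KineticParams":
        return replace(self, values=np.asarray(values, dtype=float))

    @classmethod
    def from_dict(cls, model: str, values: dict[str, float], **kw) -> "KineticParams":
        _check_model(model)
        names = PARAM_NAMES[model]
        missing = set(names) - set(values)
        if missing:
            raise InvalidParameterError(f"{model}: missing parameters {sorted(missing)}")
        return cls(model, np.array([values[n] for n in names], dtype=float), **kw)


@dataclass(frozen=True)
class DerivedParams:
    """Display-unit output parameter set of one model.

    Only the entries defined for the model are populated.  Entries whose
    defining ratio divides by zero are reported as NaN and listed in
    ``undefined`` rather than raising.
    """

    model: str
    values: dict[str, float]
    units: dict[str, str]
    undefined: frozenset[str] = frozenset()

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# --------------------------------------------------------------------------
# exponential convolution


def exp_conv(T: float, aif: TimeSeriesCurve) -> TimeSeriesCurve:
    """Convolve a curve with the normalized kernel (1/T) exp(-t/T).

    Returns y(t) = int_0^t (1/T) exp(-(t-u)/T) aif(u) du on the aif's grid,
    treating the input as piecewise linear between samples and integrating
    each interval exactly.  Stable for T down to the grid spacing and on
    non-uniform grids.
    """
    if not (np.isfinite(T) and T > 0):
        raise InvalidParameterError(f"exponential time constant must be > 0, got {T}")
    t = aif.grid.t
    a = aif.values
    y = np.zeros_like(a)
    dt = np.diff(t)
    x = dt / T
    E = np.exp(-x)
    # int_0^dt (1/T) e^{-s/T} s ds = T - (T + dt) e^{-dt/T}, written via expm1
    # to avoid cancellation when dt << T
    w_slope = -T * np.expm1(-x) - dt * E
    m = np.diff(a) / dt
    incr = -a[1:] * np.expm1(-x) - m * w_slope
    for i in range(t.size - 1):
        y[i + 1] = y[i] * E[i] + incr[i]
    return aif.with_values(y)


def _cumulative_integral(aif: TimeSeriesCurve) -> np.ndarray:
    """Trapezoidal cumulative integral (exact for piecewise-linear input)."""
    t, a = aif.grid.t, aif.values
    out = np.zeros_like(a)
    out[1:] = np.cumsum(0.5 * (a[1:] + a[:-1]) * np.diff(t))
    return out


# --------------------------------------------------------------------------
# residue functions


def _positive(model: str, **kv: float) -> None:
    for name, v in kv.items():
        if not (np.isfinite(v) and v > 0):
            raise InvalidParameterError(f"{model}: {name} must be > 0, got {v}")


def _nonnegative(model: str, **kv: float) -> None:
    for name, v in kv.items():
        if not (np.isfinite(v) and v >= 0):
            raise InvalidParameterError(f"{model}: {name} must be >= 0, got {v}")


def _exp_decay(t: np.ndarray, T: float) -> np.ndarray:
    T = max(T, _TINY_T)
    return np.exp(-t / T)


def _biexp_components(Fp: float, vp: float, PS: float, ve: float):
    """Eigen-decomposition of the exchange system.

    Returns (coalescent, ...) -- either the two exponential modes
    (False, r_plus, T_plus, r_minus, T_minus) with
    R(t) = r+ e^{-t/T+} + r- e^{-t/T-}, or the degenerate double-root form
    (True, lam, beta) with R(t) = (1 + beta t) e^{lam t}.
    """
    a = (Fp + PS) / vp
    b = PS / vp
    c = PS / ve
    s = a + c
    disc = np.sqrt((a - c) ** 2 + 4.0 * b * c)
    if disc <= _COALESCENT_RTOL * 0.5 * s:
        lam = -0.5 * s
        return True, lam, (lam + c + b)
    lam_p = 0.5 * (-s + disc)  # slow eigenvalue (closer to zero)
    lam_m = 0.5 * (-s - disc)
    p_plus = (lam_p + c) / disc
    r_plus = p_plus + b / disc
    r_minus = 1.0 - r_plus
    return False, r_plus, -1.0 / min(lam_p, -_TINY_T), r_minus, -1.0 / lam_m


def residue(model: str, params: KineticParams, grid: TimeGrid) -> np.ndarray:
    """Sampled residue function R(t) for the convolutional models.

    R(0) = 1 for all four models; ETM has no residue representation here
    (its closed form lives in :func:`forward_model`).
    """
    _check_model(model)
    if params.model != model:
        raise InvalidParameterError(
            f"parameter set is for {params.model}, not {model}"
        )
    t = grid.t - grid.t[0]
    p = params.as_dict()

    if model == "1CP":
        _positive(model, Fp=p["Fp"], vp=p["vp"])
        return _exp_decay(t, p["vp"] / p["Fp"])

    if model == "2CUM":
        _positive(model, Fp=p["Fp"], vp=p["vp"])
        _nonnegative(model, PS=p["PS"])
        Tp = p["vp"] / (p["Fp"] + p["PS"])
        E = p["PS"] / (p["Fp"] + p["PS"])
        return E + (1.0 - E) * _exp_decay(t, Tp)

    if model == "2CFM":
        _positive(model, Fp=p["Fp"], vp=p["vp"], Tt=p["Tt"])
        _nonnegative(model, Ft=p["Ft"])
        Tp = p["vp"] / (p["Fp"] + p["Ft"])
        E = p["Ft"] / (p["Fp"] + p["Ft"])
        Tt = p["Tt"]
        plasma = _exp_decay(t, Tp)
        if abs(Tt - Tp) <= _COALESCENT_RTOL * max(Tt, Tp):
            tubular = E * (t / max(Tp, _TINY_T)) * plasma
        else:
            tubular = E * Tt / (Tt - Tp) * (_exp_decay(t, Tt) - plasma)
        return plasma + tubular

    if model == "2CXM":
        _positive(model, Fp=p["Fp"], vp=p["vp"], ve=p["ve"])
        _nonnegative(model, PS=p["PS"])
        comps = _biexp_components(p["Fp"], p["vp"], p["PS"], p["ve"])
        if comps[0]:
            _, lam, beta = comps
            return (1.0 + beta * t) * np.exp(lam * t)
        _, r_p, T_p, r_m, T_m = comps
        return r_p * _exp_decay(t, T_p) + r_m * _exp_decay(t, T_m)

    raise InvalidParameterError("ETM has no residue-function form; use forward_model")


# --------------------------------------------------------------------------
# forward models


def forward_model(model: str, params: KineticParams, aif: TimeSeriesCurve) -> TimeSeriesCurve:
    """Tissue concentration curve for a model, parameters and plasma AIF.

    The AIF must already be haematocrit-corrected (plasma concentration).
    Convolutional models return c_t = Fp * (R (*) c_a); the ETM uses its
    closed form.  The output is linear and time-invariant in the AIF.
    """
    _check_model(model)
    if params.model != model:
        raise InvalidParameterError(f"parameter set is for {params.model}, not {model}")
    p = params.as_dict()
    t = aif.grid.t - aif.grid.t[0]

    if model == "ETM":
        _nonnegative(model, Ktrans=p["Ktrans"], vp=p["vp"])
        ct = p["vp"] * aif.values
        if p["Ktrans"] > 0:
            _positive(model, ve=p["ve"])
            kep = p["Ktrans"] / p["ve"]
            if kep < 1.0 / 1e9:  # effectively no efflux: pure accumulation
                ct = ct + p["Ktrans"] * _cumulative_integral(aif)
            else:
                ct = ct + p["ve"] * exp_conv(1.0 / kep, aif).values
        return aif.with_values(ct, label=f"{model} model")

    if model == "1CP":
        _positive(model, Fp=p["Fp"], vp=p["vp"])
        Tp = p["vp"] / p["Fp"]
        return aif.with_values(p["vp"] * exp_conv(max(Tp, _TINY_T), aif).values,
                               label=f"{model} model")

    if model == "2CUM":
        _positive(model, Fp=p["Fp"], vp=p["vp"])
        _nonnegative(model, PS=p["PS"])
        Tp = p["vp"] / (p["Fp"] + p["PS"])
        E = p["PS"] / (p["Fp"] + p["PS"])
        conv = (1.0 - E) * Tp * exp_conv(max(Tp, _TINY_T), aif).values
        ct = p["Fp"] * (E * _cumulative_integral(aif) + conv)
        return aif.with_values(ct, label=f"{model} model")

    if model == "2CFM":
        _positive(model, Fp=p["Fp"], vp=p["vp"], Tt=p["Tt"])
        _nonnegative(model, Ft=p["Ft"])
        Tp = p["vp"] / (p["Fp"] + p["Ft"])
        E = p["Ft"] / (p["Fp"] + p["Ft"])
        Tt = p["Tt"]
        Tp_s = max(Tp, _TINY_T)
        plasma = Tp * exp_conv(Tp_s, aif).values
        if abs(Tt - Tp) <= _COALESCENT_RTOL * max(Tt, Tp):
            # (t/Tp) e^{-t/Tp} is the Gamma(2) kernel: apply the recursion twice
            tubular = E * Tp * exp_conv(Tp_s, exp_conv(Tp_s, aif)).values
        else:
            tubular = (
                E * Tt / (Tt - Tp)
                * (Tt * exp_conv(max(Tt, _TINY_T), aif).values - plasma)
            )
        return aif.with_values(p["Fp"] * (plasma + tubular), label=f"{model} model")

    # 2CXM
    _positive(model, Fp=p["Fp"], vp=p["vp"], ve=p["ve"])
    _nonnegative(model, PS=p["PS"])
    comps = _biexp_components(p["Fp"], p["vp"], p["PS"], p["ve"])
    if comps[0]:
        _, lam, beta = comps
        T = -1.0 / min(lam, -1.0 / 1e12)
        base = T * exp_conv(T, aif).values
        gamma2 = beta * T * T * exp_conv(T, exp_conv(T, aif)).values
        ct = p["Fp"] * (base + gamma2)
    else:
        _, r_p, T_p, r_m, T_m = comps
        ct = p["Fp"] * (
            r_p * T_p * exp_conv(T_p, aif).values
            + r_m * T_m * exp_conv(max(T_m, _TINY_T), aif).values
        )
    return aif.with_values(ct, label=f"{model} model")


# --------------------------------------------------------------------------
# derived (display) parameters


def _ratio(num: float, den: float):
    """num/den, or (NaN, True) when the denominator vanishes."""
    if den == 0:
        return float("nan"), True
    return num / den, False


_UNITS = {
    "plasma_flow": "ml/min/100 ml",
    "plasma_mtt": "s",
    "plasma_volume": "ml/100 ml",
    "interstitial_mtt": "s",
    "interstitial_volume": "ml/100 ml",
    "tubular_mtt": "s",
    "tubular_flow": "ml/min/100 ml",
    "extraction_fraction": "%",
    "ps": "ml/min/100 ml",
    "ktrans": "ml/min/100 ml",
}


def derive_parameters(model: str, fitted: KineticParams) -> DerivedParams:
    """Full display-unit output set for a model's fitted parameters.

    Conversions: fractional rates (1/s) x 6000 -> ml/min/100 ml; volume
    fractions x 100 -> ml/100 ml; extraction fraction as %.  Ktrans = E * Fp
    for the compartment models; the ETM reports PS = Ktrans by definition.
    Ratios with a vanishing denominator are flagged undefined (NaN), never
    raised.
    """
    _check_model(model)
    if fitted.model != model:
        raise InvalidParameterError(f"parameter set is for {fitted.model}, not {model}")
    p = fitted.as_dict()
    out: dict[str, float] = {}
    undef: set[str] = set()

    def put(name, value, is_undef=False):
        out[name] = float(value)
        if is_undef or not np.isfinite(value):
            undef.add(name)

    if model == "1CP":
        put("plasma_flow", p["Fp"] * RATE_TO_DISPLAY)
        mtt, bad = _ratio(p["vp"], p["Fp"])
        put("plasma_mtt", mtt, bad)
        put("plasma_volume", p["vp"] * VOLUME_TO_DISPLAY)

    elif model in ("2CUM", "2CXM"):
        Fp, vp, PS = p["Fp"], p["vp"], p["PS"]
        put("plasma_flow", Fp * RATE_TO_DISPLAY)
        mtt, bad = _ratio(vp, Fp + PS)
        put("plasma_mtt", mtt, bad)
        put("plasma_volume", vp * VOLUME_TO_DISPLAY)
        E, bad = _ratio(PS, Fp + PS)
        put("extraction_fraction", E * 100.0, bad)
        put("ps", PS * RATE_TO_DISPLAY)
        put("ktrans", E * Fp * RATE_TO_DISPLAY, bad)
        if model == "2CXM":
            ve = p["ve"]
            imtt, bad = _ratio(ve, PS)
            put("interstitial_mtt", imtt, bad)
            put("interstitial_volume", ve * VOLUME_TO_DISPLAY)

    elif model == "2CFM":
        Fp, vp, Ft, Tt = p["Fp"], p["vp"], p["Ft"], p["Tt"]
        put("plasma_flow", Fp * RATE_TO_DISPLAY)
        mtt, bad = _ratio(vp, Fp + Ft)
        put("plasma_mtt", mtt, bad)
        put("plasma_volume", vp * VOLUME_TO_DISPLAY)
        put("tubular_mtt", Tt)
        put("tubular_flow", Ft * RATE_TO_DISPLAY)
        E, bad = _ratio(Ft, Fp + Ft)
        put("extraction_fraction", E * 100.0, bad)
        # the PS display slot of the filtration model carries the tubular flow
        put("ps", Ft * RATE_TO_DISPLAY)
        put("ktrans", E * Fp * RATE_TO_DISPLAY, bad)

    else:  # ETM
        Kt, ve, vp = p["Ktrans"], p["ve"], p["vp"]
        put("plasma_volume", vp * VOLUME_TO_DISPLAY)
        put("interstitial_volume", ve * VOLUME_TO_DISPLAY)
        imtt, bad = _ratio(ve, Kt)
        put("interstitial_mtt", imtt, bad)
        put("ps", Kt * RATE_TO_DISPLAY)  # PS = Ktrans by definition
        put("ktrans", Kt * RATE_TO_DISPLAY)

    units = {k: _UNITS[k] for k in out}
    return DerivedParams(model=model, values=out, units=units, undefined=frozenset(undef))
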