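"""Bounded nonlinear least-squares fitting of kinetic models to curves.

The central object is :class:`KineticCurveFit`, a scikit-learn style
estimator: construct it with a model name and fit settings, call
``fit(tissue, aif)``, and read the fitted quantities from trailing-underscore
attributes (``params_``, ``derived_``, ``chi2_``, ``aicc_`` ...).  The
module-level functions :func:`fit_curve`, :func:`compare_models` and
:func:`compare_rois` are thin wrappers over it.

The optimizer is scipy's bounded trust-region-reflective least-squares
solver, a box-constrained Levenberg--Marquardt-type method: it minimizes the
unweighted sum of squared residuals between the model curve and the data,
honours per-parameter [lower, upper] boxes, and holds parameters flagged as
fixed exactly at their initial value.

Goodness of fit is reported as the final chi-square (unweighted SSR) and the
corrected Akaike information criterion

    AIC  = n ln(chi2 / n) + 2 k
    AICc = AIC + 2 k (k + 1) / (n - k - 1)

with n data points and k free parameters.  When several models are compared,
each result is annotated with the relative information loss
exp((AICc_i - AICc_min) / 2), which is 1 for the best-ranked model and >= 1
for every other.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .curves import TimeSeriesCurve, require_same_grid
from .errors import ConfigError, DegenerateFitError, PerfkitError
from .kinetics import (
    MODELS,
    PARAM_NAMES,
    DerivedParams,
    KineticParams,
    derive_parameters,
    forward_model,
)
from .prep import PrepConfig, RoiMask, blood_to_plasma, prepare_curve, roi_mean_curve
from .volume import Dynamic4D

#: physiologic mid-range initial values (internal units: 1/s, fractions, s)
DEFAULT_INITIALS = {
    "Fp": 0.01,
    "vp": 0.05,
    "ve": 0.2,
    "PS": 0.002,
    "Ft": 0.002,
    "Tt": 120.0,
    "Ktrans": 0.002,
}

#: parameters that must stay strictly positive inside the model equations
_STRICT_POSITIVE = {
    "1CP": ("Fp", "vp"),
    "2CUM": ("Fp", "vp"),
    "2CFM": ("Fp", "vp", "Tt"),
    "2CXM": ("Fp", "vp", "ve"),
    "ETM": ("ve",),
}
_EVAL_EPS = 1e-12

#: volume fractions are additionally bounded above by 1
_VOLUME_PARAMS = ("vp", "ve")


def default_params(model: str, init: dict | None = None, fixed: dict | None = None,
                   lower: dict | None = None, upper: dict | None = None) -> KineticParams:
    """Default initial values, fixed flags and box bounds for a model.

    Defaults: every parameter starts at its physiologic mid-range value,
    no parameter is fixed, rates are bounded to [0, inf), volume fractions
    to [0, 1], mean transit times to (0, inf).
    """
    names = PARAM_NAMES[model]
    init = init or {}
    fixed = fixed or {}
    lower = lower or {}
    upper = upper or {}
    values = np.array([float(init.get(n, DEFAULT_INITIALS[n])) for n in names])
    fx = np.array([bool(fixed.get(n, False)) for n in names])
    lo = np.array([float(lower.get(n, 0.0)) for n in names])
    up = np.array(
        [float(upper.get(n, 1.0 if n in _VOLUME_PARAMS else np.inf)) for n in names]
    )
    return KineticParams(model, values, fx, lo, up)


@dataclass
class FitConfig:
    """Fit-algorithm settings, shared by all models of one analysis.

    ``initials``/``fixed``/``lower``/``upper`` are per-model dicts of
    per-parameter overrides, e.g. ``initials={"2CXM": {"Fp": 0.02}}``.
    """

    max_iterations: int = 200
    cost_tol: float = 1e-10
    step_tol: float = 1e-10
    restarts: int = 0
    seed: int = 0
    initials: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    lower: dict = field(default_factory=dict)
    upper: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if not (self.cost_tol > 0 and self.step_tol > 0):
            raise ConfigError("tolerances must be > 0")
        if self.restarts < 0:
            raise ConfigError("restarts must be >= 0")

    def params_for(self, model: str) -> KineticParams:
        return default_params(
            model,
            init=self.initials.get(model),
            fixed=self.fixed.get(model),
            lower=self.lower.get(model),
            upper=self.upper.get(model),
        )

    def to_dict(self) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "cost_tol": self.cost_tol,
            "step_tol": self.step_tol,
            "restarts": self.restarts,
            "seed": self.seed,
            "initials": self.initials,
            "fixed": self.fixed,
            "lower": self.lower,
            "upper": self.upper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of fitting one model to one curve."""

    model: str
    params: KineticParams
    derived: DerivedParams
    chi2: float
    aic: float
    aicc: float
    n: int
    k: int
    converged: bool
    iterations: int
    curve: TimeSeriesCurve | None
    label: str = ""
    info_loss: float | None = None
    error: str | None = None  # set when the fit itself failed

    @property
    def aicc_defined(self) -> bool:
        return not math.isnan(self.aicc)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "label": self.label,
            "fitted_parameters": self.params.as_dict() if self.params is not None else None,
            "fixed": self.params.fixed.tolist() if self.params is not None else None,
            "derived_parameters": self.derived.values if self.derived is not None else None,
            "units": self.derived.units if self.derived is not None else None,
            "undefined": sorted(self.derived.undefined) if self.derived is not None else [],
            "final_chi_square": self.chi2,
            "aic": self.aic,
            "corrected_aic": self.aicc,
            "n_points": self.n,
            "n_free_parameters": self.k,
            "converged": self.converged,
            "iterations": self.iterations,
            "relative_information_loss": self.info_loss,
            "error": self.error,
        }


# --------------------------------------------------------------------------
# goodness of fit


def chi_square(data, model_curve) -> float:
    """Unweighted sum of squared residuals."""
    d = np.asarray(data, dtype=float)
    m = np.asarray(model_curve, dtype=float)
    if d.shape != m.shape:
        raise ConfigError(f"length mismatch: data {d.shape} vs model {m.shape}")
    return float(np.sum((d - m) ** 2))


def aic(chi2: float, n: int, k: int) -> float:
    """Least-squares AIC; -inf for a perfect fit, NaN when undefined."""
    if chi2 < 0 or n < 1:
        return float("nan")
    if chi2 == 0.0:
        return float("-inf")
    return n * math.log(chi2 / n) + 2.0 * k


def aicc(chi2: float, n: int, k: int) -> float:
    """Corrected AIC; NaN (flagged, not raised) when n <= k + 1."""
    if n <= k + 1:
        return float("nan")
    base = aic(chi2, n, k)
    if math.isnan(base) or math.isinf(base):
        return base
    return base + 2.0 * k * (k + 1) / (n - k - 1)


def relative_information_loss(aic_i: float, aic_min: float) -> float:
    """exp((AIC_i - AIC_min)/2): 1 for the best model, >= 1 otherwise."""
    if aic_i == aic_min:  # covers the -inf perfect-fit pair
        return 1.0
    try:
        return float(math.exp((aic_i - aic_min) / 2.0))
    except OverflowError:
        return float("inf")


# --------------------------------------------------------------------------
# the estimator


def _safe_forward(model: str, values: np.ndarray, template: KineticParams,
                  aif: TimeSeriesCurve) -> np.ndarray:
    """Evaluate the forward model with boundary values nudged off zero.

    The box bounds admit 0 for flows and volumes; the model equations divide
    by some of them, so strictly-positive parameters are clipped to a tiny
    epsilon for evaluation only (returned parameters are never clipped).
    """
    names = PARAM_NAMES[model]
    v = np.array(values, dtype=float)
    for name in _STRICT_POSITIVE[model]:
        i = names.index(name)
        v[i] = max(v[i], _EVAL_EPS)
    p = KineticParams(model, v, lower=np.full(v.size, -np.inf),
                      upper=np.full(v.size, np.inf))
    return forward_model(model, p, aif).values


class KineticCurveFit(BaseEstimator):
    """Fit one tracer-kinetic model to a tissue concentration curve.

    Parameters
    ----------
    model : {"1CP", "2CUM", "2CFM", "2CXM", "ETM"}
    init, fixed, lower, upper : dict, optional
        Per-parameter overrides of the default initial values, fixed flags
        and box bounds (internal units).
    max_iterations : int
        Iteration budget of the least-squares solver.
    cost_tol, step_tol : float
        Termination tolerances on the cost decrease and the parameter step.
    restarts : int
        Number of seeded random restarts from perturbed initial values; the
        best final cost wins.  0 fits once from the configured initials.
    seed : int
        Seed for the restart perturbations (ignored when restarts == 0).

    Attributes
    ----------
    params_ : KineticParams
        Fitted parameter vector (internal units), bounds-respecting; fixed
        parameters are returned bit-identical to their initial value.
    derived_ : DerivedParams
        Display-unit parameter set of the model.
    chi2_, aic_, aicc_ : float
        Final chi-square and (corrected) Akaike information criterion.
    n_, k_ : int
        Number of data points and of free parameters.
    converged_ : bool
        False when the iteration budget was exhausted (never raised).
    n_iter_ : int
        Residual evaluations spent.
    curve_ : TimeSeriesCurve
        Fitted model curve on the data grid.
    result_ : FitResult
        All of the above bundled for reporting.
    """

    def __init__(self, model: str = "2CXM", init: dict | None = None,
                 fixed: dict | None = None, lower: dict | None = None,
                 upper: dict | None = None, max_iterations: int = 200,
                 cost_tol: float = 1e-10, step_tol: float = 1e-10,
                 restarts: int = 0, seed: int = 0):
        self.model = model
        self.init = init
        self.fixed = fixed
        self.lower = lower
        self.upper = upper
        self.max_iterations = max_iterations
        self.cost_tol = cost_tol
        self.step_tol = step_tol
        self.restarts = restarts
        self.seed = seed

    # estimator API ---------------------------------------------------------

    def fit(self, tissue: TimeSeriesCurve, aif: TimeSeriesCurve) -> "KineticCurveFit":
        """Fit the model to ``tissue`` given the plasma AIF ``aif``."""
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}")
        require_same_grid(tissue, aif)
        start = default_params(self.model, self.init, self.fixed, self.lower, self.upper)
        free = ~start.fixed
        if not free.any():
            raise DegenerateFitError(f"{self.model}: all parameters are fixed")

        names = PARAM_NAMES[self.model]
        data = tissue.values
        full = start.values.copy()

        def assemble(x_free: np.ndarray) -> np.ndarray:
            v = full.copy()
            v[free] = x_free
            return v

        def residuals(x_free: np.ndarray) -> np.ndarray:
            return _safe_forward(self.model, assemble(x_free), start, aif) - data

        lb, ub = start.lower[free], start.upper[free]
        x0 = np.clip(start.values[free], lb, ub)
        starts = [x0]
        if self.restarts:
            rng = np.random.default_rng(self.seed)
            for _ in range(int(self.restarts)):
                fac = rng.uniform(0.5, 1.5, size=x0.size)
                starts.append(np.clip(x0 * fac, lb, ub))

        best = None
        for xs in starts:
            res = least_squares(
                residuals, xs, bounds=(lb, ub), method="trf",
                ftol=self.cost_tol, xtol=self.step_tol, gtol=1e-12,
                max_nfev=int(self.max_iterations) * (int(free.sum()) + 1),
            )
            if best is None or res.cost < best.cost:
                best = res

        fitted_values = assemble(best.x)
        # bounds can be overshot by floating-point noise; clamp exactly
        fitted_values[free] = np.clip(fitted_values[free], lb, ub)
        fitted = KineticParams(self.model, fitted_values, start.fixed,
                               start.lower, start.upper)
        model_vals = _safe_forward(self.model, fitted_values, start, aif)
        curve = tissue.with_values(model_vals, label=f"{self.model} fit")

        self.params_ = fitted
        self.derived_ = derive_parameters(self.model, fitted)
        self.chi2_ = chi_square(data, model_vals)
        self.n_ = int(data.size)
        self.k_ = int(free.sum())
        self.aic_ = aic(self.chi2_, self.n_, self.k_)
        self.aicc_ = aicc(self.chi2_, self.n_, self.k_)
        self.converged_ = bool(best.status > 0)
        self.n_iter_ = int(best.nfev)
        self.curve_ = curve
        self._aif = aif
        self.result_ = FitResult(
            model=self.model, params=fitted, derived=self.derived_,
            chi2=self.chi2_, aic=self.aic_, aicc=self.aicc_, n=self.n_,
            k=self.k_, converged=self.converged_, iterations=self.n_iter_,
            curve=curve, label=tissue.label,
        )
        return self

    def predict(self, aif: TimeSeriesCurve | None = None) -> np.ndarray:
        """Model curve for the fitted parameters (on a new AIF if given)."""
        if not hasattr(self, "params_"):
            raise ConfigError("estimator is not fitted yet")
        a = self._aif if aif is None else aif
        return _safe_forward(self.model, self.params_.values, self.params_, a)


# --------------------------------------------------------------------------
# module-level operations


def fit_curve(model: str, tissue: TimeSeriesCurve, aif: TimeSeriesCurve,
              config: FitConfig | None = None) -> FitResult:
    """Fit one model to one prepared curve; see :class:`KineticCurveFit`."""
    config = config or FitConfig()
    est = KineticCurveFit(
        model=model,
        init=config.initials.get(model),
        fixed=config.fixed.get(model),
        lower=config.lower.get(model),
        upper=config.upper.get(model),
        max_iterations=config.max_iterations,
        cost_tol=config.cost_tol,
        step_tol=config.step_tol,
        restarts=config.restarts,
        seed=config.seed,
    )
    est.fit(tissue, aif)
    return est.result_


def ranking_chi2_floor(data: np.ndarray) -> float:
    """Numerical chi-square floor for model ranking.

    Residuals below ~1e-8 of the data scale are numerical noise; two models
    whose SSR both fall below this floor fit the data equally well, and the
    ranking then falls back to the free-parameter count.
    """
    scale = float(np.max(np.abs(data))) if np.asarray(data).size else 0.0
    return np.asarray(data).size * (1e-8 * max(scale, 1e-300)) ** 2


def _ranked(results: list[FitResult], data: np.ndarray) -> list[FitResult]:
    floor = ranking_chi2_floor(data)
    keyed = []
    for r in results:
        if r.error is not None or r.params is None:
            keyed.append((float("inf"), 99, r.model, r, float("nan")))
            continue
        a = aicc(max(r.chi2, floor), r.n, r.k)
        if math.isnan(a):
            a = float("inf")
        keyed.append((a, r.k, r.model, r, a))
    keyed.sort(key=lambda item: item[:3])
    finite = [item[4] for item in keyed if not math.isnan(item[4]) and item[0] != float("inf")]
    a_min = min(finite) if finite else float("nan")
    out = []
    for a_sort, _, _, r, a_val in keyed:
        loss = relative_information_loss(a_val, a_min) if not math.isnan(a_val) and a_sort != float("inf") else float("nan")
        r.info_loss = loss
        out.append(r)
    return out


def compare_models(tissue: TimeSeriesCurve, aif: TimeSeriesCurve,
                   config: FitConfig | None = None,
                   models: tuple[str, ...] = MODELS) -> list[FitResult]:
    """Fit several models to the same curve and rank them by AICc.

    Results are sorted by AICc ascending; ties (equal AICc, including two
    numerically perfect fits) go to the model with fewer free parameters,
    then to model-name order.  Each result carries the relative information
    loss exp((AICc_i - AICc_min)/2).  Per-model failures are returned as
    flagged entries; the loop never aborts.
    """
    if len(models) < 2:
        raise ConfigError("model comparison needs at least 2 models")
    config = config or FitConfig()
    results = []
    for m in models:
        try:
            results.append(fit_curve(m, tissue, aif, config))
        except PerfkitError as exc:
            results.append(FitResult(
                model=m, params=None, derived=None, chi2=float("inf"),
                aic=float("nan"), aicc=float("nan"), n=tissue.grid.n, k=0,
                converged=False, iterations=0, curve=None,
                label=tissue.label, error=str(exc),
            ))
    return _ranked(results, tissue.values)


def resolve_aif(volume: Dynamic4D, aif, prep: PrepConfig) -> TimeSeriesCurve:
    """Turn an AIF source (curve or arterial ROI) into a plasma AIF curve.

    An ROI is averaged, normalized with the shared preparation settings, and
    haematocrit-corrected; a curve is taken as already being plasma
    concentration.
    """
    if isinstance(aif, TimeSeriesCurve):
        return aif
    if isinstance(aif, RoiMask):
        blood = prepare_curve(roi_mean_curve(volume, aif), prep)
        return blood_to_plasma(blood, prep.hct_a)
    raise ConfigError(f"AIF source must be a curve or an ROI, got {type(aif).__name__}")


def compare_rois(volume: Dynamic4D, rois: list[RoiMask], model: str, aif,
                 prep: PrepConfig | None = None,
                 config: FitConfig | None = None) -> list[FitResult]:
    """Fit one model to each tissue ROI with shared AIF and prep settings."""
    if not rois:
        raise ConfigError("compare_rois needs at least one ROI")
    prep = prep or PrepConfig()
    config = config or FitConfig()
    aif_curve = resolve_aif(volume, aif, prep)
    results = []
    for roi in rois:
        tissue = prepare_curve(roi_mean_curve(volume, roi), prep)
        r = fit_curve(model, tissue, aif_curve, config)
        r.label = roi.label
        results.append(r)
    return results
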