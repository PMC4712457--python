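"""Synthetic test-data generator with known ground truth.

Real DCE-MRI validation data for this kind of software are not publicly
available, so every test input is generated here: a parametric population-
shaped arterial input function, forward-simulated tissue curves for each
kinetic model with known parameters, additive Gaussian noise, and a small
4D reference object -- one 8 x 4-pixel slice over 100 time points whose
upper half holds the (blood) AIF and whose lower half holds simulated
tissue.  Everything is reproducible from a truth manifest and a seed alone.

Defaults emulate a clinical bolus-injection study: 1.5 s temporal
resolution, bolus arrival at 10 s with a 5 s linear upslope into a
biexponential washout, and a peak plasma concentration of about 5 a.u.
after haematocrit correction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .curves import TimeGrid, TimeSeriesCurve
from .errors import ConfigError, InvalidParameterError
from .kinetics import MODELS, KineticParams, forward_model
from .volume import Dynamic4D

AIF_SHAPES = ("biexponential_bolus", "gamma_variate")

#: default blood-curve bolus: peak 2.75 a.u. -> plasma peak 5 a.u. at Hct 0.45
DEFAULT_AIF = {
    "shape": "biexponential_bolus",
    "params": {
        "amplitude": 2.75,
        "t0": 10.0,
        "rise": 5.0,
        "frac_fast": 0.8,
        "tau_fast": 15.0,
        "tau_slow": 300.0,
    },
}

#: ground-truth tissue parameters per model (internal units), deliberately
#: away from the fitter's default initial values
DEFAULT_TRUTH_PARAMS = {
    "1CP": {"Fp": 0.015, "vp": 0.08},
    "2CUM": {"Fp": 0.015, "vp": 0.08, "PS": 0.003},
    "2CFM": {"Fp": 0.015, "vp": 0.08, "Ft": 0.004, "Tt": 90.0},
    "2CXM": {"Fp": 0.015, "vp": 0.08, "PS": 0.003, "ve": 0.25},
    "ETM": {"Ktrans": 0.003, "ve": 0.25, "vp": 0.04},
}

REFERENCE_SHAPE = (8, 4)  # x (width) by y (rows); rows 0-1 AIF, rows 2-3 tissue
REFERENCE_N_TIMEPOINTS = 100
DEFAULT_DT = 1.5


def make_aif(shape: str, params: dict, grid: TimeGrid) -> TimeSeriesCurve:
    """Parametric AIF: nonnegative, zero before bolus arrival ``t0``.

    ``biexponential_bolus``: linear upslope over ``rise`` seconds to
    ``amplitude``, then a two-exponential washout (fractions ``frac_fast``
    at ``tau_fast`` and the rest at ``tau_slow``), continuous at the peak.

    ``gamma_variate``: amplitude-normalized gamma variate
    A ((t-t0)/(alpha beta))^alpha exp(alpha - (t-t0)/beta) with its mode at
    t0 + alpha * beta.
    """
    if shape not in AIF_SHAPES:
        raise ConfigError(f"unknown AIF shape {shape!r}; choose from {AIF_SHAPES}")
    t = grid.t
    A = float(params.get("amplitude", 1.0))
    if A < 0:
        raise InvalidParameterError("AIF amplitude must be >= 0")
    t0 = float(params.get("t0", 10.0))
    y = np.zeros_like(t)
    if shape == "biexponential_bolus":
        rise = float(params.get("rise", 5.0))
        f = float(params.get("frac_fast", 0.8))
        tau1 = float(params.get("tau_fast", 15.0))
        tau2 = float(params.get("tau_slow", 300.0))
        if rise <= 0 or tau1 <= 0 or tau2 <= 0 or not (0 <= f <= 1):
            raise InvalidParameterError(f"invalid bolus parameters {params}")
        up = (t > t0) & (t <= t0 + rise)
        y[up] = A * (t[up] - t0) / rise
        down = t > t0 + rise
        td = t[down] - (t0 + rise)
        y[down] = A * (f * np.exp(-td / tau1) + (1 - f) * np.exp(-td / tau2))
    else:
        alpha = float(params.get("alpha", 3.0))
        beta = float(params.get("beta", 4.0))
        if alpha <= 0 or beta <= 0:
            raise InvalidParameterError(f"invalid gamma-variate parameters {params}")
        late = t > t0
        x = (t[late] - t0) / (alpha * beta)
        y[late] = A * np.power(x, alpha) * np.exp(alpha * (1.0 - x))
    return TimeSeriesCurve(grid, y, label=f"{shape} AIF")


def simulate_tissue(model: str, params: KineticParams | dict, aif: TimeSeriesCurve,
                    noise_sd: float = 0.0, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> TimeSeriesCurve:
    """Forward-model tissue curve plus i.i.d. Gaussian noise.

    ``noise_sd = 0`` returns exactly the forward model; with the same seed
    the noisy curve is bit-reproducible.
    """
    if isinstance(params, dict):
        params = KineticParams.from_dict(model, params)
    clean = forward_model(model, params, aif)
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if noise_sd == 0:
        return clean
    if rng is None:
        rng = np.random.default_rng(seed)
    return clean.with_values(clean.values + rng.normal(0.0, noise_sd, clean.grid.n),
                             label=f"{model} + noise")


@dataclass
class PhantomTruth:
    """Complete generating description of a reference object.

    ``regions`` assign a model and parameter set to inclusive row ranges of
    the lower (tissue) half; rows 0-1 always carry the blood AIF.
    """

    regions: list[dict] = field(default_factory=lambda: [
        {"label": "tissue", "model": "2CXM",
         "params": dict(DEFAULT_TRUTH_PARAMS["2CXM"]), "rows": [2, 3]},
    ])
    aif: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_AIF)))
    noise_sd: float = 0.0
    seed: int = 0
    hct_a: float = 0.45
    n_timepoints: int = REFERENCE_N_TIMEPOINTS
    dt: float = DEFAULT_DT
    baseline_offset: float = 0.0
    shape: tuple[int, int] = REFERENCE_SHAPE

    def __post_init__(self):
        self.shape = tuple(self.shape)
        if self.shape != REFERENCE_SHAPE:
            raise ConfigError(f"reference object layout must be {REFERENCE_SHAPE}, got {self.shape}")
        if not self.regions:
            raise ConfigError("at least one tissue region is required")
        covered = set()
        for r in self.regions:
            if r["model"] not in MODELS:
                raise ConfigError(f"unknown model {r['model']!r} in region {r}")
            r0, r1 = r["rows"]
            if not (2 <= r0 <= r1 <= 3):
                raise ConfigError(
                    f"tissue region rows {r['rows']} must lie in the lower half (rows 2-3)"
                )
            covered.update(range(r0, r1 + 1))
        if covered != {2, 3}:
            raise ConfigError("tissue regions must cover rows 2-3 exactly")

    def grid(self) -> TimeGrid:
        return TimeGrid.uniform(self.n_timepoints, self.dt)

    def to_dict(self) -> dict:
        return {
            "regions": self.regions,
            "aif": self.aif,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "hct_a": self.hct_a,
            "n_timepoints": self.n_timepoints,
            "dt": self.dt,
            "baseline_offset": self.baseline_offset,
            "shape": list(self.shape),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "PhantomTruth":
        return cls.from_dict(json.loads(s))


def default_truth(model: str = "2CXM", noise_sd: float = 0.0, seed: int = 0,
                  two_regions: bool = False, baseline_offset: float = 0.0) -> PhantomTruth:
    """Convenience truth: one (or two) tissue regions of the given model."""
    if two_regions:
        a = dict(DEFAULT_TRUTH_PARAMS[model])
        b = dict(DEFAULT_TRUTH_PARAMS[model])
        flow = "Ktrans" if model == "ETM" else "Fp"
        b[flow] = 2.0 * b[flow]
        regions = [
            {"label": "tissue_low", "model": model, "params": a, "rows": [2, 2]},
            {"label": "tissue_high", "model": model, "params": b, "rows": [3, 3]},
        ]
    else:
        regions = [{"label": "tissue", "model": model,
                    "params": dict(DEFAULT_TRUTH_PARAMS[model]), "rows": [2, 3]}]
    return PhantomTruth(regions=regions, noise_sd=noise_sd, seed=seed,
                        baseline_offset=baseline_offset)


def make_reference_object(truth: PhantomTruth | None = None) -> tuple[Dynamic4D, PhantomTruth]:
    """Build the 8 x 4 x 1 x 100 reference object from a truth manifest.

    The upper half (rows 0-1) holds the arterial *blood* curve -- the
    analysis pipeline applies the haematocrit correction itself -- and the
    lower half holds tissue curves simulated from the plasma AIF.  With
    ``noise_sd = 0`` all AIF-half voxels are identical.
    """
    truth = truth or PhantomTruth()
    grid = truth.grid()
    nx, ny = truth.shape
    aif_blood = make_aif(truth.aif["shape"], truth.aif["params"], grid)
    aif_plasma = aif_blood.with_values(aif_blood.values / (1.0 - truth.hct_a))

    data = np.zeros((nx, ny, 1, grid.n))
    data[:, 0:2, 0, :] = aif_blood.values  # upper half: vessel
    for region in truth.regions:
        params = KineticParams.from_dict(region["model"], region["params"])
        ct = forward_model(region["model"], params, aif_plasma)
        r0, r1 = region["rows"]
        data[:, r0 : r1 + 1, 0, :] = ct.values
    data += truth.baseline_offset
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        data += rng.normal(0.0, truth.noise_sd, data.shape)

    vol = Dynamic4D(data, grid, meta={
        "source": "perfkit phantom",
        "truth_seed": truth.seed,
        "noise_sd": truth.noise_sd,
    })
    return vol, truth
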