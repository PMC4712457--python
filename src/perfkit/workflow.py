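"""End-to-end analysis sessions: prep -> fit -> report.

A :class:`Session` captures every user-settable option of one analysis --
input reference, preparation settings, model choice, ROIs, AIF source, fit
configuration and output prefix -- and is fully JSON-serializable, so any
result artifact can be regenerated from the saved session plus the input
data.  The three drivers mirror the interactive workflow: ROI analysis,
parametric maps, and multi-model comparison with shared settings.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dicom_io import write_map_dicom, write_report
from .errors import ConfigError, PerfkitError
from .fitting import FitConfig, compare_models, compare_rois, resolve_aif
from .mapping import BoundingBox, compare_models_maps, fit_maps
from .prep import PrepConfig, RoiMask, trim_and_slice
from .volume import Dynamic4D


def _roi_from_spec(spec: dict) -> RoiMask:
    return RoiMask(label=spec.get("label", "roi"), slice_index=int(spec["slice"]),
                   rect=tuple(int(v) for v in spec["rect"]))


@dataclass
class Session:
    """All settings of one analysis run (serializable)."""

    input: str | None = None
    prep: PrepConfig = field(default_factory=PrepConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    model: str = "2CXM"
    models: list[str] = field(default_factory=list)
    aif_roi: dict | None = None          # {"label", "slice", "rect": [x0,y0,x1,y1]}
    tissue_rois: list[dict] = field(default_factory=list)
    bbox: list[int] | None = None        # [x0, y0, x1, y1]
    prefix: str = "perfkit"
    out_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "prep": self.prep.to_dict(),
            "fit": self.fit.to_dict(),
            "model": self.model,
            "models": list(self.models),
            "aif_roi": self.aif_roi,
            "tissue_rois": self.tissue_rois,
            "bbox": self.bbox,
            "prefix": self.prefix,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        d = dict(d)
        d["prep"] = PrepConfig.from_dict(d.get("prep", {}))
        d["fit"] = FitConfig.from_dict(d.get("fit", {}))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "Session":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def settings_hash(self) -> str:
        """Hash over the shared prep + fit settings (model excluded)."""
        blob = json.dumps({"prep": self.prep.to_dict(), "fit": self.fit.to_dict()},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _step(name: str):
    class _StepContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, PerfkitError):
                raise type(exc)(f"[step: {name}] {exc}") from exc
            return False

    return _StepContext()


def _prepare_inputs(session: Session, volume: Dynamic4D):
    with _step("trim/slice selection"):
        vol = trim_and_slice(volume, session.prep)
    with _step("AIF extraction"):
        if session.aif_roi is None:
            raise ConfigError("session has no AIF source")
        aif = resolve_aif(vol, _roi_from_spec(session.aif_roi), session.prep)
    return vol, aif


def _results_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"label": r.label, "model": r.model, "chi2": r.chi2,
               "aicc": r.aicc, "converged": r.converged,
               "info_loss": r.info_loss}
        if r.derived is not None:
            for nm, v in r.derived.values.items():
                row[f"{nm} [{r.derived.units[nm]}]"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _plot_fits(results, out_path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for r in results:
        if r.curve is None:
            continue
        ax.plot(r.curve.t, r.curve.values, "-", label=f"{r.model} {r.label} fit")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("concentration [a.u.]")
    ax.legend(fontsize=7)
    fig.savefig(out_path, dpi=120)


def run_roi_analysis(session: Session, volume: Dynamic4D):
    """ROI mode: average each tissue ROI, fit the selected model, report."""
    vol, aif = _prepare_inputs(session, volume)
    with _step("ROI fitting"):
        if not session.tissue_rois:
            raise ConfigError("session has no tissue ROI")
        rois = [_roi_from_spec(s) for s in session.tissue_rois]
        results = compare_rois(vol, rois, session.model,
                               aif, session.prep, session.fit)
    out = Path(session.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / session.prefix
    with _step("report"):
        _results_table(results).to_csv(f"{prefix}_params.csv", index=False)
        _plot_fits(results, f"{prefix}_fit.png")
        write_report(_report_session(session, vol, rois=rois), results, prefix)
    return results


def run_map_analysis(session: Session, volume: Dynamic4D):
    """Map mode: voxelwise fit inside the bounding box, map export, report."""
    vol, aif = _prepare_inputs(session, volume)
    with _step("voxelwise fitting"):
        if session.bbox is None:
            raise ConfigError("map mode requires a bounding box")
        mapset = fit_maps(vol, BoundingBox(*session.bbox), session.model,
                          aif, session.prep, session.fit)
    out = Path(session.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / session.prefix
    with _step("map export"):
        np.savez(f"{prefix}_maps.npz", chi2=mapset.chi2_map, aicc=mapset.aicc_map,
                 converged=mapset.converged_mask, **mapset.maps)
        sidecar = {
            "model": mapset.model,
            "bbox": mapset.bbox.to_list(),
            "units": mapset.units,
            "missing_value": "NaN outside bbox; failed in-box voxels are 0 with converged=False",
            "report": f"{session.prefix}.report.json",
        }
        Path(f"{prefix}_maps.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
        for nm, arr in mapset.maps.items():
            write_map_dicom(arr, nm, mapset.units[nm], f"{prefix}_dicom",
                            report_ref=f"{session.prefix}.report.json")
    with _step("report"):
        write_report(_report_session(session, vol), [], prefix)
    return mapset


def run_model_comparison(session: Session, volume: Dynamic4D, models=None):
    """Fit several models with identical settings; rank by AICc."""
    models = list(models or session.models)
    if len(models) < 2:
        raise ConfigError("model comparison needs at least 2 models")
    vol, aif = _prepare_inputs(session, volume)
    with _step("model comparison"):
        if not session.tissue_rois:
            raise ConfigError("session has no tissue ROI")
        roi = _roi_from_spec(session.tissue_rois[0])
        from .prep import prepare_curve, roi_mean_curve

        tissue = prepare_curve(roi_mean_curve(vol, roi), session.prep)
        results = compare_models(tissue, aif, session.fit, tuple(models))
    out = Path(session.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / session.prefix
    with _step("report"):
        table = _results_table(results)
        table.to_csv(f"{prefix}_ranking.csv", index=False)
        write_report(_report_session(session, vol, models=models), results, prefix)
    return results


def _report_session(session: Session, vol: Dynamic4D, rois=None, models=None) -> dict:
    d = session.to_dict()
    d["settings_hash"] = session.settings_hash()
    d["initial_parameters"] = {
        m: session.fit.params_for(m).as_dict()
        for m in (models or [session.model])
    }
    d["parameter_bounds"] = {
        m: {"lower": session.fit.params_for(m).lower.tolist(),
            "upper": session.fit.params_for(m).upper.tolist(),
            "fixed": session.fit.params_for(m).fixed.tolist()}
        for m in (models or [session.model])
    }
    d["baseline_n"] = session.prep.baseline_n
    d["normalization"] = session.prep.normalization
    d["hct_a"] = session.prep.hct_a
    d["time_points"] = vol.grid.n
    d["input_meta"] = {k: v for k, v in vol.meta.items() if not isinstance(v, np.ndarray)}
    if rois is not None:
        d["roi_voxel_counts"] = {r.label: r.voxel_count for r in rois}
    return d
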