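"""Vendor-aware DICOM I/O for dynamic series, parametric maps and reports.

Clinical vendors store the temporal resolution of a dynamic series in
different header locations:

==================== =============================================
dialect              timing source
==================== =============================================
siemens              per-volume Acquisition Time (0008,0032), a TM
                     clock string, differenced
ge_philips_single    Trigger Time (0018,1060) in milliseconds
philips_multiframe   Content Time (0008,0033) differences, falling
                     back to Acquisition Time (0008,0032)
bruker_2d            uniform grid from Repetition Time (0018,0080)
                     times the acquired images per volume (0018,1310)
==================== =============================================

If none of a dialect's tags can be found the series is unusable for model
fitting and a :class:`~perfkit.errors.TimingUnavailableError` names the
missing tag.  Time vectors are always re-zeroed to the first frame and kept
per-frame (non-uniform grids are preserved).

The writer here exists for synthetic series (phantom round-trip and
interoperability tests) and for exporting parametric maps and analysis
reports as DICOM secondary-capture objects.  Patient-identifying tags are
never written.
"""
from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import __version__
from .curves import TimeGrid
from .errors import ReadError, TimingUnavailableError
from .volume import Dynamic4D

DIALECTS = ("siemens", "ge_philips_single", "philips_multiframe", "bruker_2d")

_MR_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
_SC_STORAGE = "1.2.840.10008.5.1.4.1.1.7"

_MANUFACTURER = {
    "siemens": "SIEMENS",
    "ge_philips_single": "GE MEDICAL SYSTEMS",
    "philips_multiframe": "Philips Medical Systems",
    "bruker_2d": "Bruker BioSpin",
}


# --------------------------------------------------------------------------
# timing extraction


def parse_tm(value: str) -> float:
    """DICOM TM string (HHMMSS.FFFFFF, possibly truncated) -> seconds."""
    s = str(value).strip()
    if not s:
        raise ValueError("empty TM string")
    hh = int(s[0:2])
    mm = int(s[2:4]) if len(s) > 2 else 0
    ss = float(s[4:]) if len(s) > 4 else 0.0
    return hh * 3600.0 + mm * 60.0 + ss


def _get_tag(header, group: int, elem: int):
    """Fetch a tag value from a pydicom Dataset or a plain mapping."""
    if isinstance(header, Dataset):
        el = header.get(Tag(group, elem))
        return None if el is None else el.value
    for key in ((group, elem), f"{group:04X},{elem:04X}", f"({group:04X},{elem:04X})"):
        if key in header:
            return header[key]
    return None


def _clock_times_to_vector(clock: list[float]) -> np.ndarray:
    """Re-zeroed elapsed seconds from clock times, with midnight rollover."""
    t = np.asarray(clock, dtype=float)
    d = np.diff(t)
    d[d < 0] += 86400.0  # acquisition crossed midnight
    return np.concatenate([[0.0], np.cumsum(d)])


def extract_temporal_resolution(headers, dialect: str) -> np.ndarray:
    """Per-volume time vector in seconds from one header per temporal frame."""
    if dialect not in DIALECTS:
        raise ReadError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    headers = list(headers)
    if not headers:
        raise ReadError("no headers supplied")

    if dialect == "siemens":
        vals = [_get_tag(h, 0x0008, 0x0032) for h in headers]
        if any(v is None for v in vals):
            raise TimingUnavailableError("(0008,0032)", dialect)
        return _clock_times_to_vector([parse_tm(v) for v in vals])

    if dialect == "ge_philips_single":
        vals = [_get_tag(h, 0x0018, 0x1060) for h in headers]
        if any(v is None for v in vals):
            raise TimingUnavailableError("(0018,1060)", dialect)
        t = np.array([float(v) for v in vals]) / 1000.0
        return t - t[0]

    if dialect == "philips_multiframe":
        content = [_get_tag(h, 0x0008, 0x0033) for h in headers]
        if all(v is not None for v in content):
            clock = [parse_tm(v) for v in content]
            if len(set(clock)) > 1 or len(clock) == 1:
                return _clock_times_to_vector(clock)
        acq = [_get_tag(h, 0x0008, 0x0032) for h in headers]
        if all(v is not None for v in acq):
            return _clock_times_to_vector([parse_tm(v) for v in acq])
        raise TimingUnavailableError("(0008,0033)", dialect)

    # bruker_2d: dt = TR * images-per-volume
    tr = _get_tag(headers[0], 0x0018, 0x0080)
    if tr is None:
        raise TimingUnavailableError("(0018,0080)", dialect)
    nimg = _get_tag(headers[0], 0x0018, 0x1310)
    if nimg is None:
        raise TimingUnavailableError("(0018,1310)", dialect)
    try:
        vals = [int(v) for v in nimg]
        # 4-value acquisition matrix: the acquired (phase) entries are nonzero
        phase = [v for v in (vals[2:4] if len(vals) == 4 else vals) if v > 0]
        n = max(phase) if phase else max(v for v in vals if v > 0)
    except TypeError:
        n = int(nimg)
    dt = float(tr) / 1000.0 * n
    return dt * np.arange(len(headers), dtype=float)


def detect_dialect(ds: Dataset) -> str:
    """Guess the vendor dialect from Manufacturer and frame structure."""
    manu = str(getattr(ds, "Manufacturer", "")).upper()
    multiframe = "NumberOfFrames" in ds
    if "SIEMENS" in manu:
        return "siemens"
    if "BRUKER" in manu:
        return "bruker_2d"
    if "PHILIPS" in manu and multiframe:
        return "philips_multiframe"
    if "GE" in manu or "PHILIPS" in manu:
        return "ge_philips_single"
    raise ReadError(f"cannot detect vendor dialect from Manufacturer {manu!r}")


# --------------------------------------------------------------------------
# series reading


def _orientation_key(ds: Dataset) -> tuple:
    iop = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    return tuple(round(float(v), 4) for v in iop)


def _slice_position(ds: Dataset) -> float:
    iop = [float(v) for v in getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    ipp = [float(v) for v in getattr(ds, "ImagePositionPatient", [0, 0, 0])]
    r, c = np.array(iop[:3]), np.array(iop[3:])
    normal = np.cross(r, c)
    return float(np.dot(normal, ipp))


def _temporal_key(ds: Dataset) -> float:
    for attr in ("TemporalPositionIdentifier", "AcquisitionNumber", "InstanceNumber"):
        v = getattr(ds, attr, None)
        if v is not None:
            return float(v)
    return 0.0


def read_dynamic_series(path, dialect: str | None = None,
                        orientation_index: int | None = None) -> Dynamic4D:
    """Assemble a directory of DICOM files (or multi-frame files) into 4D.

    Frames are sorted by spatial position, then time.  A series mixing
    acquisition orientations (e.g. coronal localizers among transversal
    dynamics) is split by orientation; pass ``orientation_index`` to select
    one, otherwise the available orientations are listed in the error.
    """
    p = Path(path)
    files = sorted(p.glob("*.dcm")) if p.is_dir() else [p]
    if not files:
        raise ReadError(f"no DICOM files found under {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    by_orient: dict[tuple, list[Dataset]] = {}
    for ds in datasets:
        by_orient.setdefault(_orientation_key(ds), []).append(ds)
    orients = sorted(by_orient)
    if len(orients) > 1 and orientation_index is None:
        raise ReadError(
            f"series mixes {len(orients)} orientations {orients}; "
            "pass orientation_index to select one"
        )
    group = by_orient[orients[orientation_index or 0]]

    multiframe = any("NumberOfFrames" in ds for ds in group)
    if dialect is None:
        dialect = detect_dialect(group[0])

    if multiframe:
        group.sort(key=_temporal_key)
        frames = [ds.pixel_array for ds in group]  # (nslices, rows, cols) each
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ReadError(f"inconsistent frame shapes {shapes}")
        stack = np.stack(frames, axis=-1)  # (nslices, rows, cols, time)
        if stack.ndim == 3:  # single-slice files decode to (rows, cols)
            stack = stack[np.newaxis]
        data = np.transpose(stack, (2, 1, 0, 3))  # (x, y, slice, time)
        headers = group
    else:
        by_slice: dict[float, list[Dataset]] = {}
        for ds in group:
            by_slice.setdefault(round(_slice_position(ds), 4), []).append(ds)
        zpos = sorted(by_slice)
        counts = {len(v) for v in by_slice.values()}
        if len(counts) != 1:
            raise ReadError(f"slices carry differing frame counts {counts}")
        nt = counts.pop()
        for v in by_slice.values():
            v.sort(key=_temporal_key)
        sample = by_slice[zpos[0]][0].pixel_array
        ny, nx = sample.shape
        data = np.empty((nx, ny, len(zpos), nt))
        for zi, zp in enumerate(zpos):
            for ti, ds in enumerate(by_slice[zp]):
                data[:, :, zi, ti] = ds.pixel_array.T
        headers = by_slice[zpos[0]]

    tvec = extract_temporal_resolution(headers, dialect)
    if tvec.size != data.shape[3]:
        raise ReadError(
            f"derived {tvec.size} time points but data has {data.shape[3]} volumes"
        )
    first = group[0]
    spacing = tuple(float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])) + (
        float(getattr(first, "SliceThickness", 1.0)),
    )
    meta = {
        "dialect": dialect,
        "manufacturer": str(getattr(first, "Manufacturer", "")),
        "timing_tags": {
            "siemens": ["(0008,0032)"],
            "ge_philips_single": ["(0018,1060)"],
            "philips_multiframe": ["(0008,0033)", "(0008,0032)"],
            "bruker_2d": ["(0018,1310)", "(0018,0080)"],
        }[dialect],
        "n_files": len(files),
    }
    return Dynamic4D(data, TimeGrid(tvec), spacing=spacing, meta=meta)


# --------------------------------------------------------------------------
# series writing (synthetic phantoms, maps)


def _base_dataset(sop_class: str, rows: int, cols: int, manufacturer: str) -> Dataset:
    ds = Dataset()
    fm = FileMetaDataset()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    fm.MediaStorageSOPClassUID = sop_class
    fm.MediaStorageSOPInstanceUID = generate_uid()
    ds.file_meta = fm
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Manufacturer = manufacturer
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "PERFKIT-PHANTOM"
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [1.0, 1.0]
    ds.SliceThickness = 1.0
    return ds


def _set_float_pixels(ds: Dataset, frame: np.ndarray) -> None:
    ds.BitsAllocated = 64
    ds.DoubleFloatPixelData = np.ascontiguousarray(frame, dtype=np.float64).tobytes()


def _tm_string(seconds: float) -> str:
    hh = int(seconds // 3600) % 24
    mm = int(seconds % 3600 // 60)
    ss = seconds % 60
    return f"{hh:02d}{mm:02d}{ss:09.6f}"


def write_dynamic_series(volume: Dynamic4D, outdir, dialect: str,
                         base_clock_s: float = 12 * 3600.0,
                         bruker_tr_ms: float = 50.0) -> list[Path]:
    """Write a synthetic dynamic series in one vendor dialect.

    Voxel values are stored losslessly (64-bit float pixel data), so the
    phantom -> writer -> reader round trip is exact.  For ``bruker_2d`` the
    (uniform) frame interval is encoded as Repetition Time x acquired
    images, so dt must be an integer multiple of ``bruker_tr_ms``.
    """
    if dialect not in DIALECTS:
        raise ReadError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    nx, ny, nz, nt = volume.shape
    t = volume.grid.t
    study_uid, series_uid = generate_uid(), generate_uid()
    manufacturer = _MANUFACTURER[dialect]
    written: list[Path] = []

    if dialect == "bruker_2d":
        dts = np.diff(t)
        if dts.size and not np.allclose(dts, dts[0], atol=1e-9):
            raise ReadError("bruker_2d requires a uniform time grid")
        nimg = int(round((dts[0] if dts.size else 0.0) * 1000.0 / bruker_tr_ms))
        if dts.size and not math.isclose(nimg * bruker_tr_ms / 1000.0, dts[0], rel_tol=1e-9):
            raise ReadError(
                f"dt {dts[0]} s is not an integer multiple of TR {bruker_tr_ms} ms"
            )

    if dialect == "philips_multiframe":
        for ti in range(nt):
            ds = _base_dataset(_MR_STORAGE, ny, nx, manufacturer)
            ds.StudyInstanceUID, ds.SeriesInstanceUID = study_uid, series_uid
            ds.NumberOfFrames = nz
            ds.InstanceNumber = ti + 1
            ds.TemporalPositionIdentifier = ti + 1
            ds.ContentTime = _tm_string(base_clock_s + t[ti])
            ds.AcquisitionTime = _tm_string(base_clock_s + t[ti])
            ds.ImagePositionPatient = [0.0, 0.0, 0.0]
            frames = np.transpose(volume.data[:, :, :, ti], (2, 1, 0))  # (slice, y, x)
            _set_float_pixels(ds, frames)
            fp = out / f"dyn_{ti:04d}.dcm"
            ds.save_as(str(fp), enforce_file_format=True)
            written.append(fp)
        return written

    inst = 0
    for ti in range(nt):
        for zi in range(nz):
            inst += 1
            ds = _base_dataset(_MR_STORAGE, ny, nx, manufacturer)
            ds.StudyInstanceUID, ds.SeriesInstanceUID = study_uid, series_uid
            ds.InstanceNumber = inst
            ds.TemporalPositionIdentifier = ti + 1
            ds.AcquisitionNumber = ti + 1
            ds.ImagePositionPatient = [0.0, 0.0, float(zi)]
            if dialect == "siemens":
                ds.AcquisitionTime = _tm_string(base_clock_s + t[ti])
            elif dialect == "ge_philips_single":
                ds.TriggerTime = f"{t[ti] * 1000.0:.6f}"
            else:  # bruker_2d
                ds.RepetitionTime = f"{bruker_tr_ms:.6f}"
                ds.AcquisitionMatrix = [0, nx, nimg, 0]
            _set_float_pixels(ds, volume.data[:, :, zi, ti].T)
            fp = out / f"im_{ti:04d}_{zi:03d}.dcm"
            ds.save_as(str(fp), enforce_file_format=True)
            written.append(fp)
    return written


def write_map_dicom(map_array: np.ndarray, name: str, unit: str, outdir,
                    report_ref: str = "") -> list[Path]:
    """Export one 3D parametric map as a DICOM secondary-capture series.

    Values are encoded as 16-bit integers with Rescale Slope/Intercept
    carrying the physical units; NaN (outside the fitted box) maps to 0 with
    the validity carried by the intercept range.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(map_array, dtype=float)
    finite = np.isfinite(arr)
    lo = float(arr[finite].min()) if finite.any() else 0.0
    hi = float(arr[finite].max()) if finite.any() else 1.0
    slope = (hi - lo) / 65535.0 or 1.0
    series_uid = generate_uid()
    written = []
    for zi in range(arr.shape[2]):
        sl = arr[:, :, zi]
        stored = np.zeros(sl.shape, dtype=np.uint16)
        m = np.isfinite(sl)
        stored[m] = np.round((sl[m] - lo) / slope).astype(np.uint16)
        ds = _base_dataset(_SC_STORAGE, sl.shape[1], sl.shape[0], "perfkit")
        ds.Modality = "OT"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = f"{name} [{unit}]"
        ds.InstanceNumber = zi + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(zi)]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = f"{lo:.10g}"
        ds.ImageComments = report_ref
        ds.PixelData = np.ascontiguousarray(stored.T).tobytes()
        fp = out / f"map_{name}_{zi:03d}.dcm"
        ds.save_as(str(fp), enforce_file_format=True)
        written.append(fp)
    return written


# --------------------------------------------------------------------------
# analysis report


def report_payload(session: dict, results) -> dict:
    """Machine-readable report: settings, per-result parameters and GOF.

    Deterministic by construction -- no timestamps -- so identical sessions
    produce byte-identical JSON.
    """
    return {
        "software": {"name": "perfkit", "version": __version__},
        "session": session,
        "note": (
            "relative information loss is exp((AICc_i - AICc_min)/2); "
            "1 marks the best-ranked model and larger values a worse fit"
        ),
        "results": [r.to_dict() for r in results],
    }


def write_report(session: dict, results, out_prefix) -> tuple[Path, Path]:
    """Write the analysis report as a rendered PNG plus its JSON twin."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = report_payload(session, results)
    json_path = out_prefix.with_suffix(".report.json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(8.3, 11.7))
    FigureCanvasAgg(fig)
    lines = [f"perfkit {__version__} analysis report", ""]
    for key, val in sorted(session.items()):
        lines.append(f"{key}: {json.dumps(val, sort_keys=True, default=str)}")
    lines.append("")
    for r in results:
        d = r.to_dict()
        lines.append(f"[{d['model']}] {d.get('label', '')}")
        if d["fitted_parameters"]:
            for nm, v in d["fitted_parameters"].items():
                lines.append(f"   {nm} = {v:.6g}")
            for nm, v in d["derived_parameters"].items():
                lines.append(f"   {nm} = {v:.6g} {d['units'][nm]}")
        lines.append(f"   Final Chi Square = {d['final_chi_square']:.6g}")
        lines.append(f"   Corr. Akaike Information Crit. = {d['corrected_aic']:.6g}")
        if d.get("relative_information_loss") is not None:
            lines.append(f"   relative information loss = {d['relative_information_loss']:.6g}")
        lines.append("")
    fig.text(0.05, 0.98, "\n".join(lines[:80]), va="top", family="monospace", fontsize=7)
    png_path = out_prefix.with_suffix(".report.png")
    fig.savefig(png_path, dpi=120)
    return png_path, json_path
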