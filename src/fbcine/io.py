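"""Cine containers, readers/writers, run configuration and reports.

A cine slice is an ordered stack of 2-D grayscale frames acquired at one
short-axis position while the subject breathes freely.  Public frame
indices are 1-based everywhere (frame 1 is the first acquired frame);
internally frames live in a ``(n_frames, rows, cols)`` float array.

Supported containers:

* **NPZ** — the package's native fixture format: ``frames`` array plus
  optional ``pixel_spacing`` (mm), ``frame_interval`` (ms), ``slice_id``.
* **NIfTI** (``.nii`` / ``.nii.gz``) — a 3-D volume laid out
  rows x cols x time; spacing/timing taken from the header zooms.
* **DICOM** — a directory of single-frame files, ordered by
  ``InstanceNumber``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError, FormatError

REPORT_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CineSlice:
    """One short-axis slice: N grayscale frames plus acquisition metadata."""

    frames: np.ndarray                       # (n_frames, rows, cols), float
    pixel_spacing: Optional[tuple] = None    # (row mm, col mm)
    frame_interval: Optional[float] = None   # ms between frames
    slice_id: str = "slice"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError(
                f"cine stack must be (n_frames, rows, cols); got {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise FormatError("a cine slice needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("cine frames contain non-finite intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` (1-based)."""
        if not 1 <= t <= self.n_frames:
            raise FormatError(f"frame {t} out of range 1..{self.n_frames}")
        return self.frames[t - 1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cine(path, fmt: Optional[str] = None) -> CineSlice:
    """Read a cine slice from NPZ, NIfTI or a DICOM series directory.

    ``fmt`` may be ``"npz"``, ``"nifti"`` or ``"dicom"``; when omitted it is
    inferred from the path (directory -> DICOM, else by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix == ".npz":
            fmt = "npz"
        elif path.suffix in (".nii", ".gz"):
            fmt = "nifti"
        else:
            raise FormatError(f"cannot infer cine format from {path.name}")
    if fmt == "npz":
        return _read_npz(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom":
        return _read_dicom_dir(path)
    raise FormatError(f"unsupported cine format: {fmt}")


def _read_npz(path) -> CineSlice:
    with np.load(path, allow_pickle=False) as z:
        if "frames" not in z:
            raise FormatError(f"{path}: NPZ cine fixture must contain 'frames'")
        frames = z["frames"]
        spacing = tuple(z["pixel_spacing"]) if "pixel_spacing" in z else None
        interval = float(z["frame_interval"]) if "frame_interval" in z else None
        slice_id = str(z["slice_id"]) if "slice_id" in z else Path(path).stem
    return CineSlice(frames, spacing, interval, slice_id)


def write_npz(slc: CineSlice, path) -> Path:
    path = Path(path)
    extra = {}
    if slc.pixel_spacing is not None:
        extra["pixel_spacing"] = np.asarray(slc.pixel_spacing, dtype=float)
    if slc.frame_interval is not None:
        extra["frame_interval"] = np.asarray(slc.frame_interval, dtype=float)
    np.savez(path, frames=slc.frames, slice_id=np.str_(slc.slice_id), **extra)
    return path


def _read_nifti(path) -> CineSlice:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D rows x cols x time volume")
    frames = np.moveaxis(data.astype(float), 2, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    interval = float(zooms[2]) if len(zooms) >= 3 and zooms[2] > 0 else None
    return CineSlice(frames, spacing, interval, Path(path).name.split(".")[0])


def write_nifti(slc: CineSlice, path) -> Path:
    import nibabel as nib

    vol = np.moveaxis(slc.frames, 0, 2)
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    zooms = list(slc.pixel_spacing) if slc.pixel_spacing else [1.0, 1.0]
    zooms.append(slc.frame_interval if slc.frame_interval else 1.0)
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))
    return Path(path)


def _read_dicom_dir(path) -> CineSlice:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"{path}: no .dcm files found")
    entries = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        if "InstanceNumber" not in ds:
            raise FormatError(f"{f.name}: missing InstanceNumber")
        arr = ds.pixel_array.astype(float)
        entries.append((int(ds.InstanceNumber), arr, ds))
    entries.sort(key=lambda e: e[0])
    numbers = [e[0] for e in entries]
    if numbers != list(range(numbers[0], numbers[0] + len(numbers))):
        raise FormatError(f"{path}: non-contiguous InstanceNumbers {numbers[:5]}...")
    shapes = {e[1].shape for e in entries}
    if len(shapes) != 1:
        raise FormatError(f"{path}: frames have mixed shapes {sorted(shapes)}")
    ds0 = entries[0][2]
    spacing = None
    if "PixelSpacing" in ds0:
        spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    frames = np.stack([e[1] for e in entries])
    peak = frames.max()
    if peak > 0:                       # normalize stored ints to [0, 1]
        frames = frames / peak
    return CineSlice(frames, spacing, None, Path(path).name)


def write_dicom_dir(slc: CineSlice, path, filenames=None) -> Path:
    """Write each frame as a minimal single-frame secondary-capture DICOM.

    ``filenames`` (optional) maps frame order to file names so fixtures can
    exercise reading a shuffled directory listing.
    """
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for i in range(slc.n_frames):
        name = filenames[i] if filenames else f"frame{i + 1:03d}.dcm"
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        if slc.pixel_spacing is not None:
            ds.PixelSpacing = [str(slc.pixel_spacing[0]), str(slc.pixel_spacing[1])]
        frame = slc.frames[i]
        lo, hi = float(slc.frames.min()), float(slc.frames.max())
        scaled = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
        pixels = np.round(scaled * 4095).astype(np.uint16)
        ds.Rows, ds.Columns = pixels.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.PixelData = pixels.tobytes()
        ds.save_as(str(path / name), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the published acquisition regime."""

    localizer: str = "fallback"       # "fallback" or "cnn"
    nf: object = "auto"               # cardiac-cycle length in frames, or "auto"
    window_size: int = 40             # NCC patch side, pixels
    hanning_length: object = "auto"   # low-pass kernel length, or "auto" (2*nf+1)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.localizer not in ("fallback", "cnn"):
            raise ConfigError(f"unknown localizer {self.localizer!r}")
        if self.window_size % 2 != 0 or self.window_size < 8:
            raise ConfigError("window_size must be even and >= 8")
        if self.nf != "auto":
            self.nf = int(self.nf)
            if self.nf < 4:
                raise ConfigError("nf must be 'auto' or an integer >= 4")
        if self.hanning_length != "auto":
            self.hanning_length = int(self.hanning_length)
            if self.hanning_length < 3:
                raise ConfigError("hanning_length must be 'auto' or >= 3")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

#: Minimal schema for the detection report: key -> required type(s).
REPORT_SCHEMA = {
    "schema_version": str,
    "status": str,                    # "ok" | "error"
    "slice_id": str,
    "n_frames": int,
    "ed": (int, type(None)),          # 1-based frame indices
    "es": (int, type(None)),
    "window": (list, type(None)),     # [A, B], 1-based
    "n_f": (int, type(None)),
    "ncc_min": (float, type(None)),
    "per_frame": list,
    "failures": list,
    "error": (str, type(None)),
}


def validate_report(report: dict) -> None:
    """Raise :class:`FormatError` unless ``report`` matches the schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise FormatError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise FormatError(f"report key {key!r} has type {type(report[key]).__name__}")
    if report["status"] not in ("ok", "error"):
        raise FormatError(f"bad status {report['status']!r}")


def build_report(slc: CineSlice, outcome) -> dict:
    """Assemble the JSON-serializable report for a :class:`~fbcine.detect.SliceReport`."""
    per_frame = []
    for t in range(1, slc.n_frames + 1):
        fit = outcome.fits[t - 1]
        row = {"frame": t}
        if fit is not None:
            row.update(
                center_row=round(fit.center[0], 3),
                center_col=round(fit.center[1], 3),
                area=round(fit.area, 3),
                status="ok",
            )
        else:
            row["status"] = "failed"
        if outcome.trace is not None:
            row["h"] = round(float(outcome.trace.h[t - 1]), 4)
            row["respiratory"] = round(float(outcome.trace.respiratory[t - 1]), 4)
            row["cardiac"] = round(float(outcome.trace.cardiac[t - 1]), 4)
        per_frame.append(row)
    failures = [
        {"frame": f.frame, "stage": f.stage, "reason": f.reason}
        for f in outcome.failures
    ]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "status": "ok" if outcome.result is not None else "error",
        "slice_id": slc.slice_id,
        "n_frames": slc.n_frames,
        "ed": None,
        "es": None,
        "window": None,
        "n_f": outcome.n_f,
        "ncc_min": None,
        "per_frame": per_frame,
        "failures": failures,
        "error": outcome.error,
    }
    if outcome.result is not None:
        res = outcome.result
        report.update(
            ed=res.ed,
            es=res.es,
            window=[res.window.first, res.window.last],
            ncc_min=float(res.ncc_min),
        )
    return report


def write_report(report: dict, path, trace_csv=None, trace=None) -> Path:
    """Write the report JSON (validated) and optionally the trace CSV."""
    validate_report(report)
    path = Path(path)
    os.makedirs(path.parent or Path("."), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    if trace_csv is not None and trace is not None:
        write_trace_csv(trace, trace_csv)
    return path


def write_trace_csv(trace, path) -> Path:
    import csv

    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "h", "respiratory", "cardiac"])
        for t in range(trace.n_frames):
            w.writerow(
                [t + 1, f"{trace.h[t]:.6f}", f"{trace.respiratory[t]:.6f}", f"{trace.cardiac[t]:.6f}"]
            )
    return path


def read_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    validate_report(report)
    return report
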