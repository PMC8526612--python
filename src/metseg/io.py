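"""File formats and visualization.

Two series dialects are supported: single-frame DICOM (PixelSpacing,
SliceThickness, InstanceNumber tags) for real data, and 16-bit PNG plus a
JSON manifest for phantoms and tests.  Writes are atomic
(temp-then-rename) so an interrupted run never leaves a partial file.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from dataclasses import asdict
from pathlib import Path
import imageio.v3 as iio
import numpy as np

from .calibration import Thresholds
from .ensemble import BinaryMask
from .phantom import PhantomPatient
from .preprocessing import ProcessedSlice, RawSlice

__all__ = [
    "SeriesFormatError",
    "atomic_write_bytes",
    "atomic_write_text",
    "write_patient_series",
    "read_patient_series",
    "write_dicom_series",
    "write_processed_slice",
    "read_processed_slice",
    "thresholds_to_json",
    "thresholds_from_json",
    "curves_to_csv",
    "write_mask_png",
    "read_mask_png",
    "render_overlay",
    "write_overlay_png",
    "plot_curves",
]


class SeriesFormatError(ValueError):
    """A patient series is missing files, tags or geometry."""


# -- atomic writes ----------------------------------------------------------


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: str | Path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


def atomic_write_json(path: str | Path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


# -- PNG + manifest dialect -------------------------------------------------


def write_patient_series(patient: PhantomPatient, out_dir: str | Path) -> Path:
    """Write a phantom patient as slice PNGs + mask PNGs + manifest.json."""
    out_dir = Path(out_dir) / patient.patient_id
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for slc, mask in zip(patient.slices, patient.masks):
        img_name = f"slice_{slc.slice_index:04d}.png"
        mask_name = f"mask_{slc.slice_index:04d}.png"
        atomic_write_bytes(
            out_dir / img_name,
            iio.imwrite("<bytes>", slc.pixels.astype(np.uint16), extension=".png"),
        )
        atomic_write_bytes(
            out_dir / mask_name,
            iio.imwrite(
                "<bytes>", (mask.astype(np.uint8) * 255), extension=".png"
            ),
        )
        entries.append(
            {
                "slice_index": slc.slice_index,
                "image": img_name,
                "mask": mask_name,
                "positive": bool(mask.any()),
            }
        )
    manifest = {
        "patient_id": patient.patient_id,
        "pixel_spacing_mm": list(patient.slices[0].pixel_spacing),
        "slice_thickness_mm": patient.slices[0].slice_thickness,
        "slices": entries,
        "lesions": [asdict(l) for l in patient.lesions],
    }
    atomic_write_json(out_dir / "manifest.json", manifest)
    return out_dir


def _read_png_series(path: Path) -> list[RawSlice]:
    manifest = json.loads((path / "manifest.json").read_text())
    for key in ("pixel_spacing_mm", "slice_thickness_mm"):
        if key not in manifest:
            raise SeriesFormatError(f"manifest missing {key!r}")
    spacing = tuple(float(v) for v in manifest["pixel_spacing_mm"])
    thickness = float(manifest["slice_thickness_mm"])
    pid = manifest["patient_id"]
    slices = []
    for entry in sorted(manifest["slices"], key=lambda e: e["slice_index"]):
        pixels = iio.imread(path / entry["image"])
        slices.append(
            RawSlice(
                pixels=np.asarray(pixels),
                pixel_spacing=spacing,
                slice_thickness=thickness,
                patient_id=pid,
                slice_index=int(entry["slice_index"]),
            )
        )
    return slices


def read_series_masks(path: str | Path) -> list[np.ndarray]:
    """Ground-truth masks of a PNG-dialect series, in slice order."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return [
        iio.imread(path / e["mask"]) > 0
        for e in sorted(manifest["slices"], key=lambda e: e["slice_index"])
    ]


# -- DICOM dialect ----------------------------------------------------------


def write_dicom_series(patient: PhantomPatient, out_dir: str | Path) -> Path:
    """Optional DICOM export with the geometry tags the pipeline consumes."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    out_dir = Path(out_dir) / patient.patient_id
    out_dir.mkdir(parents=True, exist_ok=True)
    for slc in patient.slices:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(
            entropy_srcs=[patient.patient_id, str(slc.slice_index)]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.PatientID = patient.patient_id
        ds.Modality = "MR"
        ds.InstanceNumber = slc.slice_index + 1
        ds.PixelSpacing = [str(slc.pixel_spacing[0]), str(slc.pixel_spacing[1])]
        ds.SliceThickness = str(slc.slice_thickness)
        ds.Rows, ds.Columns = slc.pixels.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = slc.pixels.astype(np.uint16).tobytes()
        ds.save_as(out_dir / f"slice_{slc.slice_index:04d}.dcm", enforce_file_format=True)
    return out_dir


def _read_dicom_series(path: Path, files: list[Path]) -> list[RawSlice]:
    import pydicom

    records = []
    patient_ids = set()
    for f in files:
        ds = pydicom.dcmread(f)
        for tag in ("PixelSpacing", "SliceThickness", "InstanceNumber"):
            if getattr(ds, tag, None) is None:
                raise SeriesFormatError(f"{f.name} is missing tag {tag!r}")
        patient_ids.add(str(getattr(ds, "PatientID", "")))
        records.append(ds)
    if len(patient_ids) > 1:
        raise SeriesFormatError(
            f"mixed patients in one series: {sorted(patient_ids)}"
        )
    records.sort(key=lambda ds: int(ds.InstanceNumber))
    pid = patient_ids.pop()
    return [
        RawSlice(
            pixels=ds.pixel_array,
            pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
            slice_thickness=float(ds.SliceThickness),
            patient_id=pid,
            slice_index=int(ds.InstanceNumber) - 1,
        )
        for ds in records
    ]


def read_patient_series(path: str | Path) -> list[RawSlice]:
    """Read one patient's series, DICOM or PNG+manifest, in slice order."""
    path = Path(path)
    if not path.is_dir():
        raise SeriesFormatError(f"{path} is not a directory")
    dcm = sorted(path.glob("*.dcm"))
    if dcm:
        return _read_dicom_series(path, dcm)
    if (path / "manifest.json").exists():
        return _read_png_series(path)
    raise SeriesFormatError(
        f"{path} contains neither DICOM files nor a manifest.json"
    )


# -- processed slices, thresholds, curves, masks ----------------------------


def write_processed_slice(slc: ProcessedSlice, path: str | Path) -> None:
    """Store a processed slice as .npz (pixels + ROI) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), pixels=slc.pixels, roi=slc.roi)
    atomic_write_json(
        path.with_suffix(".json"),
        {"patient_id": slc.patient_id, "slice_index": slc.slice_index},
    )


def read_processed_slice(path: str | Path) -> ProcessedSlice:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        return ProcessedSlice(
            pixels=data["pixels"],
            roi=data["roi"].astype(bool),
            patient_id=side["patient_id"],
            slice_index=int(side["slice_index"]),
        )


def thresholds_to_json(thresholds: Thresholds, path: str | Path) -> None:
    obj = {
        "t_c": thresholds.t_c,
        "mask_c": thresholds.mask_c,
        "calibration_id": thresholds.calibration_id,
        "roc_auc": thresholds.roc.auc if thresholds.roc else None,
        "pr_auc": thresholds.pr.auc if thresholds.pr else None,
    }
    atomic_write_json(path, obj)


def thresholds_from_json(path: str | Path) -> Thresholds:
    obj = json.loads(Path(path).read_text())
    return Thresholds(
        t_c=float(obj["t_c"]),
        mask_c=float(obj["mask_c"]),
        calibration_id=obj.get("calibration_id", ""),
    )


def curves_to_csv(thresholds: Thresholds, out_dir: str | Path) -> None:
    """Dump the attached ROC and PR curves as CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if thresholds.roc is not None:
        _curve_csv(
            out_dir / "roc_curve.csv",
            ["threshold", "tpr", "fpr"],
            zip(thresholds.roc.thresholds, thresholds.roc.tpr, thresholds.roc.fpr),
        )
    if thresholds.pr is not None:
        _curve_csv(
            out_dir / "pr_curve.csv",
            ["threshold", "precision", "recall", "f1"],
            zip(
                thresholds.pr.thresholds,
                thresholds.pr.precision,
                thresholds.pr.recall,
                thresholds.pr.f1,
            ),
        )


def _curve_csv(path: Path, header: list[str], rows) -> None:
    import io as _io

    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(header)
    for row in rows:
        writer.writerow([f"{float(v):.6g}" for v in row])
    atomic_write_text(path, buf.getvalue())


def write_mask_png(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    values = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    atomic_write_bytes(
        path,
        iio.imwrite("<bytes>", (values > 0).astype(np.uint8) * 255, extension=".png"),
    )


def read_mask_png(path: str | Path) -> np.ndarray:
    return iio.imread(path) > 0


def plot_curves(thresholds: Thresholds, out_dir: str | Path) -> list[Path]:
    """Write ROC and PR curve plots (PNG) for a calibrated Thresholds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if thresholds.roc is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(thresholds.roc.fpr, thresholds.roc.tpr)
        ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.set_title(f"ROC (AUC {thresholds.roc.auc:.4f}), T_c={thresholds.t_c:.3f}")
        fig.tight_layout()
        path = out_dir / "roc_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if thresholds.pr is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(thresholds.pr.recall, thresholds.pr.precision)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(
            f"pixel PR (AUC {thresholds.pr.auc:.4f}), Mask_c={thresholds.mask_c:.3f}"
        )
        fig.tight_layout()
        path = out_dir / "pr_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


# -- overlays ---------------------------------------------------------------

_TP_COLOR = (0, 0, 255)  # blue: predicted and true
_FN_COLOR = (0, 255, 0)  # green: missed tumor
_FP_COLOR = (255, 0, 0)  # red: spurious prediction


def render_overlay(
    image: np.ndarray,
    pred: BinaryMask | np.ndarray,
    truth: np.ndarray,
) -> np.ndarray:
    """RGB overlay: TP pixels blue, FN green, FP red, rest grayscale."""
    img = np.asarray(image, dtype=float)
    p = np.asarray(pred.values if isinstance(pred, BinaryMask) else pred) > 0
    t = np.asarray(truth) > 0
    if img.shape != p.shape or img.shape != t.shape:
        raise ValueError("image, prediction and truth shapes must match")
    span = np.ptp(img)
    gray = ((img - img.min()) / span * 255).astype(np.uint8) if span else (
        np.zeros_like(img, dtype=np.uint8)
    )
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[p & t] = _TP_COLOR
    rgb[~p & t] = _FN_COLOR
    rgb[p & ~t] = _FP_COLOR
    return rgb


def write_overlay_png(
    image: np.ndarray, pred, truth: np.ndarray, path: str | Path
) -> None:
    atomic_write_bytes(
        path,
        iio.imwrite("<bytes>", render_overlay(image, pred, truth), extension=".png"),
    )
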