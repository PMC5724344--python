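"""Study container and on-disk corpus layout (DICOM slices + JSON report sidecar).

A *study* — one imaging examination: an ordered stack of slices plus its
report document and patient metadata — is the unit of retrieval throughout
the package. On disk a corpus is a directory of study subdirectories, each
holding one DICOM file per slice and a ``report.json`` sidecar with the
anamnesis and report text, mirroring a hospital PACS/RIS export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .textproc import ReportDocument

__all__ = ["Study", "write_study_files", "load_study", "load_corpus",
           "write_truth_table", "load_truth_table"]

SEXES = ("M", "F", "O")

# stored_value = HU - intercept, kept unsigned 16-bit
_RESCALE_INTERCEPT = -1024.0


@dataclass
class Study:
    """One CT study: ordered slices (2-D HU arrays) + report + metadata."""

    study_id: str
    slices: list[np.ndarray]
    report: ReportDocument
    patient_age: int
    patient_sex: str
    study_code: str
    truth_class: str | None = None  # known lesion class for synthetic studies

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.patient_sex not in SEXES:
            raise ValueError(f"patient_sex must be one of {SEXES}")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"all slices must share dimensions, got {shapes}")


def _age_string(age: int) -> str:
    """DICOM AS value representation: zero-padded 'nnnY'."""
    if not 0 <= age <= 999:
        raise ValueError(f"patient age {age} outside DICOM AS range")
    return f"{age:03d}Y"


def _parse_age(value: str) -> int:
    value = str(value).strip()
    if value.endswith(("Y", "y")):
        value = value[:-1]
    return int(value)


def write_study_files(study: Study, directory: str | Path) -> list[Path]:
    """Write one DICOM per slice + report.json; returns the manifest of paths.

    Pixels are stored as unsigned 16-bit with RescaleIntercept −1024 /
    RescaleSlope 1, so applying the rescale on read reproduces HU exactly
    (slices are rounded to integer HU).
    """
    directory = Path(directory) / study.study_id
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    written: list[Path] = []
    for i, hu in enumerate(study.slices):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.PatientAge = _age_string(study.patient_age)
        ds.PatientSex = study.patient_sex
        ds.StudyDescription = study.study_code
        ds.PatientID = study.study_id
        ds.Rows, ds.Columns = hu.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = _RESCALE_INTERCEPT
        ds.RescaleSlope = 1.0
        stored = np.rint(hu - _RESCALE_INTERCEPT)
        if stored.min() < 0 or stored.max() > 0xFFFF:
            raise ValueError("HU values outside storable range [-1024, 64511]")
        ds.PixelData = stored.astype("<u2").tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = directory / f"slice_{i:03d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        written.append(path)

    sidecar = directory / "report.json"
    sidecar.write_text(
        json.dumps(
            {
                "study_id": study.study_id,
                "anamnesis": study.report.anamnesis,
                "report_text": study.report.report_text,
                "study_code": study.study_code,
            },
            indent=1,
            sort_keys=True,
        )
    )
    written.append(sidecar)
    return written


def load_study(directory: str | Path) -> Study:
    """Read back one study directory (DICOM slices + report.json)."""
    directory = Path(directory)
    sidecar = json.loads((directory / "report.json").read_text())
    datasets = [pydicom.dcmread(p) for p in sorted(directory.glob("*.dcm"))]
    if not datasets:
        raise ValueError(f"no DICOM slices found in {directory}")
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    slices = []
    for ds in datasets:
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    first = datasets[0]
    return Study(
        study_id=sidecar["study_id"],
        slices=slices,
        report=ReportDocument(
            study_id=sidecar["study_id"],
            anamnesis=sidecar.get("anamnesis", ""),
            report_text=sidecar.get("report_text", ""),
        ),
        patient_age=_parse_age(first.PatientAge),
        patient_sex=str(first.PatientSex),
        study_code=str(first.StudyDescription),
    )


def load_corpus(root: str | Path) -> list[Study]:
    """Load every study subdirectory under `root` (sorted by study_id)."""
    root = Path(root)
    studies = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sub / "report.json").exists():
            studies.append(load_study(sub))
    studies.sort(key=lambda s: s.study_id)
    return studies


def write_truth_table(studies: list[Study], path: str | Path) -> None:
    """CSV ``study_id,truth_class`` for a synthetic corpus."""
    lines = ["study_id,truth_class"]
    for s in sorted(studies, key=lambda s: s.study_id):
        lines.append(f"{s.study_id},{s.truth_class or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_truth_table(path: str | Path) -> dict[str, str]:
    lines = Path(path).read_text().splitlines()
    out = {}
    for line in lines[1:]:
        if line.strip():
            sid, cls = line.split(",", 1)
            out[sid] = cls
    return out
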