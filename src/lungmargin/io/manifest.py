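"""Cohort manifest: one YAML file listing the cases of a study.

Each entry names a case, its laterality, prescription and the paths (relative
to the manifest) of its PTV and ipsilateral-lung masks, plus optionally a dose
volume.  A bilateral patient is encoded as two entries, one left and one
right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import InvalidInputError
from ..model import CohortRecord
from .nifti import read_dose, read_mask, write_dose, write_mask

__all__ = ["ManifestEntry", "CohortManifest", "load_cohort", "write_cohort"]


@dataclass
class ManifestEntry:
    case_id: str
    laterality: str
    prescription_Gy_RBE: float
    ptv_path: str
    lung_path: str
    dose_path: str | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise InvalidInputError(
                f"{self.case_id}: laterality must be left or right, got {self.laterality!r}"
            )
        if not self.prescription_Gy_RBE > 0:
            raise InvalidInputError(f"{self.case_id}: prescription must be positive")


@dataclass
class CohortManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.case_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("case_ids in a manifest must be unique")

    @classmethod
    def load(cls, path) -> "CohortManifest":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "cases" not in payload:
            raise InvalidInputError(f"{path}: manifest must have a 'cases' list")
        entries = [
            ManifestEntry(
                case_id=str(c["case_id"]),
                laterality=str(c["laterality"]),
                prescription_Gy_RBE=float(c["prescription_Gy_RBE"]),
                ptv_path=str(c["ptv"]),
                lung_path=str(c["lung"]),
                dose_path=str(c["dose"]) if c.get("dose") else None,
            )
            for c in payload["cases"]
        ]
        return cls(entries=entries)

    def dump(self, path) -> None:
        payload = {
            "cases": [
                {
                    "case_id": e.case_id,
                    "laterality": e.laterality,
                    "prescription_Gy_RBE": e.prescription_Gy_RBE,
                    "ptv": e.ptv_path,
                    "lung": e.lung_path,
                    **({"dose": e.dose_path} if e.dose_path else {}),
                }
                for e in self.entries
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_cohort(manifest_path) -> list[CohortRecord]:
    """Read every case of a manifest into memory; paths resolve relative to
    the manifest file."""
    manifest_path = Path(manifest_path)
    manifest = CohortManifest.load(manifest_path)
    base = manifest_path.parent
    records = []
    for e in manifest.entries:
        dose = None
        if e.dose_path is not None:
            dose = read_dose(base / e.dose_path, prescription=e.prescription_Gy_RBE)
        records.append(
            CohortRecord(
                case_id=e.case_id,
                laterality=e.laterality,
                ptv=read_mask(base / e.ptv_path),
                ipsilateral_lung=read_mask(base / e.lung_path),
                prescription=e.prescription_Gy_RBE,
                dose=dose,
            )
        )
    return records


def write_cohort(records: list[CohortRecord], out_dir) -> Path:
    """Write a cohort as NIfTI volumes plus ``manifest.yaml``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for r in records:
        ptv_name = f"{r.case_id}_ptv.nii.gz"
        lung_name = f"{r.case_id}_lung.nii.gz"
        write_mask(r.ptv, out_dir / ptv_name)
        write_mask(r.ipsilateral_lung, out_dir / lung_name)
        dose_name = None
        if r.dose is not None:
            dose_name = f"{r.case_id}_dose.nii.gz"
            write_dose(r.dose, out_dir / dose_name)
        entries.append(
            ManifestEntry(
                case_id=r.case_id,
                laterality=r.laterality,
                prescription_Gy_RBE=r.prescription,
                ptv_path=ptv_name,
                lung_path=lung_name,
                dose_path=dose_name,
            )
        )
    manifest_path = out_dir / "manifest.yaml"
    CohortManifest(entries=entries).dump(manifest_path)
    return manifest_path
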