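"""The margin model: calibration, convergence and contour-only prediction.

The model predicts an organ's dose-volume metric V_D from contours alone: the
fraction V(m) of the ipsilateral lung contained in the PTV expanded
isotropically by a margin m serves as the predictor, and m is calibrated per
dose level D by minimizing the root-mean-square error of V(m) − V_D over a
cohort of planned cases,

    m_D = argmin_m  sqrt( ⟨ (V(m) − V_D)² ⟩ ),

with the mean error ME = ⟨ V(m) − V_D ⟩ tracked as a measure of systematic
bias.  Errors are expressed in percentage points of lung volume.  All doses
are rescaled to a common 50.4 Gy(RBE) prescription before V_D extraction, so
the calibrated margins are reference-frame constants.

The shipped defaults map 20 Gy(RBE) → 11 mm and 5 Gy(RBE) → 22 mm.

Calibration is a grid search over candidate margins (default −10 mm to 40 mm
in 0.5 mm steps; negative margins shrink the PTV); ties in RMSE are broken
toward the smallest margin, the conservative choice for lung sparing.  Cohort
growth is monitored by re-evaluating the RMSE after each added case until it
stabilises, which justifies the sample size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dvh import REFERENCE_PRESCRIPTION, rescale_to_reference, volume_at_dose
from .errors import (
    IncompleteRecordError,
    InvalidInputError,
    UnknownDoseLevelError,
)
from .geometry import BinaryMask, DoseGrid
from .morphology import signed_distance_map, v_of_m_curve

__all__ = [
    "CohortRecord",
    "CalibrationResult",
    "ConvergenceResult",
    "DefaultModel",
    "default_margin_grid",
    "prediction_errors",
    "calibrate_margin",
    "convergence_run",
    "predict_volume",
]


@dataclass
class CohortRecord:
    """One patient-side of a cohort.

    A bilateral patient appears as two records, one left and one right.
    ``dose`` may be absent for prediction-only cases; calibration requires it.
    """

    case_id: str
    laterality: str
    ptv: BinaryMask
    ipsilateral_lung: BinaryMask
    prescription: float
    dose: DoseGrid | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        if not self.prescription > 0:
            raise ValueError("prescription must be positive")


@dataclass
class CalibrationResult:
    """Outcome of a margin calibration at one dose level."""

    dose_level: float          # D in Gy(RBE), reference frame
    margin_mm: float           # calibrated m_D
    rmse: float                # percentage points of lung volume
    mean_error: float          # ME, percentage points (signed)
    per_case_errors: list[tuple[str, float]] = field(default_factory=list)
    trace: list[tuple[int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dose_level_Gy_RBE": self.dose_level,
            "margin_mm": self.margin_mm,
            "rmse_pct": self.rmse,
            "me_pct": self.mean_error,
            "per_case_errors_pct": [
                {"case_id": c, "error_pct": e} for c, e in self.per_case_errors
            ],
            "trace": [{"n": n, "rmse_pct": r} for n, r in self.trace],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ConvergenceResult:
    """RMSE trace of the cohort-growth procedure at a fixed margin."""

    trace: list[tuple[int, float]]
    converged_n: int | None

    @property
    def converged(self) -> bool:
        return self.converged_n is not None


@dataclass
class DefaultModel:
    """Dose level (Gy(RBE), reference frame) → calibrated margin (mm)."""

    margins: dict[float, float]
    reference_prescription: float = REFERENCE_PRESCRIPTION
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.margins.values()):
            raise ValueError("default-model margins must be positive")

    def margin_for(self, dose_level: float) -> float:
        for level, margin in self.margins.items():
            if abs(level - dose_level) < 1e-9:
                return margin
        raise UnknownDoseLevelError(
            f"no calibrated margin for D = {dose_level} Gy(RBE); "
            f"available: {sorted(self.margins)}"
        )

    @classmethod
    def shipped(cls) -> "DefaultModel":
        """The packaged default model (20 Gy(RBE) → 11 mm, 5 Gy(RBE) → 22 mm)."""
        text = resources.files("lungmargin.data").joinpath(
            "default_model.json").read_text()
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_dict(cls, payload: dict) -> "DefaultModel":
        return cls(
            margins={float(k): float(v) for k, v in payload["margins_mm"].items()},
            reference_prescription=float(
                payload.get("reference_prescription_Gy_RBE", REFERENCE_PRESCRIPTION)
            ),
            version=str(payload.get("version", "unversioned")),
        )

    @classmethod
    def from_json(cls, path) -> "DefaultModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "reference_prescription_Gy_RBE": self.reference_prescription,
            "margins_mm": {f"{k:g}": v for k, v in self.margins.items()},
        }


def default_margin_grid() -> np.ndarray:
    """Candidate margins for calibration: −10 mm to 40 mm in 0.5 mm steps."""
    return np.arange(-10.0, 40.0 + 1e-9, 0.5)


@dataclass
class _CaseSummary:
    """Cached per-case quantities for fast margin sweeps."""

    case_id: str
    lung_distances: np.ndarray  # sorted PTV signed distances at lung voxels, mm
    v_d: float                  # planned V_D, fraction

    def v_of_m(self, margins: np.ndarray) -> np.ndarray:
        counts = np.searchsorted(self.lung_distances, margins, side="right")
        return counts / self.lung_distances.size


def _summarise(
    record: CohortRecord, dose_level: float, reference: float
) -> _CaseSummary:
    if record.dose is None:
        raise IncompleteRecordError(
            f"case {record.case_id!r} has no dose grid; calibration requires one"
        )
    rescaled = rescale_to_reference(record.dose, reference)
    v_d = volume_at_dose(rescaled, record.ipsilateral_lung, dose_level)
    sdm = signed_distance_map(record.ptv)
    d_lung = np.sort(sdm.values[record.ipsilateral_lung.data])
    return _CaseSummary(case_id=record.case_id, lung_distances=d_lung, v_d=v_d)


def _error_matrix(
    summaries: list[_CaseSummary], margins: np.ndarray
) -> np.ndarray:
    """Per-case prediction errors V(m) − V_D, percentage points; shape (cases, margins)."""
    rows = [100.0 * (s.v_of_m(margins) - s.v_d) for s in summaries]
    return np.vstack(rows)


def prediction_errors(
    cohort: list[CohortRecord],
    margin_mm: float,
    dose_level: float,
    reference: float = REFERENCE_PRESCRIPTION,
) -> tuple[float, float, list[tuple[str, float]]]:
    """RMSE, mean error and per-case errors of V(m) as a predictor of V_D.

    Errors are ``V(m) − V_D`` in percentage points of ipsilateral lung volume,
    with every plan rescaled to the reference prescription first.
    """
    if not cohort:
        raise InvalidInputError("cohort is empty")
    summaries = [_summarise(r, dose_level, reference) for r in cohort]
    errs = _error_matrix(summaries, np.asarray([margin_mm]))[:, 0]
    rmse = float(np.sqrt(np.mean(errs**2)))
    me = float(np.mean(errs))
    return rmse, me, [(s.case_id, float(e)) for s, e in zip(summaries, errs)]


def calibrate_margin(
    cohort: list[CohortRecord],
    dose_level: float,
    m_grid: np.ndarray | None = None,
    reference: float = REFERENCE_PRESCRIPTION,
) -> CalibrationResult:
    """Grid-search the margin minimizing the RMSE of V(m) against planned V_D.

    Ties are broken toward the smallest margin.  The returned result carries
    the RMSE and mean error at the optimum and the per-case error table.
    """
    if not cohort:
        raise InvalidInputError("cohort is empty")
    margins = default_margin_grid() if m_grid is None else np.asarray(m_grid, float)
    if margins.size == 0:
        raise InvalidInputError("margin grid is empty")
    if np.any(np.diff(margins) <= 0):
        raise InvalidInputError("margin grid must be strictly ascending")
    summaries = [_summarise(r, dose_level, reference) for r in cohort]
    errmat = _error_matrix(summaries, margins)
    rmse_per_m = np.sqrt(np.mean(errmat**2, axis=0))
    best = int(np.argmin(rmse_per_m))  # argmin takes the first = smallest margin
    errs = errmat[:, best]
    return CalibrationResult(
        dose_level=dose_level,
        margin_mm=float(margins[best]),
        rmse=float(rmse_per_m[best]),
        mean_error=float(np.mean(errs)),
        per_case_errors=[(s.case_id, float(e)) for s, e in zip(summaries, errs)],
    )


def convergence_run(
    cohort_stream: list[CohortRecord],
    dose_level: float,
    margin_mm: float,
    window: int = 3,
    tol: float = 0.25,
    min_n: int = 10,
    reference: float = REFERENCE_PRESCRIPTION,
) -> ConvergenceResult:
    """Grow the cohort case by case and track the RMSE at a fixed margin.

    Convergence is declared at the first n ≥ ``min_n`` (and n > ``window``)
    where the RMSE changed by at most ``tol`` percentage points relative to
    each of the previous ``window`` cohort sizes.  The stream order is
    caller-controlled.
    """
    if len(cohort_stream) < window + 1:
        raise InvalidInputError(
            f"stream of {len(cohort_stream)} cases is shorter than window + 1 = {window + 1}"
        )
    summaries = [_summarise(r, dose_level, reference) for r in cohort_stream]
    errs = _error_matrix(summaries, np.asarray([margin_mm]))[:, 0]
    cumulative = np.cumsum(errs**2)
    ns = np.arange(1, errs.size + 1)
    rmse = np.sqrt(cumulative / ns)
    trace = [(int(n), float(r)) for n, r in zip(ns, rmse)]
    converged_n: int | None = None
    for i in range(errs.size):
        n = i + 1
        if n < max(min_n, window + 1):
            continue
        recent = rmse[i - window:i]
        if np.max(np.abs(rmse[i] - recent)) <= tol:
            converged_n = n
            break
    return ConvergenceResult(trace=trace, converged_n=converged_n)


def predict_volume(
    ptv: BinaryMask,
    lung: BinaryMask,
    model: DefaultModel | CalibrationResult,
    dose_level: float,
) -> float:
    """Contour-only prediction of V_D: fractional lung volume inside PTV + m_D.

    No dose grid is consulted; the margin comes from the model.  Returns a
    fraction in [0, 1].
    """
    if isinstance(model, CalibrationResult):
        if abs(model.dose_level - dose_level) > 1e-9:
            raise UnknownDoseLevelError(
                f"model calibrated at D = {model.dose_level}, not {dose_level}"
            )
        margin = model.margin_mm
    else:
        margin = model.margin_for(dose_level)
    (_, fraction), = v_of_m_curve(ptv, lung, [margin])
    return fraction
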