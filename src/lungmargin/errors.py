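"""Exception hierarchy for lungmargin.

All package-specific failures derive from :class:`LungMarginError` so callers
(and the CLI) can catch one base class.
"""


class LungMarginError(Exception):
    """Base class for all lungmargin errors."""


class GridMismatchError(LungMarginError):
    """Two volumes that must share a voxel grid do not."""


class DegenerateMaskError(LungMarginError):
    """A mask with no surface (all-true or all-false) where one is required."""


class InsufficientPaddingError(LungMarginError):
    """A margin expansion reached the edge of the voxel grid and would be clipped."""


class EmptyOrganError(LungMarginError):
    """An organ mask with zero voxels where a nonempty organ is required."""


class InvalidPrescriptionError(LungMarginError):
    """A non-positive prescription dose."""


class NoOverlapError(LungMarginError):
    """Dose and target grids have spatially disjoint extents."""


class UndefinedQueryError(LungMarginError):
    """A DVH query with no defined answer (e.g. dose at zero volume)."""


class FalloffNotFoundError(LungMarginError):
    """The dose never drops below the requested isodose level within the scan range."""


class IncompleteRecordError(LungMarginError):
    """A cohort record is missing the dose grid required for calibration."""


class InvalidInputError(LungMarginError):
    """Structurally invalid input (empty cohort, empty margin grid, ...)."""


class UnknownDoseLevelError(LungMarginError):
    """A prediction was requested at a dose level the model was not calibrated for."""


class DegenerateSpecError(LungMarginError):
    """A phantom specification that yields an empty PTV or lung."""


class InvalidFalloffError(LungMarginError):
    """A dose falloff profile that is not strictly decreasing from 1.0 at distance 0."""


class StructureNotFoundError(LungMarginError):
    """A required ROI could not be resolved in an RT-STRUCT file."""


class UnsupportedGeometryError(LungMarginError):
    """RT-STRUCT contour geometry outside the supported planar subset."""


class MalformedDoseError(LungMarginError):
    """An RT-DOSE file missing required tags (e.g. DoseGridScaling)."""


class UnsupportedOrientationError(LungMarginError):
    """A DICOM orientation other than axis-aligned identity (v1 scope)."""


class InvalidMaskError(LungMarginError):
    """A volumetric mask file containing values other than 0 and 1."""
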