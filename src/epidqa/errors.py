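"""Exception hierarchy for epidqa.

All exceptions derive from :class:`EpidQAError` so callers can catch the
package's failures with one clause; most also derive from :class:`ValueError`
because they signal invalid inputs.
"""


class EpidQAError(Exception):
    """Base class for all epidqa errors."""


class ShapeMismatchError(EpidQAError, ValueError):
    """Two images (or an image and a map) do not share geometry."""


class OutOfBoundsError(EpidQAError, ValueError):
    """A requested field or sampling range falls outside the panel."""


class CalibrationDataError(EpidQAError, ValueError):
    """Calibration inputs are unusable (e.g. non-positive flood-dark pixel)."""


class NotCalibratedError(EpidQAError, RuntimeError):
    """A CU conversion was requested before the CU scale was established."""


class ProfileCoverageError(EpidQAError, ValueError):
    """A beam profile does not cover the panel and extrapolation is disabled."""


class RangeError(EpidQAError, ValueError):
    """Two profiles share no overlapping off-axis range."""


class FitError(EpidQAError, ValueError):
    """A polynomial fit cannot be performed (too few points, rank deficiency)."""


class CorrectionValidityError(EpidQAError, ValueError):
    """Applying a correction would produce a non-positive profile value."""


class GammaInputError(EpidQAError, ValueError):
    """Gamma evaluation inputs are invalid (e.g. zero normalization)."""
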