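"""Varian-style EPID dose calibration chain.

A raw portal image is turned into a dose image in calibrated units (CU) in
three steps:

1. dark/flood correction: ``(raw - dark) / (flood - dark)``, rescaled by the
   mean of ``flood - dark`` so the overall signal magnitude is preserved
   (Greer-style normalization).  The flood divides out both detector
   sensitivity and the open-beam non-uniformity.
2. beam-profile restoration: the flood correction also removed the real
   beam's off-axis shape (the "horns"), so each pixel is multiplied by the
   diagonal beam profile evaluated at its radial distance.  Alternatively a
   generic 2D correction map (PDPC-like) replaces this step.
3. CU normalization: 1 CU is defined as the central-axis signal of a fully
   processed 100 MU, 10x10 cm^2 reference delivery, so ``cu_scale`` is the
   reciprocal of that central-axis value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    CalibrationDataError,
    NotCalibratedError,
    ProfileCoverageError,
    ShapeMismatchError,
)
from .geometry import ImageGrid, ProfileCurve, central_axis_value, radial_distance_map
from . import io as _io

__all__ = [
    "CalibrationSet",
    "apply_dark_flood",
    "restore_beam_profile",
    "apply_2d_correction",
    "calibrate_cu",
    "dose_calibrate",
    "process_portal_image",
    "save_calibration",
    "load_calibration",
]

MU_REFERENCE = 100.0
FIELD_REFERENCE_CM = (10.0, 10.0)


@dataclass(frozen=True)
class CalibrationSet:
    """Everything needed to convert a raw portal image to CU.

    ``beam_profile`` is the diagonal profile used to restore the horns,
    normalized to 1 on the central axis.  ``correction_2d``, when present,
    replaces the 1D restoration with an element-wise multiplicative map.
    """

    dark: ImageGrid
    flood: ImageGrid
    beam_profile: ProfileCurve
    cu_scale: float | None = None
    correction_2d: np.ndarray | None = None
    mu_reference: float = MU_REFERENCE
    field_reference_cm: tuple[float, float] = FIELD_REFERENCE_CM
    profile_extrapolation: str = field(default="clamp", compare=False)

    def __post_init__(self) -> None:
        if not self.dark.same_geometry(self.flood):
            raise ShapeMismatchError("dark and flood images must share geometry")
        net = self.flood.values - self.dark.values
        if np.any(net <= 0):
            iy, ix = np.unravel_index(int(np.argmin(net)), net.shape)
            raise CalibrationDataError(
                f"flood - dark is non-positive at pixel (iy={iy}, ix={ix}): {net[iy, ix]:g}"
            )
        p0 = float(np.interp(0.0, self.beam_profile.r_cm, self.beam_profile.value))
        if abs(p0 - 1.0) > 1e-9:
            raise CalibrationDataError(
                f"beam profile must equal 1 at r=0 (got {p0!r}); call ProfileCurve.normalized()"
            )
        if self.cu_scale is not None and self.cu_scale <= 0:
            raise CalibrationDataError(f"cu_scale must be positive, got {self.cu_scale}")
        if self.correction_2d is not None:
            corr = np.asarray(self.correction_2d, dtype=float)
            if corr.shape != self.flood.values.shape:
                raise ShapeMismatchError("correction_2d must match the panel shape")
            if np.any(corr <= 0):
                raise CalibrationDataError("correction_2d must be strictly positive")
            object.__setattr__(self, "correction_2d", corr)


def apply_dark_flood(raw: ImageGrid, cal: CalibrationSet) -> ImageGrid:
    """Dark-field and flood-field correction of a raw image.

    Returns ``(raw - dark) / (flood - dark) * mean(flood - dark)``; the
    rescaling keeps the corrected image on the raw signal scale so the
    chain is dimension-preserving.
    """
    if not raw.same_geometry(cal.dark):
        raise ShapeMismatchError(
            f"raw image {raw.values.shape} does not match calibration {cal.dark.values.shape}"
        )
    net = cal.flood.values - cal.dark.values
    out = (raw.values - cal.dark.values) / net * float(np.mean(net))
    return raw.with_values(out)


def restore_beam_profile(image: ImageGrid, profile: ProfileCurve, *, extrapolate: str = "clamp") -> ImageGrid:
    """Multiply the image by the beam profile evaluated at each pixel's radius.

    This re-introduces the beam non-uniformity the flood correction removed.
    The central-axis value is unchanged because the profile is 1 at r = 0.
    Beyond the profile's last sample the value is held (clamped) with a
    warning, or a :class:`ProfileCoverageError` is raised with
    ``extrapolate='error'``.
    """
    r = radial_distance_map(image)
    r_needed = float(r.max())
    if r_needed > profile.r_max_cm + 1e-9:
        if extrapolate == "error":
            raise ProfileCoverageError(
                f"profile covers r <= {profile.r_max_cm:.3f} cm but the panel "
                f"extends to {r_needed:.3f} cm"
            )
        warnings.warn(
            f"beam profile clamped beyond r = {profile.r_max_cm:.3f} cm "
            f"(panel reaches {r_needed:.3f} cm)",
            stacklevel=2,
        )
    return image.with_values(image.values * profile(r))


def apply_2d_correction(image: ImageGrid, correction_map: np.ndarray) -> ImageGrid:
    """Element-wise multiplication by an externally supplied 2D map.

    Generic hook for PDPC-like correction files; replaces
    :func:`restore_beam_profile` in the chain when a map is configured.
    """
    corr = np.asarray(correction_map, dtype=float)
    if corr.shape != image.values.shape:
        raise ShapeMismatchError(
            f"correction map shape {corr.shape} does not match image {image.values.shape}"
        )
    return image.with_values(image.values * corr)


def calibrate_cu(reference_image: ImageGrid, cal: CalibrationSet) -> CalibrationSet:
    """Set the CU scale from a fully processed 100 MU, 10x10 cm^2 reference.

    ``cu_scale`` becomes the reciprocal of the reference's central-axis
    value (bilinear interpolation at the beam axis), so that
    :func:`dose_calibrate` maps that image's central axis to exactly 1 CU.
    """
    cax = central_axis_value(reference_image)
    if cax <= 0:
        raise CalibrationDataError(f"reference central-axis value must be positive, got {cax:g}")
    return replace(cal, cu_scale=1.0 / cax)


def dose_calibrate(image: ImageGrid, cal: CalibrationSet) -> ImageGrid:
    """Convert a processed image to CU: multiply by the CU scale factor."""
    if cal.cu_scale is None:
        raise NotCalibratedError("cu_scale is unset; run calibrate_cu on a reference image first")
    return image.with_values(image.values * cal.cu_scale)


def process_portal_image(raw: ImageGrid, cal: CalibrationSet, *, to_cu: bool = True) -> ImageGrid:
    """Run the full chain: dark/flood, profile (or 2D map) restoration, CU.

    With ``to_cu=False`` the CU step is skipped (used while establishing
    the CU scale itself).
    """
    img = apply_dark_flood(raw, cal)
    if cal.correction_2d is not None:
        img = apply_2d_correction(img, cal.correction_2d)
    else:
        img = restore_beam_profile(img, cal.beam_profile, extrapolate=cal.profile_extrapolation)
    if to_cu:
        img = dose_calibrate(img, cal)
    return img


def save_calibration(cal: CalibrationSet, directory: str | Path) -> Path:
    """Persist a calibration as dark.csv / flood.csv / beam_profile.csv / meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _io.write_image_csv(directory / "dark.csv", cal.dark)
    _io.write_image_csv(directory / "flood.csv", cal.flood)
    _io.write_profile_csv(directory / "beam_profile.csv", cal.beam_profile)
    if cal.correction_2d is not None:
        _io.write_image_csv(
            directory / "correction_2d.csv",
            ImageGrid(cal.correction_2d, pitch_mm=cal.flood.pitch_mm),
        )
    meta = {
        "cu_scale": cal.cu_scale,
        "mu_reference": cal.mu_reference,
        "field_reference_cm": list(cal.field_reference_cm),
        "profile_extrapolation": cal.profile_extrapolation,
        "has_correction_2d": cal.correction_2d is not None,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_calibration(directory: str | Path) -> CalibrationSet:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    corr = None
    if meta.get("has_correction_2d"):
        corr = _io.read_image_csv(directory / "correction_2d.csv").values
    return CalibrationSet(
        dark=_io.read_image_csv(directory / "dark.csv"),
        flood=_io.read_image_csv(directory / "flood.csv"),
        beam_profile=_io.read_profile_csv(directory / "beam_profile.csv"),
        cu_scale=meta.get("cu_scale"),
        correction_2d=corr,
        mu_reference=meta.get("mu_reference", MU_REFERENCE),
        field_reference_cm=tuple(meta.get("field_reference_cm", FIELD_REFERENCE_CM)),
        profile_extrapolation=meta.get("profile_extrapolation", "clamp"),
    )
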