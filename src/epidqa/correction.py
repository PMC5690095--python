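"""Diagonal-profile polynomial correction for portal-imager calibration.

The off-axis response of the flood-calibrated imager does not match the
planning system's prediction: at large off-axis distances the detector
over-responds by up to ~10%.  The correction derived here follows the 1D
recipe: take the diagonal profiles of a measured and a predicted portal
image of a large open field, normalize both to the central axis, form the
ratio rho(r) = measured/predicted, and fit a polynomial to rho(r) - 1 over
a chosen window.  The fitted correction factor c(r) is then divided out of
the diagonal beam profile used in the dose calibration, so subsequent
images are calibrated with a profile that compensates the detector's
off-axis response.

Three preset modes are provided:

- ``inhouse_large``: 4th-order fit from the central axis to ~22 cm, applied
  to 22 cm (derived from a 38x28 cm^2 field, roughly the largest field of
  interest);
- ``inhouse_20x20``: 4th-order fit to ~11 cm, applied to 14 cm (the 20x20
  field's half-diagonal) and zero beyond — for use with a 20x20 flood;
- ``bailey``: 1st-order (line) fit of the ratio from 10 to 25 cm, applied
  across the whole profile.

Beyond the application radius the correction is exactly zero (hard cutoff);
an optional linear taper can smooth the resulting step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import CorrectionValidityError, FitError, RangeError
from .geometry import ProfileCurve

__all__ = [
    "RatioCurve",
    "PolyCorrection",
    "compute_ratio",
    "fit_correction",
    "correction_factor",
    "apply_profile_correction",
    "derive_correction_mode",
    "MODE_CONSTANTS",
    "save_correction",
    "load_correction",
]

#: Preset constants per derivation mode: polynomial order, fit window (cm)
#: and application radius (cm).  Overridable through fit_correction.
MODE_CONSTANTS: dict[str, dict[str, float]] = {
    "inhouse_large": {"order": 4, "r_fit_min_cm": 0.0, "r_fit_max_cm": 22.0, "r_apply_max_cm": 22.0},
    "inhouse_20x20": {"order": 4, "r_fit_min_cm": 0.0, "r_fit_max_cm": 11.0, "r_apply_max_cm": 14.0},
    # The line fit runs 10-25 cm but the correction is applied across the
    # whole profile; 30 cm exceeds the panel half-diagonal (25 cm).
    "bailey": {"order": 1, "r_fit_min_cm": 10.0, "r_fit_max_cm": 25.0, "r_apply_max_cm": 30.0},
}


@dataclass(frozen=True)
class RatioCurve:
    """measured(r)/predicted(r), both normalized to 1 on the central axis."""

    r_cm: np.ndarray
    ratio: np.ndarray
    orientation: str = field(default="measured_over_predicted", compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r_cm, dtype=float)
        q = np.asarray(self.ratio, dtype=float)
        if r.ndim != 1 or q.shape != r.shape or r.size < 2:
            raise ValueError("r_cm and ratio must be matching 1D arrays with >= 2 samples")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r_cm must be strictly increasing")
        if not np.all(q > 0):
            raise ValueError("ratio values must be positive")
        if r[0] == 0.0 and abs(q[0] - 1.0) > 1e-9:
            raise ValueError(f"ratio must be 1 at r=0 after normalization, got {q[0]!r}")
        object.__setattr__(self, "r_cm", r)
        object.__setattr__(self, "ratio", q)


@dataclass(frozen=True)
class PolyCorrection:
    """A fitted polynomial correction factor c(r).

    ``coefficients`` are constant-term-first for the polynomial in r (cm)
    representing c(r) = fitted(rho) - 1.  The factor is exactly zero for
    r > ``r_apply_max_cm``; ``taper_band_cm`` > 0 ramps c linearly to zero
    over the band just inside the cutoff instead of stepping.
    """

    coefficients: tuple[float, ...]
    order: int
    r_fit_min_cm: float
    r_fit_max_cm: float
    r_apply_max_cm: float
    r_squared: float
    mode: str = "custom"
    ratio_orientation: str = "measured_over_predicted"
    apply_style: str = "divide"
    taper_band_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.r_apply_max_cm <= 0:
            raise ValueError("r_apply_max_cm must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if len(self.coefficients) != self.order + 1:
            raise ValueError("need order + 1 coefficients, constant term first")

    def __call__(self, r) -> np.ndarray:
        return correction_factor(self, r)


def compute_ratio(
    measured: ProfileCurve,
    predicted: ProfileCurve,
    *,
    orientation: str = "measured_over_predicted",
) -> RatioCurve:
    """Central-axis-normalized profile ratio on the measured r grid.

    Both profiles are rescaled to 1 at r = 0, the predicted profile is
    linearly resampled onto the measured grid, and the ratio is restricted
    to the overlapping r range.  ``orientation`` may flip the quotient
    (the inverse reading of the ratio).
    """
    if orientation not in ("measured_over_predicted", "predicted_over_measured"):
        raise ValueError(f"unknown orientation {orientation!r}")
    m = measured.normalized()
    p = predicted.normalized()
    lo = max(m.r_cm[0], p.r_cm[0])
    hi = min(m.r_cm[-1], p.r_cm[-1])
    if hi <= lo:
        raise RangeError(
            f"profiles share no overlapping r range ([{m.r_cm[0]}, {m.r_cm[-1]}] vs "
            f"[{p.r_cm[0]}, {p.r_cm[-1]}] cm)"
        )
    keep = (m.r_cm >= lo - 1e-12) & (m.r_cm <= hi + 1e-12)
    r = m.r_cm[keep]
    p_on_m = np.interp(r, p.r_cm, p.value)
    if np.any(p_on_m == 0):
        raise ZeroDivisionError("predicted profile interpolates to zero inside the overlap")
    ratio = m.value[keep] / p_on_m
    if orientation == "predicted_over_measured":
        ratio = 1.0 / ratio
    return RatioCurve(r, ratio, orientation=orientation)


def fit_correction(
    ratio: RatioCurve,
    order: int,
    r_fit_min_cm: float,
    r_fit_max_cm: float,
    r_apply_max_cm: float,
    *,
    mode: str = "custom",
    taper_band_cm: float = 0.0,
) -> PolyCorrection:
    """Unweighted least-squares polynomial fit of (ratio - 1) over a window.

    Fitting the deviation from unity rather than the ratio itself makes the
    no-correction case the exact zero polynomial.  R^2 is computed on the
    fit window against (ratio - 1); when the window has zero variance, R^2
    is defined as 1 for a perfect fit and 0 otherwise.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    sel = (ratio.r_cm >= r_fit_min_cm) & (ratio.r_cm <= r_fit_max_cm)
    r = ratio.r_cm[sel]
    y = ratio.ratio[sel] - 1.0
    if r.size < order + 1:
        raise FitError(
            f"need at least {order + 1} samples in [{r_fit_min_cm}, {r_fit_max_cm}] cm, "
            f"have {r.size}"
        )
    design = np.vander(r, order + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < order + 1:
        raise FitError(f"rank-deficient design (rank {rank} < {order + 1}); degenerate r samples")
    y_hat = design @ coeffs
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r_squared = 1.0 if ss_res <= 1e-24 else 0.0
    else:
        r_squared = min(1.0, max(0.0, 1.0 - ss_res / ss_tot))
    # Exact-zero ratios should produce the exact zero polynomial.
    coeffs[np.abs(coeffs) < 1e-15] = 0.0
    return PolyCorrection(
        coefficients=tuple(float(c) for c in coeffs),
        order=order,
        r_fit_min_cm=float(r_fit_min_cm),
        r_fit_max_cm=float(r_fit_max_cm),
        r_apply_max_cm=float(r_apply_max_cm),
        r_squared=r_squared,
        mode=mode,
        ratio_orientation=ratio.orientation,
        taper_band_cm=float(taper_band_cm),
    )


def correction_factor(corr: PolyCorrection, r) -> np.ndarray | float:
    """Evaluate c(r): the polynomial inside the application radius, 0 beyond.

    The cutoff is hard (the correction "is set to zero" past the
    application radius); a positive ``taper_band_cm`` instead ramps the
    factor linearly to zero across the band ending at the cutoff.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("off-axis distance r must be non-negative")
    c = np.polynomial.polynomial.polyval(r_arr, np.asarray(corr.coefficients))
    if corr.taper_band_cm > 0:
        start = corr.r_apply_max_cm - corr.taper_band_cm
        w = np.clip((corr.r_apply_max_cm - r_arr) / corr.taper_band_cm, 0.0, 1.0)
        c = np.where(r_arr <= start, c, c * w)
    c = np.where(r_arr > corr.r_apply_max_cm, 0.0, c)
    return float(c) if np.isscalar(r) or r_arr.ndim == 0 else c


def apply_profile_correction(profile: ProfileCurve, corr: PolyCorrection) -> ProfileCurve:
    """Correct a calibration beam profile: P(r) / (1 + c(r)), CAX-renormalized.

    Division (the default ``apply_style``) means an over-responding detector
    (measured > predicted, c > 0) gets its calibration profile reduced.
    Beyond the application radius c = 0 and the profile is unchanged (up to
    the final central-axis renormalization).
    """
    c = correction_factor(corr, profile.r_cm)
    denom = 1.0 + np.asarray(c, dtype=float)
    if np.any(denom <= 0):
        raise CorrectionValidityError("1 + c(r) must stay positive over the profile")
    if corr.apply_style == "divide":
        corrected = profile.value / denom
    elif corr.apply_style == "multiply":
        corrected = profile.value * denom
    else:
        raise ValueError(f"unknown apply_style {corr.apply_style!r}")
    return ProfileCurve(profile.r_cm, corrected, name=profile.name).normalized()


def derive_correction_mode(
    mode: str,
    measured: ProfileCurve,
    predicted: ProfileCurve,
    *,
    orientation: str = "measured_over_predicted",
    **overrides,
) -> PolyCorrection:
    """Chain compute_ratio and fit_correction with a preset mode's constants.

    Keyword ``overrides`` may replace any of the mode constants (order,
    fit window, application radius), e.g. to shorten the fit window when
    the available diagonal is shorter than the preset.
    """
    if mode not in MODE_CONSTANTS:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(MODE_CONSTANTS)}")
    params = {**MODE_CONSTANTS[mode], **overrides}
    ratio = compute_ratio(measured, predicted, orientation=orientation)
    return fit_correction(
        ratio,
        order=int(params["order"]),
        r_fit_min_cm=params["r_fit_min_cm"],
        r_fit_max_cm=params["r_fit_max_cm"],
        r_apply_max_cm=params["r_apply_max_cm"],
        mode=mode,
        taper_band_cm=params.get("taper_band_cm", 0.0),
    )


def save_correction(corr: PolyCorrection, path: str | Path) -> Path:
    path = Path(path)
    payload = asdict(corr)
    payload["coefficients"] = list(corr.coefficients)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_correction(path: str | Path) -> PolyCorrection:
    payload = json.loads(Path(path).read_text())
    payload["coefficients"] = tuple(payload["coefficients"])
    return PolyCorrection(**payload)
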