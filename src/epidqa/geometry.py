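"""Physical coordinate model of the EPID panel.

The amorphous-silicon portal imager is modelled as a rectangular grid of
square pixels.  The default hardware is an aS1000-class panel: a 40x30 cm^2
sensitive area read out as a 512x384 matrix, i.e. a pixel pitch of
400/512 = 0.78125 mm, mounted with the beam axis through the panel centre
(source-to-imager distance 100 cm, panel at isocenter).

Axis convention
---------------
+X points toward patient left, +Y toward the gantry side of the imager
(where the support arm sits).  Array storage is ``values[iy, ix]`` with row
0 on the gantry side, so CSV dumps read top-to-bottom as gantry-to-target.
Pixel centres sit at

    x(ix) = (ix - (n_x - 1)/2) * pitch,    y(iy) = ((n_y - 1)/2 - iy) * pitch,

which places the beam axis exactly between pixels on an even-dimensioned
panel.  Off-axis distances ``r`` are in cm throughout; the pitch is carried
in mm as the vendor quotes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import OutOfBoundsError, RangeError

__all__ = [
    "ImageGrid",
    "ProfileCurve",
    "pixel_pitch",
    "radial_distance_map",
    "extract_diagonal_profile",
    "sample_bilinear",
    "central_axis_value",
]

#: Source-to-imager distance, cm.  Fixed: all images live at the calibration
#: location (isocenter); other SIDs are out of scope.
SID_CM = 100.0


def pixel_pitch(sensitive_length_mm: float, n_pixels: int) -> float:
    """Pixel pitch in mm of a panel axis: sensitive length / pixel count.

    For the reference panel both axes give the same square pitch:
    400/512 = 300/384 = 0.78125 mm (quoted as 0.781 mm).
    """
    if sensitive_length_mm <= 0:
        raise ValueError(f"sensitive_length_mm must be positive, got {sensitive_length_mm}")
    if n_pixels <= 0 or int(n_pixels) != n_pixels:
        raise ValueError(f"n_pixels must be a positive integer, got {n_pixels}")
    return sensitive_length_mm / int(n_pixels)


@dataclass(frozen=True)
class ImageGrid:
    """A 2D portal image with physical geometry.

    Parameters
    ----------
    values
        Array of shape ``(n_y, n_x)``; signal in arbitrary units or CU.
    pitch_mm
        Square pixel pitch in mm.
    """

    values: np.ndarray
    pitch_mm: float = 0.78125

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(f"values must be a non-empty 2D array, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch_mm must be positive, got {self.pitch_mm}")
        object.__setattr__(self, "values", values)

    @property
    def n_x(self) -> int:
        return self.values.shape[1]

    @property
    def n_y(self) -> int:
        return self.values.shape[0]

    @property
    def pitch_cm(self) -> float:
        return self.pitch_mm / 10.0

    @property
    def extent_x_cm(self) -> float:
        """Physical width along X: n_x * pitch."""
        return self.n_x * self.pitch_cm

    @property
    def extent_y_cm(self) -> float:
        return self.n_y * self.pitch_cm

    @property
    def half_diagonal_cm(self) -> float:
        return float(np.hypot(self.extent_x_cm / 2.0, self.extent_y_cm / 2.0))

    def x_coords_cm(self) -> np.ndarray:
        """Pixel-centre X coordinates (cm), increasing with column index."""
        return (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch_cm

    def y_coords_cm(self) -> np.ndarray:
        """Pixel-centre Y coordinates (cm) per row; row 0 is the gantry side."""
        return ((self.n_y - 1) / 2.0 - np.arange(self.n_y)) * self.pitch_cm

    def same_geometry(self, other: "ImageGrid") -> bool:
        return self.values.shape == other.values.shape and np.isclose(
            self.pitch_mm, other.pitch_mm, rtol=0, atol=1e-9
        )

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values=np.asarray(values, dtype=float), pitch_mm=self.pitch_mm)


def radial_distance_map(grid: ImageGrid) -> np.ndarray:
    """Per-pixel Euclidean distance (cm) from the beam axis.

    Symmetric under 180-degree rotation about the panel centre and bounded
    by the panel half-diagonal.
    """
    x = grid.x_coords_cm()
    y = grid.y_coords_cm()
    return np.hypot(x[None, :], y[:, None])


def sample_bilinear(grid: ImageGrid, x_cm, y_cm, *, clip: bool = True) -> np.ndarray:
    """Bilinear interpolation of the image at physical points (x, y) in cm.

    Coordinates beyond the outermost pixel centres are clamped to the edge
    when ``clip`` is true, otherwise they produce NaN.
    """
    x_cm = np.asarray(x_cm, dtype=float)
    y_cm = np.asarray(y_cm, dtype=float)
    p = grid.pitch_cm
    jx = x_cm / p + (grid.n_x - 1) / 2.0
    iy = (grid.n_y - 1) / 2.0 - y_cm / p
    if clip:
        jx = np.clip(jx, 0.0, grid.n_x - 1.0)
        iy = np.clip(iy, 0.0, grid.n_y - 1.0)
    inside = (jx >= 0) & (jx <= grid.n_x - 1) & (iy >= 0) & (iy <= grid.n_y - 1)
    j0 = np.clip(np.floor(jx).astype(int), 0, grid.n_x - 2) if grid.n_x > 1 else np.zeros_like(jx, int)
    i0 = np.clip(np.floor(iy).astype(int), 0, grid.n_y - 2) if grid.n_y > 1 else np.zeros_like(iy, int)
    fj = jx - j0
    fi = iy - i0
    v = grid.values
    j1 = np.minimum(j0 + 1, grid.n_x - 1)
    i1 = np.minimum(i0 + 1, grid.n_y - 1)
    out = (
        v[i0, j0] * (1 - fi) * (1 - fj)
        + v[i0, j1] * (1 - fi) * fj
        + v[i1, j0] * fi * (1 - fj)
        + v[i1, j1] * fi * fj
    )
    if not clip:
        out = np.where(inside, out, np.nan)
    return out


def central_axis_value(grid: ImageGrid) -> float:
    """Signal at the beam axis, bilinearly interpolated.

    On an even-dimensioned panel the beam axis falls between pixels, so a
    nearest-pixel readout would be biased; interpolation is used instead.
    """
    return float(sample_bilinear(grid, 0.0, 0.0))


@dataclass(frozen=True)
class ProfileCurve:
    """A sampled 1D profile P(r) of diagonal off-axis distance r (cm).

    ``r_cm`` must be strictly increasing and non-negative; values must be
    positive.  Profiles anchored at the central axis start at r = 0.
    """

    r_cm: np.ndarray
    value: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r_cm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if r.ndim != 1 or v.shape != r.shape or r.size < 2:
            raise ValueError("r_cm and value must be matching 1D arrays with >= 2 samples")
        if r[0] < 0 or np.any(np.diff(r) <= 0):
            raise ValueError("r_cm must be non-negative and strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError("profile values must be finite and positive")
        object.__setattr__(self, "r_cm", r)
        object.__setattr__(self, "value", v)

    @property
    def r_max_cm(self) -> float:
        return float(self.r_cm[-1])

    def __call__(self, r, *, extrapolate: str = "clamp") -> np.ndarray:
        """Linear interpolation of the profile at r (cm).

        ``extrapolate='clamp'`` holds the end values beyond the sampled
        range; ``'error'`` raises :class:`RangeError` instead.
        """
        r = np.asarray(r, dtype=float)
        if extrapolate == "error" and (np.any(r < self.r_cm[0]) or np.any(r > self.r_cm[-1])):
            raise RangeError(
                f"requested r outside profile range [{self.r_cm[0]}, {self.r_cm[-1]}] cm"
            )
        return np.interp(r, self.r_cm, self.value)

    def normalized(self) -> "ProfileCurve":
        """Profile rescaled so the r = 0 (or innermost) value is exactly 1."""
        v0 = float(np.interp(0.0, self.r_cm, self.value))
        return ProfileCurve(self.r_cm, self.value / v0, name=self.name)


def extract_diagonal_profile(
    image: ImageGrid,
    n_samples: int,
    r_max_cm: float,
    *,
    symmetrize: bool = False,
    angle_deg: float = 45.0,
) -> ProfileCurve:
    """Sample a diagonal profile from the panel centre outward.

    Values are bilinearly interpolated at ``n_samples`` uniformly spaced
    radii from 0 to ``r_max_cm`` along a ray at ``angle_deg`` from the +X
    axis (45 degrees by default, i.e. toward gantry/patient-left).  With
    ``symmetrize`` the two opposite rays are averaged, which cancels the
    odd (arm-backscatter) component of the response.

    ``angle_deg`` exists because "the diagonal" of a non-square field or
    panel is not at 45 degrees: the corner of a 38x28 cm^2 field lies along
    atan(14/19) ~ 36.4 degrees, and only along that ray does the profile
    extend to the 23.6 cm half-diagonal.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if r_max_cm <= 0:
        raise ValueError("r_max_cm must be positive")
    if r_max_cm > image.half_diagonal_cm + 1e-9:
        raise OutOfBoundsError(
            f"r_max_cm={r_max_cm} exceeds panel half-diagonal {image.half_diagonal_cm:.3f} cm"
        )
    r = np.linspace(0.0, r_max_cm, n_samples)
    theta = np.deg2rad(angle_deg)
    vx, vy = np.cos(theta), np.sin(theta)
    vals = sample_bilinear(image, r * vx, r * vy, clip=True)
    if symmetrize:
        vals = 0.5 * (vals + sample_bilinear(image, -r * vx, -r * vy, clip=True))
    return ProfileCurve(r, vals)
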