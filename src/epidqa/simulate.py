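"""Parametric synthetic EPID image generator.

Produces measured/predicted portal-image pairs and calibration inputs with
the spatial structure seen on real amorphous-silicon portal imagers:

- radially symmetric beam "horns" P(r) (flattening-filter off-axis rise);
- a radial detector over-response rho_true(r) relative to the calibration
  (flood) condition, reaching ~+10% at large off-axis distance;
- additive arm backscatter on the gantry half of the panel, scaled by how
  much of the panel the field covers (a full flood embeds more backscatter
  than a small field, which is what makes flood-corrected small fields
  under-respond on the gantry side);
- a smooth fixed random sensitivity map, a uniform scatter floor, dark
  signal, and multiplicative Gaussian noise.

Everything is a parametric stand-in calibrated to the documented effect
magnitudes (2-3% small-field asymmetry, up to 10% off-axis discrepancy,
correction factors spanning -0.4% to +9.9%); none of it claims to model a
specific vendor's hardware.  All randomness is seeded, so identical
configurations produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import OutOfBoundsError
from .geometry import ImageGrid, ProfileCurve, radial_distance_map

__all__ = [
    "SimConfig",
    "make_field_fluence",
    "simulate_predicted",
    "simulate_raw",
    "make_calibration_inputs",
    "golden_beam_profile",
    "dark_map",
    "synthetic_ratio_curve",
    "fit_check_quartic_coeffs",
    "FLOOD_FIELDS",
]

#: Flood-field jaw settings (x1, x2, y1, y2 half-extents in cm) per name.
FLOOD_FIELDS = {
    "f40x30": (20.0, 20.0, 15.0, 15.0),
    "f40x32": (20.0, 20.0, 16.0, 16.0),  # clipped to the 40x30 panel
    "f20x20": (10.0, 10.0, 10.0, 10.0),
}

#: Default beam-horn even polynomial P(r) = 1 + a2 r^2 + a4 r^4 (r in cm):
#: ~+3% at 15 cm, peaking ~+4.6% near 20 cm.  A mild flattened-beam shape.
DEFAULT_HORN_COEFFS = (1.8e-4, -2.2e-7)

#: Default over-response rho_true(r) = 1 + a2 r^2 + a4 r^4, chosen so that
#: rho - 1 spans -0.40% (at r ~ 8.9 cm) to +9.9% (at 22 cm) over 0-22 cm.
DEFAULT_OVERRESPONSE_COEFFS = (-1.0e-4, 6.3e-7)


@dataclass(frozen=True)
class SimConfig:
    """Simulator settings; defaults are the package's study conditions.

    ``backscatter_amplitude`` is the saturated additive arm signal as a
    fraction of the central-axis signal for a panel-covering field;
    ``backscatter_extent_cm`` is the distance over which the ramp
    saturates on the gantry side.  ``scatter_fraction`` is a uniform
    field-scatter floor (also coverage-scaled) that keeps flood images
    strictly positive outside the collimated area.
    """

    n_x: int = 512
    n_y: int = 384
    pitch_mm: float = 0.78125
    horn_coeffs: tuple[float, float] = DEFAULT_HORN_COEFFS
    overresponse_coeffs: tuple[float, float] = DEFAULT_OVERRESPONSE_COEFFS
    backscatter_amplitude: float = 0.03
    backscatter_extent_cm: float = 15.0
    scatter_fraction: float = 0.01
    sensitivity_amplitude: float = 0.003
    sensitivity_seed: int = 20150308
    noise_sigma: float = 0.002
    noise_seed: int = 499
    dark_level: float = 0.02
    dark_jitter: float = 0.001
    penumbra_cm: float = 0.3

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2 or self.pitch_mm <= 0:
            raise ValueError("panel must have n_x, n_y >= 2 and positive pitch")
        if self.backscatter_amplitude < 0 or self.backscatter_extent_cm <= 0:
            raise ValueError("backscatter parameters must be non-negative / positive")
        if self.noise_sigma < 0 or self.sensitivity_amplitude < 0 or self.scatter_fraction < 0:
            raise ValueError("noise, sensitivity and scatter amplitudes must be >= 0")

    def blank(self) -> ImageGrid:
        return ImageGrid(np.zeros((self.n_y, self.n_x)), pitch_mm=self.pitch_mm)

    def horn_profile_values(self, r) -> np.ndarray:
        a2, a4 = self.horn_coeffs
        r = np.asarray(r, dtype=float)
        return 1.0 + a2 * r**2 + a4 * r**4

    def overresponse_values(self, r) -> np.ndarray:
        a2, a4 = self.overresponse_coeffs
        r = np.asarray(r, dtype=float)
        return 1.0 + a2 * r**2 + a4 * r**4

    def distortion_free(self) -> "SimConfig":
        """Copy with every distortion switched off (ideal detector)."""
        return replace(
            self,
            overresponse_coeffs=(0.0, 0.0),
            backscatter_amplitude=0.0,
            scatter_fraction=0.0,
            sensitivity_amplitude=0.0,
            noise_sigma=0.0,
            dark_level=0.0,
            dark_jitter=0.0,
        )


def golden_beam_profile(config: SimConfig, r_max_cm: float = 25.0, n_samples: int = 501) -> ProfileCurve:
    """The diagonal beam profile P(r) used for horn restoration, P(0) = 1.

    Stands in for the vendor's 40x40 cm^2 water-measured diagonal data.
    """
    r = np.linspace(0.0, r_max_cm, n_samples)
    return ProfileCurve(r, config.horn_profile_values(r), name="golden_diagonal")


def _axis_coverage(coords: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Fractional in-field coverage along one axis with a linear penumbra
    ramp of width ``ramp`` centred on each jaw edge."""
    if ramp <= 0:
        return ((coords >= lo) & (coords <= hi)).astype(float)
    up = np.clip((coords - lo) / ramp + 0.5, 0.0, 1.0)
    down = np.clip((hi - coords) / ramp + 0.5, 0.0, 1.0)
    return up * down


def make_field_fluence(
    config: SimConfig,
    x1_cm: float,
    x2_cm: float,
    y1_cm: float,
    y2_cm: float,
    pattern: str = "open",
    *,
    clip_to_panel: bool = False,
) -> ImageGrid:
    """Fluence of a jaw-collimated field spanning [-x1, x2] x [-y1, y2] cm.

    Patterns: ``open`` (uniform, 1 at CAX), ``split_imrt`` (two abutting
    half-fields with unequal weights and a modulated junction, the shape
    that defeats a 14 cm correction radius when half-extents exceed 10 cm),
    ``pyramid`` (three concentric intensity steps).  Jaw edges get a 3 mm
    linear penumbra ramp.
    """
    if min(x1_cm, x2_cm, y1_cm, y2_cm) <= 0:
        raise ValueError("jaw half-extents must be positive")
    grid = config.blank()
    hx = grid.extent_x_cm / 2.0
    hy = grid.extent_y_cm / 2.0
    if clip_to_panel:
        x1_cm, x2_cm = min(x1_cm, hx), min(x2_cm, hx)
        y1_cm, y2_cm = min(y1_cm, hy), min(y2_cm, hy)
    if x1_cm > hx + 1e-9 or x2_cm > hx + 1e-9 or y1_cm > hy + 1e-9 or y2_cm > hy + 1e-9:
        raise OutOfBoundsError(
            f"field [-{x1_cm}, {x2_cm}] x [-{y1_cm}, {y2_cm}] cm exceeds the "
            f"{2 * hx:g}x{2 * hy:g} cm panel"
        )
    x = grid.x_coords_cm()
    y = grid.y_coords_cm()
    ramp = config.penumbra_cm
    fy = _axis_coverage(y, -y1_cm, y2_cm, ramp)[:, None]

    if pattern == "open":
        fx = _axis_coverage(x, -x1_cm, x2_cm, ramp)[None, :]
        values = fx * fy
    elif pattern == "split_imrt":
        left = _axis_coverage(x, -x1_cm, 0.0, ramp)[None, :]
        right = _axis_coverage(x, 0.0, x2_cm, ramp)[None, :]
        modulation = 1.0 + 0.05 * np.cos(2 * np.pi * y / 10.0)[:, None]
        values = (1.0 * left + 0.93 * right) * fy * modulation
    elif pattern == "pyramid":
        values = np.zeros((config.n_y, config.n_x))
        for scale, level in ((1.0, 0.4), (2.0 / 3.0, 0.3), (1.0 / 3.0, 0.3)):
            fx = _axis_coverage(x, -x1_cm * scale, x2_cm * scale, ramp)[None, :]
            fy_s = _axis_coverage(y, -y1_cm * scale, y2_cm * scale, ramp)[:, None]
            values = values + level * fx * fy_s
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return grid.with_values(values)


def simulate_predicted(fluence: ImageGrid, config: SimConfig) -> ImageGrid:
    """Noise-free prediction surrogate: fluence times the radially
    symmetric horn profile, 1.0 at CAX for the open 10x10 reference."""
    r = radial_distance_map(fluence)
    return fluence.with_values(fluence.values * config.horn_profile_values(r))


def _sensitivity_map(config: SimConfig) -> np.ndarray:
    """Smooth fixed pixel-sensitivity map, mean ~1, seeded."""
    if config.sensitivity_amplitude == 0:
        return np.ones((config.n_y, config.n_x))
    rng = np.random.default_rng(config.sensitivity_seed)
    coarse = rng.standard_normal((6, 8))
    coarse -= coarse.mean()
    smooth = ndimage.zoom(coarse, (config.n_y / 6.0, config.n_x / 8.0), order=3, grid_mode=True, mode="nearest")
    peak = np.abs(smooth).max()
    return 1.0 + config.sensitivity_amplitude * smooth / peak


def _backscatter_map(config: SimConfig) -> np.ndarray:
    """Arm-backscatter shape: zero on the non-arm half, concave rise toward
    the gantry side saturating at the extent, times the amplitude."""
    grid = config.blank()
    y = grid.y_coords_cm()
    frac = np.sqrt(np.clip(y / config.backscatter_extent_cm, 0.0, 1.0))
    return config.backscatter_amplitude * np.repeat(frac[:, None], config.n_x, axis=1)


def dark_map(config: SimConfig) -> ImageGrid:
    """The dark-signal image: a constant level plus a small fixed random
    offset.  Deterministic per config, so the dark calibration image and
    the dark content of raw acquisitions are the same array."""
    rng = np.random.default_rng((config.noise_seed, 0xDA))
    values = config.dark_level + config.dark_jitter * rng.standard_normal((config.n_y, config.n_x))
    return ImageGrid(np.maximum(values, 0.0), pitch_mm=config.pitch_mm)


def _coverage(fluence: ImageGrid) -> float:
    peak = float(fluence.values.max())
    if peak <= 0:
        return 0.0
    return float(fluence.values.mean()) / peak


def simulate_raw(
    fluence: ImageGrid,
    config: SimConfig,
    *,
    include_overresponse: bool = True,
    noise_stream: int = 0,
) -> ImageGrid:
    """Raw detector image of a fluence, with all configured distortions.

    raw = [F.P(r).rho(r).S(x,y) + (scatter + backscatter).coverage + dark]
          x (1 + noise)

    ``rho`` is the off-axis over-response *relative to the flood
    calibration condition*; calibration floods are generated with
    ``include_overresponse=False`` (see make_calibration_inputs).
    ``noise_stream`` decorrelates the noise of different acquisitions while
    keeping every image reproducible from the config seeds.
    """
    r = radial_distance_map(fluence)
    signal = fluence.values * config.horn_profile_values(r)
    if include_overresponse:
        signal = signal * config.overresponse_values(r)
    signal = signal * _sensitivity_map(config)
    cov = _coverage(fluence)
    signal = signal + cov * (config.scatter_fraction + _backscatter_map(config))
    signal = signal + dark_map(config).values
    if config.noise_sigma > 0:
        rng = np.random.default_rng((config.noise_seed, 1 + noise_stream))
        signal = signal * (1.0 + config.noise_sigma * rng.standard_normal(signal.shape))
    return fluence.with_values(signal)


def fit_check_quartic_coeffs() -> np.ndarray:
    """Ground-truth quartic (constant term first) for fit-quality checks.

    Interpolates c(r) through (0, 0), (5.5, -9%), (11, -5%), (16.5, +4%),
    (22, +9.9%): a smooth curve whose deviation from unity stays within
    +/-10% while swinging through most of that allowance, the regime in
    which a fourth-order fit of a lightly noisy ratio reaches R^2 ~ 0.9997.
    """
    r_nodes = np.array([0.0, 5.5, 11.0, 16.5, 22.0])
    c_nodes = np.array([0.0, -0.09, -0.05, 0.04, 0.099])
    return np.polynomial.polynomial.polyfit(r_nodes, c_nodes, 4)


def synthetic_ratio_curve(
    seed: int,
    coeffs: np.ndarray | None = None,
    noise_sigma: float = 0.001,
    r_max_cm: float = 22.0,
    pitch_mm: float = 0.78125,
):
    """A synthetic measured/predicted ratio curve: ground-truth polynomial
    times multiplicative Gaussian noise, sampled at one point per pixel
    pitch and renormalized to 1 at the central axis.

    Returns a :class:`~epidqa.correction.RatioCurve`.
    """
    from .correction import RatioCurve

    if coeffs is None:
        coeffs = fit_check_quartic_coeffs()
    r = np.arange(0.0, r_max_cm + 1e-9, pitch_mm / 10.0)
    clean = 1.0 + np.polynomial.polynomial.polyval(r, np.asarray(coeffs))
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + rng.normal(0.0, noise_sigma, r.size)) if noise_sigma > 0 else clean
    return RatioCurve(r, noisy / noisy[0])


def make_calibration_inputs(
    config: SimConfig, flood_field: str = "f40x30"
) -> tuple[ImageGrid, ImageGrid, ImageGrid]:
    """Dark, flood, and raw 10x10 / 100 MU reference images.

    The flood is a raw acquisition of the chosen open flood fluence
    (40x32 is clipped to the panel) *without* the over-response term: the
    over-response is defined relative to the flood condition, which is why
    flood division does not cancel it out of measurement fields.
    """
    if flood_field not in FLOOD_FIELDS:
        raise ValueError(f"unknown flood field {flood_field!r}; choose from {sorted(FLOOD_FIELDS)}")
    x1, x2, y1, y2 = FLOOD_FIELDS[flood_field]
    flood_fluence = make_field_fluence(config, x1, x2, y1, y2, "open", clip_to_panel=True)
    flood = simulate_raw(flood_fluence, config, include_overresponse=False, noise_stream=1)
    reference_fluence = make_field_fluence(config, 5.0, 5.0, 5.0, 5.0, "open")
    reference = simulate_raw(reference_fluence, config, noise_stream=2)
    return dark_map(config), flood, reference
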