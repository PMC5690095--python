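"""Global gamma-index comparison of portal dose images.

For each reference pixel the gamma index is the minimum, over positions in
the evaluated image, of

    gamma = sqrt( d^2 / dta^2  +  dD^2 / crit^2 )

where ``d`` is the spatial offset, ``dta`` the distance-to-agreement
criterion (mm), ``dD`` the dose difference at that position, and ``crit``
the dose criterion expressed as a fraction of a global normalization value
(the reference maximum by default, optionally its central axis).  A pixel
passes when gamma <= 1 (ties pass).  The default criterion is 3%, 3 mm.

Two implementations are provided: :func:`gamma_map`, which minimizes over a
grid of sub-pixel offsets using weighted array slices, and
:func:`gamma_oracle`, an exhaustive fine-grid search built on scipy's
interpolator, kept as an independent ground truth for testing.  Because the
coarse offset grid is a subset of the oracle's fine grid, gamma_map is
always >= the oracle value, within floating-point noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GammaInputError, ShapeMismatchError
from .geometry import ImageGrid, central_axis_value

__all__ = ["GammaParams", "GammaResult", "gamma_map", "gamma_oracle", "pass_rate_summary"]


@dataclass(frozen=True)
class GammaParams:
    """Gamma criteria and search configuration.

    ``low_dose_threshold_pct`` excludes reference pixels below that
    percentage of the normalization value (0 evaluates every pixel).
    ``search_radius_factor`` bounds the search at that multiple of the
    distance criterion; ``search_subsample`` sets the offset-grid step to
    ``distance_criterion_mm / search_subsample``.
    """

    dose_criterion_pct: float = 3.0
    distance_criterion_mm: float = 3.0
    normalization: str = "global_max"
    low_dose_threshold_pct: float = 0.0
    search_radius_factor: float = 3.0
    search_subsample: int = 10

    def __post_init__(self) -> None:
        if self.dose_criterion_pct <= 0 or self.distance_criterion_mm <= 0:
            raise ValueError("dose and distance criteria must be positive")
        if self.normalization not in ("global_max", "global_cax"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not (0.0 <= self.low_dose_threshold_pct < 100.0):
            raise ValueError("low_dose_threshold_pct must lie in [0, 100)")
        if self.search_radius_factor <= 0 or self.search_subsample < 1:
            raise ValueError("search_radius_factor and search_subsample must be positive")


@dataclass(frozen=True)
class GammaResult:
    """Per-pixel gamma map (NaN where not evaluated) and its pass rate."""

    gamma: np.ndarray
    pass_rate_pct: float
    n_evaluated: int
    params: GammaParams = field(compare=False, default=GammaParams())

    @property
    def n_passing(self) -> int:
        return int(np.sum(self.gamma[np.isfinite(self.gamma)] <= 1.0))


def _normalization_value(reference: ImageGrid, params: GammaParams) -> float:
    if params.normalization == "global_max":
        norm = float(reference.values.max())
    else:
        norm = central_axis_value(reference)
    if norm <= 0:
        raise GammaInputError(f"reference normalization value must be positive, got {norm:g}")
    return norm


def _offset_grid(params: GammaParams, subsample: int) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (mm) on a centred square grid, kept within the search radius."""
    dta = params.distance_criterion_mm
    step = dta / subsample
    radius = params.search_radius_factor * dta
    n = int(math.floor(radius / step + 1e-9))
    axis = np.arange(-n, n + 1) * step
    ox, oy = np.meshgrid(axis, axis)
    ox, oy = ox.ravel(), oy.ravel()
    keep = np.hypot(ox, oy) <= radius * (1 + 1e-12)
    return ox[keep], oy[keep]


def _finalize(
    gamma: np.ndarray, reference: ImageGrid, params: GammaParams, norm: float
) -> GammaResult:
    evaluated_mask = reference.values >= params.low_dose_threshold_pct / 100.0 * norm
    gamma = np.where(evaluated_mask, gamma, np.nan)
    n_eval = int(evaluated_mask.sum())
    if n_eval == 0:
        raise GammaInputError("low-dose threshold excluded every reference pixel")
    n_pass = int(np.sum(gamma[evaluated_mask] <= 1.0))
    return GammaResult(
        gamma=gamma,
        pass_rate_pct=100.0 * n_pass / n_eval,
        n_evaluated=n_eval,
        params=params,
    )


def _shifted_bilinear(padded: np.ndarray, pad: int, di: float, dj: float, shape) -> np.ndarray:
    """Evaluated image sampled at every pixel plus a constant sub-pixel shift.

    ``padded`` is the evaluated image inside a NaN border of width ``pad``;
    samples that fall outside the true image pick up NaN and are ignored by
    the running minimum.
    """
    h, w = shape
    i0 = math.floor(di)
    j0 = math.floor(dj)
    fi = di - i0
    fj = dj - j0
    bi = pad + i0
    bj = pad + j0
    terms = (
        ((1 - fi) * (1 - fj), padded[bi : bi + h, bj : bj + w]),
        ((1 - fi) * fj, padded[bi : bi + h, bj + 1 : bj + 1 + w]),
        (fi * (1 - fj), padded[bi + 1 : bi + 1 + h, bj : bj + w]),
        (fi * fj, padded[bi + 1 : bi + 1 + h, bj + 1 : bj + 1 + w]),
    )
    # skip zero-weight corners: 0 * NaN would otherwise poison exact
    # integer shifts along the image border
    out = None
    for weight, corner in terms:
        if weight > 0:
            out = weight * corner if out is None else out + weight * corner
    return out


def _check_pair(reference: ImageGrid, evaluated: ImageGrid) -> None:
    if not reference.same_geometry(evaluated):
        raise ShapeMismatchError(
            f"reference {reference.values.shape} and evaluated {evaluated.values.shape} "
            "must share geometry"
        )


def gamma_map(reference: ImageGrid, evaluated: ImageGrid, params: GammaParams | None = None) -> GammaResult:
    """Gamma index at every reference pixel (sub-pixel grid search).

    The evaluated image is bilinearly interpolated at offsets on a grid of
    step ``dta / search_subsample`` within the search radius; gamma at a
    pixel is the minimum combined dose/distance metric over those offsets.
    """
    from scipy import ndimage

    params = params or GammaParams()
    _check_pair(reference, evaluated)
    norm = _normalization_value(reference, params)
    crit_abs = params.dose_criterion_pct / 100.0 * norm
    dta = params.distance_criterion_mm
    pitch = reference.pitch_mm
    radius = params.search_radius_factor * dta

    ox, oy = _offset_grid(params, params.search_subsample)
    order = np.argsort(np.hypot(ox, oy))  # near offsets first: tightens the running min early
    ox, oy = ox[order], oy[order]

    pad = int(math.ceil(radius / pitch)) + 1
    padded = np.full(
        (evaluated.n_y + 2 * pad + 1, evaluated.n_x + 2 * pad + 1), np.nan
    )
    padded[pad : pad + evaluated.n_y, pad : pad + evaluated.n_x] = evaluated.values

    ref = reference.values
    gamma2 = np.full_like(ref, np.inf)
    best_dx = np.zeros_like(ref)
    best_dy = np.zeros_like(ref)
    for dx_mm, dy_mm in zip(ox, oy):
        dist2 = (dx_mm * dx_mm + dy_mm * dy_mm) / (dta * dta)
        # offsets are sorted by distance, so once no pixel's running gamma^2
        # exceeds the pure distance term, later offsets cannot improve it
        if not np.any(gamma2 > dist2):
            break
        # +dy in mm moves toward the gantry side, i.e. toward smaller row index
        shifted = _shifted_bilinear(padded, pad, -dy_mm / pitch, dx_mm / pitch, ref.shape)
        cand = ((shifted - ref) / crit_abs) ** 2 + dist2
        better = cand < gamma2
        best_dx = np.where(better, dx_mm, best_dx)
        best_dy = np.where(better, dy_mm, best_dy)
        gamma2 = np.where(better, cand, gamma2)

    # Local refinement: resample at 1/5 of the coarse step around each
    # pixel's best offset.  The refined offsets lie on the oracle's fine
    # lattice and inside the search radius, so gamma_map stays an upper
    # bound on the exhaustive fine-grid minimum.
    substep = dta / params.search_subsample / 5.0
    ii, jj = np.meshgrid(
        np.arange(ref.shape[0], dtype=float), np.arange(ref.shape[1], dtype=float), indexing="ij"
    )
    for kx in range(-4, 5):
        for ky in range(-4, 5):
            if kx == 0 and ky == 0:
                continue
            fx = best_dx + kx * substep
            fy = best_dy + ky * substep
            coords = np.stack([ii - fy / pitch, jj + fx / pitch])
            vals = ndimage.map_coordinates(
                evaluated.values, coords, order=1, mode="constant", cval=np.nan
            )
            dist2 = (fx**2 + fy**2) / dta**2
            cand = ((vals - ref) / crit_abs) ** 2 + dist2
            cand = np.where(np.isnan(cand) | (np.hypot(fx, fy) > radius * (1 + 1e-12)), np.inf, cand)
            gamma2 = np.fmin(gamma2, cand)
    return _finalize(np.sqrt(gamma2), reference, params, norm)


def gamma_oracle(reference: ImageGrid, evaluated: ImageGrid, params: GammaParams | None = None) -> GammaResult:
    """Brute-force gamma on a fine fixed grid (50 subdivisions per dta).

    Exhaustive reference implementation: every offset on the fine grid is
    evaluated through scipy's RegularGridInterpolator with no search
    shortcuts.  Intended for small images (<= 64x64 advisory); serves as
    ground truth for :func:`gamma_map`.
    """
    from scipy import ndimage

    params = params or GammaParams()
    _check_pair(reference, evaluated)
    norm = _normalization_value(reference, params)
    crit_abs = params.dose_criterion_pct / 100.0 * norm
    dta = params.distance_criterion_mm
    pitch = reference.pitch_mm

    ox, oy = _offset_grid(params, 50)
    h, w = reference.values.shape
    ii, jj = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")

    gamma2 = np.full((h, w), np.inf)
    chunk = max(1, 2_000_000 // (h * w))
    for start in range(0, ox.size, chunk):
        dx = ox[start : start + chunk]
        dy = oy[start : start + chunk]
        coords = np.stack(
            [
                ii[None, :, :] - (dy / pitch)[:, None, None],
                jj[None, :, :] + (dx / pitch)[:, None, None],
            ]
        )
        vals = ndimage.map_coordinates(
            evaluated.values, coords, order=1, mode="constant", cval=np.nan
        )
        dist2 = ((dx**2 + dy**2) / dta**2)[:, None, None]
        cand = ((vals - reference.values[None, :, :]) / crit_abs) ** 2 + dist2
        cand = np.nanmin(np.where(np.isnan(cand), np.inf, cand), axis=0)
        gamma2 = np.fmin(gamma2, cand)
    return _finalize(np.sqrt(gamma2), reference, params, norm)


def pass_rate_summary(results) -> dict:
    """Average / minimum / maximum / population SD / count of pass rates.

    Accepts :class:`GammaResult` objects or bare pass-rate percentages.
    """
    rates = [
        float(r.pass_rate_pct) if isinstance(r, GammaResult) else float(r) for r in results
    ]
    if not rates:
        raise ValueError("pass_rate_summary requires a non-empty list")
    arr = np.asarray(rates)
    return {
        "average": float(arr.mean()),
        "minimum": float(arr.min()),
        "maximum": float(arr.max()),
        "std_dev": float(arr.std(ddof=0)),
        "n_fields": int(arr.size),
    }
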