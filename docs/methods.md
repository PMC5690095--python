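# Methods

This note records the models, numerical choices and deliberate assumptions
behind `epidqa`, in the spirit of a model-description document: what is
computed, under which conventions, and what the synthetic data do and do
not establish.

## Panel geometry

The panel is a rectangular grid of square pixels (default 512×384 at
0.78125 mm — a 40×30 cm² aS1000-class imager) with the beam axis through
the geometric centre and the source-to-imager distance fixed at 100 cm
(images at the calibration plane; other SIDs are out of scope). Pixel
centres follow the half-pixel convention `x(i) = (i − (n−1)/2)·pitch`, so
on an even-dimensioned panel the beam axis falls *between* pixels; every
central-axis readout is therefore a bilinear interpolation at the axis
point, never a nearest-pixel lookup. +X points to patient left, +Y to the
gantry side (where the support arm sits). Off-axis radii `r` are in cm;
pitches in mm (the vendor's unit); conversions are internal.

Diagonal profiles are sampled by bilinear interpolation at uniform radii
along a ray from the centre. The ray angle is a parameter
(`angle_deg`, default 45°): the corner of a non-square field is *not* at
45° — for a 38×28 cm² field it lies along atan(14/19) ≈ 36.4°, and only
along that ray do the 22 cm fit window and the 23.6 cm half-diagonal
exist on the panel. Derivations in the experiment module therefore use
the field-corner diagonal. Averaging the two opposite rays
(`symmetrize`) is off by default: the correction is historically derived
from a single profile that embeds the arm asymmetry it then fits
radially; the flag lets users test both readings.

## Calibration chain

`(raw − dark)/(flood − dark)` is rescaled by `mean(flood − dark)` so the
flood correction preserves the overall signal scale (Greer-style
normalization; the rescaling constant is otherwise arbitrary and cancels
in the CU step). Beam-profile restoration multiplies each pixel by the
diagonal profile at its radius, with linear interpolation in `r`; beyond
the last profile sample the value is clamped with a warning (configurable
to raise), because panel corners can outrun a tabulated profile. A
supplied 2D multiplicative map (the generic stand-in for vendor
"pre-configuration" correction files, whose format is proprietary and not
parsed here) replaces the 1D restoration step when present; whether such
maps should apply before or after CU scaling is not standardized, and
this package fixes them at the restoration slot. The CU scale is the
reciprocal of the central-axis value of the fully processed 100 MU,
10×10 cm² reference, making that image read exactly 1 CU at the axis by
construction. Dose-rate dependence is not modelled — images are
rate-agnostic signal arrays.

## Profile correction

The ratio is `measured/predicted` after both diagonals are renormalized
to 1 at `r = 0`; the predicted curve is linearly resampled onto the
measured grid and the ratio restricted to the overlapping range. The
orientation (and whether the correction is applied by division or
multiplication) is switchable; the defaults make an over-responding
detector get its calibration profile *reduced*, which is the
self-consistent reading of an over-response whose correction factor is
quoted as positive. The fit target is `ratio − 1`, so the no-correction
case is the exact zero polynomial; the fit is unweighted OLS on the
sampled ratio (no weighting scheme is standard here), with the sampling
pitch defaulting to one sample per pixel pitch along the diagonal. R² is
computed on the fit window against `ratio − 1`; when the window has zero
variance, R² is defined as 1 for zero residuals and 0 otherwise.

Beyond the application radius the correction factor is exactly zero — a
hard cutoff, as the clinical recipe prescribes. The resulting step in the
corrected profile means pixels whose bilinear neighbourhood straddles the
cutoff mix corrected and uncorrected values: a one-pixel-wide transition
ring (~0.9% with the default over-response) that closed-loop checks
evaluate just inside of. An optional linear taper over a configurable
band (default off, 1 cm when enabled) smooths the step for users who
prefer continuity over fidelity to the recipe.

Mode constants: `inhouse_large` fits order 4 over 0–22 cm and applies to
22 cm; `inhouse_20x20` fits to 11 cm and applies to 14 cm (the 20×20
field's half-diagonal); `bailey` fits a line over 10–25 cm and applies
across the whole profile (stored as a 30 cm radius, beyond the 25 cm
panel half-diagonal). All constants are overridable per call.

## Gamma evaluation

Global gamma: dose differences are normalized by the reference maximum
(optionally its central axis), the criterion defaults to 3%/3 mm, all
pixels are evaluated unless a low-dose threshold is set, and ties at
γ = 1 pass. The reference is the *predicted* image by QA convention. The
search is two-stage: a grid of sub-pixel offsets at `Δd/search_subsample`
(default 0.3 mm) within `search_radius_factor·Δd` (default 9 mm), then a
local refinement at 1/5 of that step around each pixel's best offset.
Refined offsets stay on the fine lattice used by the exhaustive oracle
and inside the search radius, so `gamma_map` is always an upper bound on
the oracle's minimum. A single-pass coarse search systematically
overestimates γ wherever local dose gradients are steep (the dose term
quantizes in steps of ∇D·0.3 mm); the refinement removes this except when
the coarse pass lands in the wrong basin, which the one-sided bound still
covers. `gamma_oracle` evaluates every offset on a fixed 50-per-Δd grid
with no shortcuts and is intended for small images as ground truth.
Normalization, threshold, search resolution and reference/evaluated roles
are documented as this package's assumptions — the clinical systems whose
behaviour they emulate do not publish theirs, so absolute pass-rate
reproduction of any particular machine is not claimed.

## Synthetic data

`simulate_raw` composes, per pixel:

    raw = [F·P(r)·ρ(r)·S(x,y) + (scatter + B(x,y))·coverage + dark]·(1 + ε)

- `F`: jaw-collimated fluence with a 3 mm linear penumbra ramp; patterns
  `open`, `split_imrt` (two abutting half-fields, weights 1.0/0.93, ±5%
  junction-axis modulation) and `pyramid` (steps 0.4/0.7/1.0).
- `P(r) = 1 + 1.8·10⁻⁴ r² − 2.2·10⁻⁷ r⁴`: mild flattened-beam horns
  (~+3% at 15 cm).
- `ρ(r) = 1 − 1.0·10⁻⁴ r² + 6.3·10⁻⁷ r⁴`: the off-axis over-response,
  chosen analytically so ρ − 1 spans −0.40% (at r ≈ 8.9 cm) to +9.9%
  (at 22 cm) — the documented range of the correction it feeds. ρ is
  defined *relative to the flood condition* (it models the field-size
  dependence of the off-axis response), so calibration floods are
  generated without it; otherwise flood division would cancel it exactly
  and no off-axis discrepancy could exist.
- `S`: a smooth fixed sensitivity map (seeded coarse noise, cubic
  upsampling, ±0.3%).
- `B`: arm backscatter, zero on the target half, rising as
  `amplitude·√(y/extent)` on the gantry side and saturating at the extent
  (amplitude 0.03, extent 15 cm). The concave rise was chosen so the
  defaults realize the documented 2–3%-order gantry-side asymmetry at the
  edge of a 10×10 field (a linear ramp over 15 cm yields only ~0.9%).
  Backscatter and the uniform `scatter` floor (1%) scale with the
  fraction of the panel the field covers, so a panel-covering flood
  embeds more backscatter than a small field — which is exactly what
  makes flood-corrected small fields under-respond on the gantry side.
- `dark`: constant level (0.02) plus a small fixed random offset; the
  same array serves as the dark-calibration image.
- `ε`: multiplicative Gaussian noise (σ = 0.002, single frame), with a
  per-acquisition stream index so different images decorrelate while
  remaining bit-reproducible from the config seeds.

All of this is a parametric stand-in calibrated to documented effect
magnitudes; it does not model any vendor's hardware, energy spectra,
ghosting, MLC effects or delivery dynamics. Consequently, passing tests
establish that the *algorithms* behave as specified on data with the
right structure and magnitudes — not that any particular linac would
produce the same pass rates.

## Controlled experiments and problem sizes

Parameter-recovery and closed-loop checks run with backscatter, scatter,
sensitivity and noise disabled: the recovery bound (0.1 percentage
points) and the closed-loop bound (0.5%) are tighter than the ~0.4%
central-axis normalization error a single 0.2%-noise frame introduces,
and clinical derivations use frame-averaged acquisitions, which the
noise-free configuration stands in for. Single-frame noise behaviour is
exercised separately (fit quality, gamma trends).

Gamma-heavy scenario suites run on a 160×120 panel at 2.5 mm pitch — the
same 40×30 cm² physical area at coarser sampling — which keeps a full
four-scenario experiment under ten seconds; pixel-level physics checks
(CU round trip, asymmetry bands, profile extraction) use the full
512×384 panel. The experiment runner applies a 10% low-dose threshold on
the predicted image so pixels the prediction leaves dark (outside the
field, and outside a small flood's usable area) are not scored; this is
an assumption consistent with clinical configurations, not a published
setting.

## Fit-quality check

The headline fit-quality quantity is the R² of a 4th-order fit to a
synthetic ratio curve with 0.1% multiplicative noise at pixel-pitch
sampling over 0–22 cm. For a noisy fit, R² ≈ var(c)/(var(c)+σ²): the
curve must carry enough variance for R² ≥ 0.999 at σ = 10⁻³. The
generator's ground truth is the quartic through (0, 0), (5.5, −9%),
(11, −5%), (16.5, +4%), (22, +9.9%) — deviations within ±10%, variance
≈ 4·10⁻³, hence an expected R² ≈ 0.9997, comfortably in the regime the
derivation itself operates in.

## Known limitations

- The 1D correction is radial by construction and cannot remove the
  backscatter asymmetry; the synthetic small-field asymmetry survives all
  1D scenarios, as it should.
- The hard cutoff leaves the one-pixel transition ring described above.
- `gamma_map`'s refinement can miss a distant global basin that the
  coarse grid never sees; it remains an upper bound on the oracle.
- DICOM support is read-only and minimal (pixel spacing, rescale).
- Non-square pixels, panel sag, other SIDs, and transit dosimetry are out
  of scope.
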