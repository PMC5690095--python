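"""Plain-text I/O for portal images, profiles and corrections.

Images travel as CSV matrices with a one-line header carrying the geometry;
rows run from the gantry side of the panel downward and columns from
patient right to left, matching the in-memory array layout.  Profiles are
two-column CSV (r_cm, value).  An optional DICOM RT Image reader pulls the
pixel spacing from the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImageGrid, ProfileCurve

__all__ = [
    "read_image_csv",
    "write_image_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_dicom_rtimage",
]

_HEADER_PREFIX = "# epidqa-image"


def write_image_csv(path: str | Path, grid: ImageGrid) -> Path:
    path = Path(path)
    header = f"{_HEADER_PREFIX} n_x={grid.n_x} n_y={grid.n_y} pitch_mm={grid.pitch_mm!r}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, grid.values, delimiter=",", fmt="%.10g")
    return path


def read_image_csv(path: str | Path) -> ImageGrid:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER_PREFIX):
            raise ValueError(f"{path}: missing '{_HEADER_PREFIX}' header line")
        fields = dict(tok.split("=") for tok in header[len(_HEADER_PREFIX):].split())
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    n_x, n_y = int(fields["n_x"]), int(fields["n_y"])
    if values.shape != (n_y, n_x):
        raise ValueError(f"{path}: header says {n_y}x{n_x} but data is {values.shape}")
    return ImageGrid(values, pitch_mm=float(fields["pitch_mm"]))


def write_profile_csv(path: str | Path, profile: ProfileCurve) -> Path:
    path = Path(path)
    pd.DataFrame({"r_cm": profile.r_cm, "value": profile.value}).to_csv(path, index=False)
    return path


def read_profile_csv(path: str | Path) -> ProfileCurve:
    df = pd.read_csv(path)
    for col in ("r_cm", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: profile CSV requires columns 'r_cm' and 'value'")
    return ProfileCurve(df["r_cm"].to_numpy(float), df["value"].to_numpy(float))


def read_dicom_rtimage(path: str | Path) -> ImageGrid:
    """Read a DICOM RT Image into an :class:`ImageGrid`.

    The pixel spacing is taken from ImagePlanePixelSpacing (RT Image) or
    PixelSpacing; non-square spacing is rejected.  RescaleSlope/Intercept
    are applied when present.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path}: no ImagePlanePixelSpacing/PixelSpacing")
    sy, sx = float(spacing[0]), float(spacing[1])
    if abs(sy - sx) > 1e-6:
        raise ValueError(f"{path}: non-square pixels ({sy} x {sx} mm) are unsupported")
    values = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return ImageGrid(values * slope + intercept, pitch_mm=sx)
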