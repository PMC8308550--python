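"""Synthetic skin surfaces and photograph-like renders.

Real trial photographs of cellulitic thighs are rarely shareable, so this
module builds ground-truth surface height fields (sinusoidal ridges,
Gaussian dimples, flat skin) and renders them into 8-bit grayscale rasters
under the oblique bottom-mounted illumination used in clinical cellulite
photography: a beam travelling up the thigh at a known elevation from the
participant's vertical axis, with a small angular dispersion across the
frame.  Shading is Lambertian; surface normals come from finite differences
of the height map.

Coordinate conventions
----------------------
Height fields and images are stored ``[row, col]`` with row 0 at the TOP of
the raster.  Physical coordinates are millimetres measured from the
bottom-left corner, ``y`` increasing upward (matching tape-measure positions
"10 and 20 cm above the knee").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SurfaceField",
    "IlluminationModel",
    "SkinImage",
    "make_flat_field",
    "make_undulation_field",
    "make_dimple_field",
    "ridge_amplitude_for_contrast",
    "render_image",
    "draw_marks",
]


@dataclass(frozen=True)
class SurfaceField:
    """Ground-truth skin surface: elevations in mm on a square mm-grid.

    ``heights[0, 0]`` is the top-left sample; rows run downward in the
    raster but physical ``y`` runs upward.
    """

    heights: np.ndarray
    grid_spacing_mm: float
    descriptor: str = ""

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite everywhere")
        if not self.grid_spacing_mm > 0:
            raise ValueError("grid_spacing_mm must be > 0")
        object.__setattr__(self, "heights", h)

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) covered by the grid, in mm."""
        nrow, ncol = self.heights.shape
        return (ncol * self.grid_spacing_mm, nrow * self.grid_spacing_mm)


@dataclass(frozen=True)
class IlluminationModel:
    """Bottom-mounted divergent beam.

    elevation_deg
        Angle between the beam and the participant's vertical axis
        (platform-level source aimed up the thigh; default 70).
    dispersion_deg
        Beam divergence; implemented as a linear tilt of the light
        direction across the frame height spanning ±dispersion_deg/2.
    ambient_fraction
        Shading-independent fraction of the light in [0, 1).
    """

    elevation_deg: float = 70.0
    dispersion_deg: float = 15.0
    ambient_fraction: float = 0.2
    azimuth: str = "below"

    def __post_init__(self) -> None:
        if not 0.0 < self.elevation_deg < 90.0:
            raise ValueError("elevation_deg must be in (0, 90)")
        if not 0.0 <= self.ambient_fraction < 1.0:
            raise ValueError("ambient_fraction must be in [0, 1)")
        if self.dispersion_deg < 0:
            raise ValueError("dispersion_deg must be >= 0")
        if self.azimuth != "below":
            raise ValueError("only bottom-mounted illumination is modelled")


@dataclass(frozen=True)
class SkinImage:
    """8-bit single-channel raster with a mm<->pixel calibration."""

    pixels: np.ndarray
    px_per_mm: float = 10.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if p.dtype != np.uint8:
            if np.any(p < 0) or np.any(p > 255):
                raise ValueError("pixel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be > 0")
        object.__setattr__(self, "pixels", p)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.width_px / self.px_per_mm, self.height_px / self.px_per_mm)


def _grid_mm(extent_mm: tuple[float, float], spacing: float):
    """Pixel-center style sample coordinates; y increases upward."""
    width, height = extent_mm
    ncol = int(round(width / spacing))
    nrow = int(round(height / spacing))
    if ncol < 1 or nrow < 1:
        raise ValueError("extent too small for the requested grid spacing")
    x = (np.arange(ncol) + 0.5) * spacing
    y_up = (np.arange(nrow)[::-1] + 0.5) * spacing  # row 0 = top
    return np.meshgrid(x, y_up)


def make_flat_field(
    extent_mm: tuple[float, float] = (60.0, 70.0),
    grid_spacing_mm: float = 0.1,
) -> SurfaceField:
    """Perfectly smooth skin: the scorer's zero reference."""
    xx, _ = _grid_mm(extent_mm, grid_spacing_mm)
    return SurfaceField(np.zeros_like(xx), grid_spacing_mm, "flat")


def make_undulation_field(
    amplitude_mm: float,
    wavelength_mm: float,
    orientation_deg: float = 0.0,
    phase_rad: float = 0.0,
    extent_mm: tuple[float, float] = (60.0, 70.0),
    grid_spacing_mm: float = 0.1,
) -> SurfaceField:
    """Sinusoidal ridge field.

    ``h(x, y) = A sin(2π (x sinθ + y cosθ)/λ + φ)`` with y measured upward;
    θ = 0 gives horizontal ridges (height varies along y), θ = 90 vertical
    ridges, which oblique bottom lighting cannot reveal.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    if wavelength_mm <= 0:
        raise ValueError("wavelength_mm must be > 0")
    xx, yy = _grid_mm(extent_mm, grid_spacing_mm)
    theta = math.radians(orientation_deg)
    u = xx * math.sin(theta) + yy * math.cos(theta)
    heights = amplitude_mm * np.sin(2.0 * np.pi * u / wavelength_mm + phase_rad)
    desc = (
        f"sinusoid A={amplitude_mm}mm λ={wavelength_mm}mm "
        f"θ={orientation_deg}° φ={phase_rad}"
    )
    return SurfaceField(heights, grid_spacing_mm, desc)


def ridge_amplitude_for_contrast(
    contrast_levels: float,
    wavelength_mm: float,
    illum: IlluminationModel = IlluminationModel(),
    base_level: float = 180.0,
) -> float:
    """Amplitude of a horizontal ridge field whose noise-free render spans
    roughly ``contrast_levels`` grey levels peak-to-trough.

    Small-slope shading of ``h = A sin(2πy/λ)`` gives intensity
    ``base·[1 + (1−a)·h′·cot e]``, so the peak-to-trough span is
    ``2A·(2π/λ)·base·(1−a)·cot e``; the brightest rows sit at the lowest
    beam elevation ``e = elevation − dispersion/2``.
    """
    if contrast_levels <= 0 or wavelength_mm <= 0:
        raise ValueError("contrast_levels and wavelength_mm must be > 0")
    e_min = math.radians(illum.elevation_deg - illum.dispersion_deg / 2.0)
    slope_gain = (
        2.0
        * (2.0 * math.pi / wavelength_mm)
        * base_level
        * (1.0 - illum.ambient_fraction)
        / math.tan(e_min)
    )
    return contrast_levels / slope_gain


def make_dimple_field(
    n_dimples: int,
    depth_mm_range: tuple[float, float] = (0.3, 0.8),
    radius_mm_range: tuple[float, float] = (3.0, 8.0),
    extent_mm: tuple[float, float] = (60.0, 70.0),
    grid_spacing_mm: float = 0.1,
    seed: int = 0,
) -> SurfaceField:
    """Irregular 'orange-peel' surrogate: superposed Gaussian depressions.

    Dimple centres are uniform over the extent; each dimple subtracts
    ``depth · exp(-r²/(2σ²))`` with σ = radius/2.  Deterministic for a
    fixed seed.
    """
    if n_dimples < 0:
        raise ValueError("n_dimples must be >= 0")
    for lo, hi, name in (
        (*depth_mm_range, "depth_mm_range"),
        (*radius_mm_range, "radius_mm_range"),
    ):
        if not (0 < lo <= hi):
            raise ValueError(f"{name} must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    xx, yy = _grid_mm(extent_mm, grid_spacing_mm)
    heights = np.zeros_like(xx)
    for _ in range(n_dimples):
        cx = rng.uniform(0.0, extent_mm[0])
        cy = rng.uniform(0.0, extent_mm[1])
        depth = rng.uniform(*depth_mm_range)
        radius = rng.uniform(*radius_mm_range)
        sigma = radius / 2.0
        heights -= depth * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return SurfaceField(
        heights, grid_spacing_mm, f"dimples n={n_dimples} seed={seed}"
    )


def _quantize_u8(values: np.ndarray) -> np.ndarray:
    """Round half away from zero, clip to [0, 255]; bit-reproducible."""
    rounded = np.sign(values) * np.floor(np.abs(values) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def _surface_normals(heights: np.ndarray, spacing: float):
    """Unit normals from central finite differences (one-sided at borders).

    Returns (nx, ny, nz) with y pointing up; rows run downward so the row
    gradient is negated.
    """
    d_row, d_col = np.gradient(heights, spacing)
    hx = d_col
    hy = -d_row  # physical y is up, row index runs down
    norm = np.sqrt(1.0 + hx**2 + hy**2)
    return -hx / norm, -hy / norm, 1.0 / norm


def render_image(
    fld: SurfaceField,
    illum: IlluminationModel = IlluminationModel(),
    px_per_mm: float = 10.0,
    base_level: float = 180.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape_px: tuple[int, int] | None = None,
) -> SkinImage:
    """Render a surface into an 8-bit photograph-like raster.

    Lambertian shading normalised so a flat surface renders at exactly
    ``base_level`` before noise::

        I = base_level · [a + (1-a) · max(0, n·l)/c] + N(0, noise_sd²)

    where ``a`` is the ambient fraction, ``n`` the surface normal, ``l`` the
    local unit light direction (elevation tilted linearly across the frame
    within ±dispersion/2) and ``c`` the flat-surface ``n·l``.  The result is
    rounded half away from zero and clipped to [0, 255].
    """
    if not 0 < base_level < 255:
        raise ValueError("base_level must lie in (0, 255)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    ext_w, ext_h = fld.extent_mm
    if shape_px is None:
        shape_px = (int(round(ext_h * px_per_mm)), int(round(ext_w * px_per_mm)))
    nrow, ncol = shape_px
    if ncol / px_per_mm > ext_w + 1e-9 or nrow / px_per_mm > ext_h + 1e-9:
        raise ValueError(
            f"field of extent {fld.extent_mm} mm is too small for a "
            f"{shape_px} raster at {px_per_mm} px/mm"
        )

    # Resample heights onto pixel centres if grids differ.
    if abs(fld.grid_spacing_mm * px_per_mm - 1.0) < 1e-12 and fld.heights.shape == (
        nrow,
        ncol,
    ):
        heights = fld.heights
    else:
        # pixel centre (r, c) lies at mm position, mapped into grid index
        rows_mm_from_top = (np.arange(nrow) + 0.5) / px_per_mm
        cols_mm = (np.arange(ncol) + 0.5) / px_per_mm
        ri = rows_mm_from_top / fld.grid_spacing_mm - 0.5
        ci = cols_mm / fld.grid_spacing_mm - 0.5
        rr, cc = np.meshgrid(ri, ci, indexing="ij")
        heights = ndimage.map_coordinates(
            fld.heights, [rr, cc], order=1, mode="nearest"
        )

    nx, ny, nz = _surface_normals(heights, 1.0 / px_per_mm)

    # Per-row light direction: elevation from the vertical axis, tilted
    # linearly with height across the frame (divergent beam from below).
    frac_up = (np.arange(nrow)[::-1] + 0.5) / nrow  # 0 at bottom, 1 at top
    elev = np.radians(
        illum.elevation_deg + illum.dispersion_deg * (frac_up - 0.5)
    )[:, None]
    ly = -np.cos(elev)  # toward the platform-level source below
    lz = np.sin(elev)

    cos_inc = np.maximum(0.0, ny * ly + nz * lz)
    flat = lz  # flat surface: n = (0, 0, 1)
    a = illum.ambient_fraction
    intensity = base_level * (a + (1.0 - a) * cos_inc / flat)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)

    return SkinImage(_quantize_u8(intensity), px_per_mm)


def draw_marks(
    image: SkinImage,
    line_rows_mm,
    darkness: float = 0.8,
    thickness_mm: float = 2.0,
) -> SkinImage:
    """Superimpose horizontal circumference lines drawn on the skin.

    Each line darkens the band [row_mm, row_mm + thickness_mm), measured
    upward from the image bottom: ``pixel <- pixel · (1 - darkness)``.
    Returns a new image; the input is unmodified.
    """
    if not 0.0 <= darkness <= 1.0:
        raise ValueError("darkness must lie in [0, 1]")
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be > 0")
    px = image.px_per_mm
    H = image.height_px
    out = image.pixels.astype(float).copy()
    for row_mm in np.atleast_1d(line_rows_mm):
        start = H - int(round((row_mm + thickness_mm) * px))
        stop = H - int(round(row_mm * px))
        if start < 0 or stop > H or start >= stop:
            raise IndexError(
                f"mark at {row_mm} mm (thickness {thickness_mm} mm) lies "
                f"outside the {H / px:.1f} mm tall raster"
            )
        out[start:stop, :] *= 1.0 - darkness
    return SkinImage(_quantize_u8(out), px)
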