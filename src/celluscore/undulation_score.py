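"""Line-scan bandpass cellulite score.

The score quantifies skin undulations from an obliquely illuminated
grayscale photograph.  For each 4 × 60 mm region of interest (ROI) the
pixel rows are averaged across the ROI width into a single vertical
intensity profile; a small (1 mm) moving average removes sub-millimetre
texture and sensor noise, a further large (20 mm) moving average of that
result forms an illumination baseline, and the summed absolute deviations
between the two isolate cellulite-scale (≈2–20 mm) undulations.  Twelve
horizontally adjacent ROIs are scored and summed into one unitless value:
smooth featureless skin scores exactly 0; visibly cellulitic skin scores
hundreds to thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic_skin import SkinImage

__all__ = [
    "RoiSpec",
    "Profile",
    "SmoothedPair",
    "ScoreParams",
    "UndulationScore",
    "extract_profile",
    "moving_average",
    "valid_interval",
    "window_px",
    "bandpass_deviation",
    "score_image",
    "oblate_marks",
]


@dataclass(frozen=True)
class RoiSpec:
    """A scoring region: lower-left corner and extent, in image mm-coordinates
    (x from the left edge, y upward from the bottom edge)."""

    x0_mm: float
    y0_mm: float
    width_mm: float = 4.0
    height_mm: float = 60.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI width and height must be > 0")


@dataclass(frozen=True)
class Profile:
    """Column-averaged vertical line-scan intensities, top to bottom."""

    values: np.ndarray
    px_per_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SmoothedPair:
    """The two smoothing stages of one profile.

    px1: small-window smoothed profile (sub-mm features removed).
    px2: px1 further smoothed by the large window (illumination baseline).
    valid_range: (start, stop) index interval on which both windows fit
    entirely, so edge-shrunken means never enter the score.
    """

    px1: np.ndarray
    px2: np.ndarray
    valid_range: tuple[int, int]


@dataclass(frozen=True)
class ScoreParams:
    """Scorer tuning.

    Windows are physical lengths converted through the image calibration;
    the conversion rounds to the nearest integer, bumping even results up
    to the next odd so the centred window is symmetric (10 px -> 11 px).
    ``deviation`` selects how px1 - px2 is accumulated.  ``quantize_profile``
    re-truncates column means to whole grey levels (strict 8-bit storage
    reading) for sensitivity checks; off by default because averaging ~40
    columns carries sub-grey-level signal.
    """

    small_window_mm: float = 1.0
    large_window_mm: float = 20.0
    n_rois: int = 12
    roi_width_mm: float = 4.0
    roi_height_mm: float = 60.0
    deviation: str = "absolute"
    quantize_profile: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.small_window_mm < self.large_window_mm:
            raise ValueError("need 0 < small_window_mm < large_window_mm")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.deviation not in ("absolute", "signed", "squared"):
            raise ValueError("deviation must be absolute, signed or squared")


@dataclass(frozen=True)
class UndulationScore:
    """Per-ROI deviation sums and their total (the overall cellulite value)."""

    roi_scores: tuple
    total: float
    region_origin_mm: tuple[float, float]
    params: ScoreParams

    def __post_init__(self) -> None:
        if len(self.roi_scores) != self.params.n_rois:
            raise ValueError("roi_scores count must equal params.n_rois")


def window_px(window_mm: float, px_per_mm: float) -> int:
    """Convert a physical window to an odd pixel count >= 1."""
    w = int(round(window_mm * px_per_mm))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def _roi_slices(image: SkinImage, roi: RoiSpec):
    px = image.px_per_mm
    H, W = image.pixels.shape
    c0 = int(round(roi.x0_mm * px))
    c1 = int(round((roi.x0_mm + roi.width_mm) * px))
    r0 = H - int(round((roi.y0_mm + roi.height_mm) * px))
    r1 = H - int(round(roi.y0_mm * px))
    if c0 < 0 or c1 > W or r0 < 0 or r1 > H or c0 >= c1 or r0 >= r1:
        raise IndexError(
            f"ROI {roi} falls outside the {W/px:.1f} x {H/px:.1f} mm raster"
        )
    return slice(r0, r1), slice(c0, c1)


def extract_profile(image: SkinImage, roi: RoiSpec) -> Profile:
    """Average the ROI's pixel rows across its width into one profile.

    Column means are kept at real precision; see ScoreParams.quantize_profile
    for the strict 8-bit variant.
    """
    rows, cols = _roi_slices(image, roi)
    values = image.pixels[rows, cols].astype(float).mean(axis=1)
    return Profile(values, image.px_per_mm)


def moving_average(values, window_px: int) -> np.ndarray:
    """Centred 'simple' moving mean, window shrinking symmetrically at edges.

    Output length equals input length.  The fully-valid interval (no edge
    shrinkage) is given by :func:`valid_interval`.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    n = v.size
    if n < window_px:
        raise ValueError(f"array of length {n} is shorter than window {window_px}")
    k = window_px // 2
    cs = np.concatenate(([0.0], np.cumsum(v)))
    i = np.arange(n)
    kk = np.minimum(k, np.minimum(i, n - 1 - i))
    return (cs[i + kk + 1] - cs[i - kk]) / (2 * kk + 1)


def valid_interval(length: int, window_px: int) -> tuple[int, int]:
    """Half-open (start, stop) over which a centred window fits entirely."""
    k = window_px // 2
    start, stop = k, length - k
    if start >= stop:
        raise ValueError("window leaves no fully-valid interval")
    return start, stop


def bandpass_deviation(profile: Profile, params: ScoreParams = ScoreParams()):
    """Two-scale smoothing, subtraction and summed deviations for one ROI.

    Returns ``(roi_score, SmoothedPair)``.  The deviations px1 - px2 are
    accumulated only where the large window fits entirely, which makes
    constant and linearly ramping profiles (pure illumination gradients)
    score exactly 0.
    """
    values = profile.values
    if params.quantize_profile:
        values = np.floor(values + 0.5)
    w_small = window_px(params.small_window_mm, profile.px_per_mm)
    w_large = window_px(params.large_window_mm, profile.px_per_mm)
    px1 = moving_average(values, w_small)
    px2 = moving_average(px1, w_large)
    lo, hi = valid_interval(values.size, w_large)
    band = px1[lo:hi] - px2[lo:hi]
    if params.deviation == "absolute":
        score = float(np.abs(band).sum())
    elif params.deviation == "squared":
        score = float((band**2).sum())
    else:
        score = float(band.sum())
    return score, SmoothedPair(px1, px2, (lo, hi))


def score_image(
    image: SkinImage,
    region_origin_mm: tuple[float, float] = (0.0, 0.0),
    params: ScoreParams = ScoreParams(),
) -> UndulationScore:
    """Score a strip of adjacent ROIs and sum into the overall value.

    ROI k has its lower-left corner at ``origin + (k · roi_width_mm, 0)``:
    adjacent, non-overlapping.  The image must accommodate the full strip.
    """
    x0, y0 = region_origin_mm
    strip_mm = params.n_rois * params.roi_width_mm
    W_mm, H_mm = image.extent_mm
    if x0 < 0 or y0 < 0 or x0 + strip_mm > W_mm + 1e-9 or (
        y0 + params.roi_height_mm > H_mm + 1e-9
    ):
        raise IndexError(
            f"strip of {params.n_rois} ROIs needs at least "
            f"{x0 + strip_mm:.1f} x {y0 + params.roi_height_mm:.1f} mm; "
            f"image is {W_mm:.1f} x {H_mm:.1f} mm"
        )
    scores = []
    for k in range(params.n_rois):
        roi = RoiSpec(
            x0 + k * params.roi_width_mm,
            y0,
            params.roi_width_mm,
            params.roi_height_mm,
        )
        s, _ = bandpass_deviation(extract_profile(image, roi), params)
        scores.append(s)
    return UndulationScore(tuple(scores), sum(scores), (x0, y0), params)


def oblate_marks(image: SkinImage, mark_rows_mm, thickness_mm: float = 2.0) -> SkinImage:
    """Erase drawn circumference lines by per-column linear interpolation.

    Marked rows (bands [row_mm, row_mm + thickness_mm) upward from the image
    bottom, matching :func:`~celluscore.synthetic_skin.draw_marks`) are
    replaced by interpolating between the nearest unmarked rows above and
    below.  Marks touching the raster border cannot be interpolated.
    """
    rows_mm = np.atleast_1d(mark_rows_mm)
    if rows_mm.size == 0:
        return image
    px = image.px_per_mm
    H = image.height_px
    marked = np.zeros(H, dtype=bool)
    for row_mm in rows_mm:
        start = H - int(round((row_mm + thickness_mm) * px))
        stop = H - int(round(row_mm * px))
        if start < 0 or stop > H:
            raise IndexError(f"mark at {row_mm} mm lies outside the raster")
        marked[start:stop] = True
    if marked[0] or marked[-1]:
        raise ValueError("cannot interpolate a mark covering an image border")
    if not marked.any():
        return image
    rows = np.arange(H)
    out = image.pixels.astype(float)
    good = ~marked
    for c in range(image.width_px):
        out[marked, c] = np.interp(rows[marked], rows[good], out[good, c])
    rounded = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return SkinImage(rounded, px)
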