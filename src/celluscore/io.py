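"""Image and table IO.

Images are 8-bit single-channel PNG or TIFF; the mm↔pixel calibration
travels in a JSON sidecar named ``<image>.meta.json`` (keys: px_per_mm,
descriptor, seed) because neither format carries it reliably.  16-bit input
is rescaled to 8-bit and multi-channel input is converted by Rec. 601
luminance, both with a logged warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic_skin import SkinImage

__all__ = ["read_image", "write_image", "sidecar_path"]

log = logging.getLogger(__name__)

_LUMA = (0.299, 0.587, 0.114)  # Rec. 601


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def write_image(
    image: SkinImage, path, descriptor: str = "", seed: int | None = None
) -> Path:
    """Write an 8-bit grayscale PNG/TIFF plus its calibration sidecar."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="L").save(path)
    meta = {"px_per_mm": image.px_per_mm, "descriptor": descriptor, "seed": seed}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path, px_per_mm: float | None = None) -> SkinImage:
    """Read a skin photograph with its calibration.

    Calibration comes from ``px_per_mm`` or, failing that, the sidecar
    ``<image>.meta.json``; with neither, an error names the convention.
    """
    path = Path(path)
    if px_per_mm is None:
        sc = sidecar_path(path)
        if not sc.exists():
            raise FileNotFoundError(
                f"no calibration for {path.name}: pass px_per_mm or provide a "
                f"sidecar {sc.name} with a px_per_mm key"
            )
        px_per_mm = float(json.loads(sc.read_text())["px_per_mm"])

    with Image.open(path) as im:
        arr = np.asarray(im)

    eight_bit = arr.dtype == np.uint8
    if arr.ndim == 3:
        log.warning("%s is multi-channel; converting by Rec. 601 luminance", path.name)
        arr = arr[..., :3].astype(float) @ np.asarray(_LUMA)
        arr = np.floor(arr + 0.5)
    if not eight_bit:
        arr = arr.astype(float)
        peak = arr.max()
        if peak > 0:
            log.warning(
                "%s is not 8-bit; rescaling so its maximum maps to 255", path.name
            )
            arr = arr * 255.0 / peak
        arr = np.floor(arr + 0.5)
    return SkinImage(np.clip(arr, 0, 255).astype(np.uint8), px_per_mm)
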