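"""Reading micrographs and writing intermediate / overlay images."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image

from .errors import FormatError
from .profile import CurveProfile

__all__ = ["read_image", "save_stages", "render_overlay"]

_CURVE_COLORS = {"base": (255, 255, 0), "intersection": (255, 0, 0)}


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF micrograph as an H x W x 3 uint8 array."""
    img = iio.imread(Path(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB or grayscale raster")
    if img.dtype == np.uint16:
        img = (img // 257).astype(np.uint8)
    return img.astype(np.uint8)


def save_stages(stages: dict, out_dir: str | Path) -> list[Path]:
    """Export every preprocessing stage.

    Lightness images go out as 16-bit grayscale PNG (L* 0-100 scaled to the
    full range); boolean masks and skeletons as 1-bit PNG.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (name, arr) in enumerate(stages.items()):
        path = out_dir / f"{i:02d}_{name}.png"
        if arr.dtype == bool:
            Image.fromarray(arr).convert("1").save(path)
        else:
            scaled = np.clip(arr / 100.0 * 65535.0, 0, 65535).astype(np.uint16)
            iio.imwrite(path, scaled)
        written.append(path)
    return written


def render_overlay(
    img: np.ndarray,
    curves: dict[str, CurveProfile],
    path: str | Path | None = None,
    thickness: int = 1,
) -> np.ndarray:
    """Paint curves over a micrograph (base curves yellow, intersection red)."""
    out = np.asarray(img).copy()
    H, W = out.shape[:2]
    cols = np.arange(W)
    for kind, profile in curves.items():
        color = _CURVE_COLORS.get(kind, (0, 255, 0))
        rows = np.clip(np.rint(profile.interpolated()), 0, H - 1).astype(int)
        for d in range(-(thickness // 2), thickness // 2 + 1):
            rr = np.clip(rows + d, 0, H - 1)
            out[rr, cols] = color
    if path is not None:
        iio.imwrite(Path(path), out)
    return out
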