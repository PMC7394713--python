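"""Loading human-drawn annotation curves.

The semi-automated counting methods need a curve supplied by a human: a base
curve traced along the leaf surface, or an intersection curve drawn through
the trichome stalks.  Two media are supported:

* polyline files — CSV with an ``x,y`` header or a JSON list of ``[x, y]``
  pairs, in 0-based pixel coordinates (x = column, y = row);
* color overlays — a copy of the micrograph with the curve painted in pure
  yellow (base curve) or pure red (intersection curve), the way annotators
  mark up the image directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .profile import CurveProfile

__all__ = ["AnnotationCurve", "load_polyline", "extract_overlay_curve", "to_profile"]

_OVERLAY_COLORS = {"yellow": (255, 255, 0), "red": (255, 0, 0)}


@dataclass(frozen=True)
class AnnotationCurve:
    """An ordered polyline in pixel coordinates.

    ``points`` is an (N, 2) float array of (column, row) pairs with columns
    weakly increasing; ``kind`` says whether this is a leaf-surface base
    curve or a trichome intersection curve.
    """

    points: np.ndarray
    kind: Literal["base", "intersection"]
    source: Literal["polyline_file", "overlay_image"]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise AnnotationError("a curve needs at least 2 (x, y) points")
        if not np.isfinite(pts).all():
            raise AnnotationError("curve points must be finite numbers")
        if (pts < 0).any():
            raise AnnotationError("curve coordinates must be non-negative")
        if np.any(np.diff(pts[:, 0]) < 0):
            raise AnnotationError("curve columns must be weakly increasing")
        object.__setattr__(self, "points", pts)


def _canonicalize(pts: np.ndarray) -> np.ndarray:
    """Sort by column and average rows of duplicate columns."""
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    xs, inverse = np.unique(pts[:, 0], return_inverse=True)
    ys = np.zeros_like(xs)
    counts = np.bincount(inverse)
    np.add.at(ys, inverse, pts[:, 1])
    return np.column_stack([xs, ys / counts])


def load_polyline(path: str | Path, kind: Literal["base", "intersection"]) -> AnnotationCurve:
    """Read an annotation polyline from a CSV (``x,y`` header) or JSON file."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
            pts = np.asarray(raw, dtype=float)
        else:
            df = pd.read_csv(path)
            if not {"x", "y"}.issubset(df.columns):
                raise AnnotationError(f"{path}: CSV needs 'x' and 'y' columns")
            pts = df[["x", "y"]].to_numpy(dtype=float)
    except (ValueError, TypeError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"{path}: could not parse numeric points ({exc})") from exc
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise AnnotationError(f"{path}: expected a list of [x, y] pairs")
    if pts.shape[0] < 2:
        raise AnnotationError(f"{path}: a curve needs at least 2 points")
    return AnnotationCurve(_canonicalize(pts), kind=kind, source="polyline_file")


def extract_overlay_curve(
    img: np.ndarray,
    color: Literal["yellow", "red"],
    tolerance: int = 60,
) -> AnnotationCurve:
    """Recover an annotation curve painted on an overlay image.

    Pixels within ``tolerance`` per channel of pure yellow (255, 255, 0) or
    pure red (255, 0, 0) are selected; the curve row at each column is the
    mean row of the selected pixels there.  At least half of the image
    columns must contain curve pixels, otherwise the overlay is rejected as
    not containing a usable curve.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise AnnotationError("overlay must be an RGB image")
    if color not in _OVERLAY_COLORS:
        raise AnnotationError(f"unknown overlay color {color!r}")
    target = np.array(_OVERLAY_COLORS[color], dtype=int)
    close = (np.abs(img.astype(int) - target) <= tolerance).all(axis=2)
    if not close.any():
        raise AnnotationError(f"no {color} pixels found in overlay")
    H, W = close.shape
    counts = close.sum(axis=0)
    covered = counts > 0
    if covered.sum() < 0.5 * W:
        raise AnnotationError(
            f"{color} curve covers only {covered.sum()}/{W} columns (need >= 50%)"
        )
    rows = np.arange(H, dtype=float)
    mean_rows = (close * rows[:, None]).sum(axis=0)[covered] / counts[covered]
    cols = np.flatnonzero(covered).astype(float)
    kind = "base" if color == "yellow" else "intersection"
    return AnnotationCurve(
        np.column_stack([cols, mean_rows]), kind=kind, source="overlay_image"
    )


def to_profile(curve: AnnotationCurve, width: int, height: int) -> CurveProfile:
    """Resample a curve onto every integer column of a W x H image.

    Rows are linearly interpolated between curve points, held at the nearest
    endpoint value beyond the curve's span, and clipped to the image.
    """
    cols = np.arange(width, dtype=float)
    rows = np.interp(cols, curve.points[:, 0], curve.points[:, 1])
    return CurveProfile(np.clip(rows, 0.0, float(height - 1)))
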