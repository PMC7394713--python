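"""Trichome counting methods on a skeleton image.

Four estimators of the number of trichomes, operating on a 1-px skeleton of a
side-view micrograph:

``endpoints``
    Every unoccluded trichome contributes one free skeleton endpoint (the
    other endpoint sits on the leaf surface), so the count of free endpoints
    estimates the count of trichomes.  Sensitive to residual noise, which
    inflates the estimate, and to occlusion, which hides endpoints.
``auto_contour``
    Detect the leaf-surface base curve (lowest foreground pixel per column),
    translate it upward by multiples of an offset, and report the mean number
    of skeleton crossings over the translated curves.
``annotated_contour``
    Same as ``auto_contour`` but with a human-supplied base curve, for
    micrographs where automatic base detection fails (uneven leaf surfaces).
``annotated_intersection``
    Count crossings of a single human-drawn curve placed through the
    trichome stalks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .errors import EmptyMaskError, TrichocountError
from .profile import CurveProfile

__all__ = [
    "ContourConfig",
    "CountResult",
    "count_endpoints",
    "detect_base_curve",
    "compute_offset",
    "translate_curve",
    "count_curve_intersections",
    "count_auto_contour",
    "count_annotated_contour",
    "count_annotated_intersection",
]

_N8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_BOX3 = np.ones((3, 3), bool)


@dataclass
class ContourConfig:
    """Parameters shared by the counting methods.

    n_curves
        Number of translated contour curves (contour methods average over
        them).
    border_margin
        Trichomes emerging from the left or right image border are not
        counted; endpoints and crossing runs falling entirely within this
        many columns of either border are discarded.
    base_exclusion
        Endpoints within this vertical distance (px) of the base curve are
        root endpoints, not free ones.
    gap_tolerance
        Crossing runs separated by at most this many columns are merged into
        one crossing (a single slanted skeleton line may touch the curve in
        nearby, non-adjacent columns due to rasterization).
    offset_mode
        ``interior`` spaces curves strictly between the base and the trichome
        tips (offset = h / (n_curves + 1)); ``inclusive`` uses h / n_curves,
        putting the last curve at tip height.
    """

    n_curves: int = 4
    border_margin: int = 5
    base_exclusion: int = 3
    gap_tolerance: int = 2
    offset_mode: Literal["interior", "inclusive"] = "interior"

    def __post_init__(self):
        if self.n_curves < 1:
            raise TrichocountError("n_curves must be >= 1")
        if min(self.border_margin, self.base_exclusion, self.gap_tolerance) < 0:
            raise TrichocountError("margins must be >= 0")
        if self.offset_mode not in ("interior", "inclusive"):
            raise TrichocountError(f"unknown offset_mode {self.offset_mode!r}")


@dataclass
class CountResult:
    """Outcome of one counting method.

    ``count`` is the trichome estimate (a real number: contour methods report
    the unrounded mean of the integer per-curve crossing counts).
    ``diagnostics`` carries method-specific detail: free-endpoint coordinates
    for the endpoint method, per-curve crossing column intervals for the
    contour methods.
    """

    method: Literal["endpoints", "auto_contour", "annotated_contour", "annotated_intersection"]
    count: float
    per_curve_counts: list[int] = field(default_factory=list)
    n_curves: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.count < 0:
            raise TrichocountError("count must be >= 0")
        if self.per_curve_counts:
            mean = float(np.mean(self.per_curve_counts))
            if abs(mean - self.count) > 1e-9:
                raise TrichocountError("count must equal the mean of per_curve_counts")


def _as_skeleton(skel: np.ndarray) -> np.ndarray:
    skel = np.asarray(skel, dtype=bool)
    if skel.ndim != 2:
        raise TrichocountError(f"skeleton must be 2-D, got shape {skel.shape}")
    return skel


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), _N8, mode="constant", cval=0)


def count_endpoints(
    skel: np.ndarray, base: CurveProfile, cfg: ContourConfig | None = None
) -> CountResult:
    """Count free skeleton endpoints.

    An endpoint is a foreground pixel with exactly one 8-neighbor.  Free
    endpoints exclude root endpoints (within ``base_exclusion`` px vertically
    of the base curve) and endpoints within ``border_margin`` columns of the
    left/right image edge.
    """
    cfg = cfg or ContourConfig()
    skel = _as_skeleton(skel)
    H, W = skel.shape
    if not skel.any():
        warnings.warn("empty skeleton: endpoint count is 0")
        return CountResult(method="endpoints", count=0.0, diagnostics={"endpoints": []})
    ends = skel & (_neighbor_counts(skel) == 1)
    base_rows = base.interpolated()
    if base_rows.size != W:
        raise TrichocountError("base profile width does not match skeleton width")
    rr, cc = np.nonzero(ends)
    free = (
        (np.abs(rr - base_rows[cc]) > cfg.base_exclusion)
        & (cc >= cfg.border_margin)
        & (cc < W - cfg.border_margin)
    )
    coords = list(zip(rr[free].tolist(), cc[free].tolist()))
    return CountResult(
        method="endpoints", count=float(free.sum()), diagnostics={"endpoints": coords}
    )


def detect_base_curve(skel: np.ndarray) -> CurveProfile:
    """Leaf-surface base curve: the lowest foreground pixel in each column.

    Columns without foreground are undefined; :meth:`CurveProfile.interpolated`
    fills them by linear interpolation (nearest value beyond the span).
    """
    skel = _as_skeleton(skel)
    if not skel.any():
        raise EmptyMaskError("cannot detect a base curve on an empty skeleton")
    H, W = skel.shape
    # lowest == maximum row index per column
    rows_desc = np.where(skel, np.arange(H)[:, None], -1)
    lowest = rows_desc.max(axis=0).astype(float)
    lowest[lowest < 0] = np.nan
    return CurveProfile(lowest)


def compute_offset(skel: np.ndarray, cfg: ContourConfig | None = None) -> float:
    """Vertical spacing between contour curves.

    The vertical extent h of the foreground (bottom-most minus topmost
    occupied row) is the height of the average trichome band; curves divide
    it into equal intervals: h/(n_curves+1) in ``interior`` mode,
    h/n_curves in ``inclusive`` mode.
    """
    cfg = cfg or ContourConfig()
    skel = _as_skeleton(skel)
    if not skel.any():
        raise EmptyMaskError("cannot compute an offset on an empty skeleton")
    occupied = np.flatnonzero(skel.any(axis=1))
    h = int(occupied[-1] - occupied[0])
    if h == 0:
        raise TrichocountError("foreground spans a single row; offset undefined")
    if cfg.offset_mode == "interior":
        return h / (cfg.n_curves + 1)
    return h / cfg.n_curves


def translate_curve(base: CurveProfile, offset: float) -> CurveProfile:
    """Move a curve vertically upward by ``round(offset)`` px (clipped at row 0)."""
    return base.translated(offset)


def _rasterize_profile(profile: CurveProfile, shape: tuple[int, int]) -> np.ndarray:
    """8-connected 1-px raster path of a profile across all columns."""
    H, W = shape
    rows = np.clip(np.rint(profile.interpolated()), 0, H - 1).astype(int)
    if rows.size != W:
        raise TrichocountError("profile width does not match image width")
    path = np.zeros(shape, dtype=bool)
    path[rows, np.arange(W)] = True
    jumps = np.flatnonzero(np.abs(np.diff(rows)) > 1)
    for c in jumps:
        rr, cc = draw_line(rows[c], c, rows[c + 1], c + 1)
        path[rr, cc] = True
    return path


def _runs_of(touched: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop] (inclusive) of True entries."""
    idx = np.flatnonzero(touched)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def count_curve_intersections(
    skel: np.ndarray, curve: CurveProfile, cfg: ContourConfig | None = None
) -> int:
    """Number of skeleton crossings of a curve.

    The curve is rasterized as an 8-connected 1-px path.  A crossing is a
    maximal run of consecutive columns in which the curve path 8-touches a
    skeleton pixel; runs separated by at most ``gap_tolerance`` columns merge
    into one crossing, and runs lying entirely within ``border_margin``
    columns of the left/right edge are discarded.
    """
    return len(_crossing_runs(skel, curve, cfg or ContourConfig()))


def _crossing_runs(
    skel: np.ndarray, curve: CurveProfile, cfg: ContourConfig
) -> list[tuple[int, int]]:
    """Column intervals [start, stop] of the crossings counted above."""
    skel = _as_skeleton(skel)
    H, W = skel.shape
    path = _rasterize_profile(curve, (H, W))
    near_skel = ndi.binary_dilation(skel, structure=_BOX3)
    touched = (path & near_skel).any(axis=0)
    merged: list[list[int]] = []
    for start, stop in _runs_of(touched):
        if merged and start - merged[-1][1] - 1 <= cfg.gap_tolerance:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    m = cfg.border_margin
    return [(a, b) for a, b in merged if not (b < m or a >= W - m)]


def _contour_count(
    skel: np.ndarray,
    base: CurveProfile,
    cfg: ContourConfig,
    method: str,
) -> CountResult:
    offset = compute_offset(skel, cfg)
    per_curve: list[int] = []
    intervals: list[list[tuple[int, int]]] = []
    for k in range(1, cfg.n_curves + 1):
        curve = translate_curve(base, k * offset)
        runs = _crossing_runs(skel, curve, cfg)
        per_curve.append(len(runs))
        intervals.append(runs)
    diagnostics = {"offset": offset, "base_rows": base.rows.copy(), "runs": intervals}
    return CountResult(
        method=method,  # type: ignore[arg-type]
        count=float(np.mean(per_curve)),
        per_curve_counts=per_curve,
        n_curves=cfg.n_curves,
        diagnostics=diagnostics,
    )


def count_auto_contour(skel: np.ndarray, cfg: ContourConfig | None = None) -> CountResult:
    """Fully automated surface contouring.

    Detects the base curve from the skeleton, translates it upward
    ``n_curves`` times with equal offset, and reports the mean number of
    crossings as the trichome count.
    """
    cfg = cfg or ContourConfig()
    base = detect_base_curve(skel)
    return _contour_count(skel, base, cfg, "auto_contour")


def count_annotated_contour(
    skel: np.ndarray, base: CurveProfile, cfg: ContourConfig | None = None
) -> CountResult:
    """Surface contouring from a human-annotated base curve.

    Identical to :func:`count_auto_contour` but using a supplied base curve,
    which sidesteps base-detection failures on uneven leaf surfaces.
    """
    cfg = cfg or ContourConfig()
    skel = _as_skeleton(skel)
    occupied = np.flatnonzero(skel.any(axis=0))
    if occupied.size:
        first, last = base.defined_span
        if first > occupied[0] or last < occupied[-1]:
            warnings.warn(
                "annotated base curve does not cover the skeleton's column span; "
                "extending by nearest-value interpolation"
            )
    return _contour_count(skel, base, cfg, "annotated_contour")


def count_annotated_intersection(
    skel: np.ndarray, curve: CurveProfile, cfg: ContourConfig | None = None
) -> CountResult:
    """Single human-drawn intersection curve through the trichome stalks."""
    cfg = cfg or ContourConfig()
    runs = _crossing_runs(skel, curve, cfg)
    return CountResult(
        method="annotated_intersection",
        count=float(len(runs)),
        per_curve_counts=[len(runs)],
        n_curves=1,
        diagnostics={"curve_rows": curve.rows.copy(), "runs": [runs]},
    )
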