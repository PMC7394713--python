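"""Micrograph preprocessing: lightness conversion, segmentation, skeletonization.

Side-view micrographs of cleared leaves show dark, hair-like trichomes over a
bright translucent background.  The pipeline separates them in the CIE L*
(lightness) channel, binarizes with a global threshold, denoises the mask, and
thins it to a 1-pixel skeleton on which all counting methods operate:

    RGB  ->  L*  ->  binary mask  ->  smoothed mask  ->  main component  ->  skeleton

Conventions: row 0 at the top of the image (the leaf band sits at high row
indices), 8-connectivity throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure
from skimage import morphology
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateSegmentationError,
    EmptyMaskError,
    FormatError,
    StageError,
)

__all__ = [
    "PreprocessConfig",
    "rgb_to_lightness",
    "segment_trichomes",
    "binarize_otsu",
    "smooth_mask",
    "keep_main_component",
    "skeletonize",
    "preprocess_pipeline",
]

_MIN_SIDE = 8  # smallest meaningful micrograph side length


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    Parameters
    ----------
    lightness_threshold
        Threshold on the L* channel (0-100 scale) separating trichomes from
        the cleared leaf, or ``"auto"`` to choose it by Otsu's criterion
        (maximum between-class variance of the lightness histogram).
    gaussian_sigma
        Standard deviation in pixels of the Gaussian blur applied to the
        binary mask before thinning; 0 disables smoothing.
    min_component_area
        Minimum component area in pixels kept under the ``area_threshold``
        strategy.
    keep_strategy
        ``"largest"`` keeps only the largest 8-connected component (the leaf
        band with its attached trichomes); ``"area_threshold"`` keeps every
        component of at least ``min_component_area`` pixels.
    polarity
        Which lightness class is trichome foreground: ``"dark"``, ``"bright"``
        or ``"auto"`` (the minority class — trichomes are sparse relative to
        the background).
    post_skeleton_sigma
        Optional second low-pass pass applied to the skeleton (followed by
        re-thinning to restore 1-px width); 0 disables it.
    """

    lightness_threshold: float | Literal["auto"] = "auto"
    gaussian_sigma: float = 1.0
    min_component_area: int = 1
    keep_strategy: Literal["largest", "area_threshold"] = "largest"
    polarity: Literal["auto", "dark", "bright"] = "auto"
    post_skeleton_sigma: float = 0.0

    def __post_init__(self):
        if self.lightness_threshold != "auto":
            t = float(self.lightness_threshold)
            if not 0.0 <= t <= 100.0:
                raise FormatError("lightness_threshold must be in [0, 100] or 'auto'")
        if self.gaussian_sigma < 0:
            raise FormatError("gaussian_sigma must be >= 0")
        if self.min_component_area < 1:
            raise FormatError("min_component_area must be >= 1")
        if self.keep_strategy not in ("largest", "area_threshold"):
            raise FormatError(f"unknown keep_strategy {self.keep_strategy!r}")
        if self.polarity not in ("auto", "dark", "bright"):
            raise FormatError(f"unknown polarity {self.polarity!r}")


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < _MIN_SIDE or img.shape[1] < _MIN_SIDE:
        raise FormatError(f"image too small: {img.shape[:2]} (need >= {_MIN_SIDE} px sides)")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise FormatError("RGB image must be 8-bit per channel")
    return img


def rgb_to_lightness(img: np.ndarray) -> np.ndarray:
    """CIE L* (D65) lightness channel of an 8-bit RGB image, 0-100 scale."""
    img = _validate_rgb(img)
    return skcolor.rgb2lab(img)[..., 0]


def segment_trichomes(lum: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Threshold the lightness image so trichome pixels are foreground.

    With ``cfg.lightness_threshold == "auto"`` the threshold maximizes the
    between-class variance of the lightness histogram (Otsu's criterion,
    256 bins).  Pixels at or below the threshold form the dark class; the
    polarity setting decides which class is foreground, with ``"auto"``
    picking the minority class.
    """
    cfg = cfg or PreprocessConfig()
    lum = np.asarray(lum, dtype=float)
    if lum.ndim != 2:
        raise FormatError(f"expected a 2-D lightness image, got shape {lum.shape}")
    if cfg.lightness_threshold == "auto":
        if np.ptp(lum) == 0:
            raise DegenerateSegmentationError("uniform image: no threshold separates two classes")
        thr = threshold_otsu(lum, nbins=256)
    else:
        thr = float(cfg.lightness_threshold)
    dark = lum <= thr
    if cfg.polarity == "dark":
        fg = dark
    elif cfg.polarity == "bright":
        fg = ~dark
    else:
        fg = dark if dark.sum() <= (~dark).sum() else ~dark
    n = fg.sum()
    if n == 0 or n == fg.size:
        raise DegenerateSegmentationError(
            f"threshold {thr:.3g} yields {'all' if n else 'no'} foreground pixels"
        )
    return fg


def binarize_otsu(gray: np.ndarray, polarity: Literal["auto", "dark", "bright"] = "auto") -> np.ndarray:
    """Global Otsu binarization of a grayscale/lightness image.

    Thin wrapper over :func:`segment_trichomes` with an automatic threshold,
    so trichome (minority, dark by default) pixels come out True.
    """
    cfg = PreprocessConfig(lightness_threshold="auto", polarity=polarity)
    return segment_trichomes(np.asarray(gray, dtype=float), cfg)


def smooth_mask(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur a binary mask (as 0/1 reals) and re-threshold at 0.5.

    ``sigma = 0`` is the identity.  Small isolated speckles fall below the
    0.5 level and vanish; large solid regions keep their interior.
    """
    mask = np.asarray(mask, dtype=bool)
    if sigma < 0:
        raise FormatError("sigma must be >= 0")
    if sigma == 0:
        return mask.copy()
    blurred = ndi.gaussian_filter(mask.astype(float), sigma)
    return blurred >= 0.5


def keep_main_component(mask: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Denoise a mask by connected-component selection (8-connectivity).

    ``largest`` keeps only the biggest component; in micrographs the leaf
    band and every trichome rooted on it form one component, so this removes
    detached speckle noise.  ``area_threshold`` keeps all components of at
    least ``cfg.min_component_area`` pixels.
    """
    cfg = cfg or PreprocessConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    if cfg.keep_strategy == "largest":
        return labels == areas.argmax()
    keep = np.flatnonzero(areas >= cfg.min_component_area)
    return np.isin(labels, keep)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-pixel-wide skeleton.

    Morphological thinning preserves the number of 8-connected components
    and is idempotent on already-thin input.  A final pruning pass deletes
    deletable pixels from any residual fully-foreground 2x2 block (thinning
    can leave one in dense diagonal clutter), so no skeleton pixel ever has
    a fully-foreground 2x2 neighborhood.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot skeletonize an empty mask")
    return _prune_2x2_blocks(morphology.thin(mask))


def _is_deletable(skel: np.ndarray, r: int, c: int) -> bool:
    """True if the 8-neighbors of (r, c) form a single 8-connected set."""
    patch = skel[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2].copy()
    patch[min(r, 1), min(c, 1)] = False
    _, n = ndi.label(patch, structure=np.ones((3, 3)))
    return n == 1


def _prune_2x2_blocks(skel: np.ndarray) -> np.ndarray:
    skel = skel.copy()
    for _ in range(8):  # blocks are rare; a few sweeps always suffice
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        if not blocks.any():
            break
        changed = False
        for r, c in np.argwhere(blocks):
            if not (skel[r, c] & skel[r, c + 1] & skel[r + 1, c] & skel[r + 1, c + 1]):
                continue
            for rr, cc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                if _is_deletable(skel, rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
        if not changed:
            break
    return skel


_STAGES = ("rgb_to_lightness", "segment_trichomes", "smooth_mask",
           "keep_main_component", "skeletonize")


def preprocess_pipeline(
    img: np.ndarray,
    cfg: PreprocessConfig | None = None,
    return_stages: bool = False,
):
    """Full preprocessing chain from RGB micrograph to denoised skeleton.

    Runs lightness conversion, segmentation, mask smoothing, component
    selection and thinning in order.  With ``return_stages=True`` also
    returns a dict of every intermediate image keyed by stage name, so each
    step can be inspected or exported.  Stage failures are re-raised as
    :class:`~trichocount.errors.StageError` carrying the stage name.
    """
    cfg = cfg or PreprocessConfig()
    stages: dict[str, np.ndarray] = {}

    def run(name, fn, *args):
        try:
            out = fn(*args)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise StageError(name, exc) from exc
        stages[name] = out
        return out

    lum = run("rgb_to_lightness", rgb_to_lightness, img)
    mask = run("segment_trichomes", segment_trichomes, lum, cfg)
    mask = run("smooth_mask", smooth_mask, mask, cfg.gaussian_sigma)
    mask = run("keep_main_component", keep_main_component, mask, cfg)
    skel = run("skeletonize", skeletonize, mask)
    if cfg.post_skeleton_sigma > 0:
        smoothed = run("post_skeleton_smooth", smooth_mask, skel, cfg.post_skeleton_sigma)
        if not smoothed.any():
            warnings.warn("post-skeleton smoothing erased the skeleton; keeping unsmoothed")
        else:
            skel = run("post_skeleton_thin", skeletonize, smoothed)
    stages["skeleton"] = skel
    if return_stages:
        return skel, stages
    return skel
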