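"""Synthetic side-view trichome scenes with exact ground truth.

Real validation data for trichome counting are side-view micrographs of
cleared leaves: a bright translucent background, a leaf band along the
bottom whose surface edge reads dark, and dark hair-like trichomes rooted on
that surface, possibly occluding one another, plus specks of debris.  This
module renders such scenes from a parametric specification and returns the
exact ground truth alongside — the true count, the true base curve, an
oracle intersection curve guaranteed to cross every filament, and the mask
of injected noise — so every counting method can be scored without manually
counted images.

Filaments are quadratic arcs (one curvature control point) rooted on a
smooth, possibly wavy base curve.  With ``occlusion_bias = 0`` the generator
enforces a horizontal clearance between neighboring filaments at every
height, so no two filaments touch; with ``occlusion_bias > 0`` a matching
fraction of filaments have their tip placed exactly on a neighbor's stalk,
reproducing the occlusion failure mode of endpoint counting (a trichome
whose free end rests on another trichome has no detectable endpoint).

Everything is drawn from a single NumPy generator seeded from ``spec.seed``,
so a spec maps to a bit-identical scene.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import color as skcolor

from .annotation import AnnotationCurve
from .errors import SceneError
from .profile import CurveProfile

__all__ = ["SceneSpec", "SceneTruth", "generate_scene", "scene_batch", "sweep_specs"]

# minimum horizontal gap (px) between non-occluding filament paths; chosen so
# that crossing runs on any contour curve stay separated after run merging
_CLEARANCE = 7.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Geometry is in pixels; lightness values are on the CIE L* 0-100 scale.
    ``filament_lightness`` must be darker than ``background_lightness``
    (dark trichomes on a cleared, bright leaf).
    """

    width: int = 640
    height: int = 300
    n_trichomes: int = 20
    base_amplitude: float = 4.0        # waviness amplitude of the leaf surface
    base_wavelength: float = 180.0
    filament_length_mean: float = 60.0
    filament_length_sd: float = 6.0
    filament_curvature: float = 3.0    # max lateral bow of the arc (px)
    filament_thickness: int = 2
    angle_sd: float = 6.0              # degrees from vertical
    occlusion_bias: float = 0.0        # fraction of filaments tipped onto a neighbor
    speckle_count: int = 0
    speckle_size: int = 5
    background_lightness: float = 85.0
    filament_lightness: float = 15.0
    edge_margin: int = 15              # keep roots away from left/right borders
    min_root_spacing: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise SceneError("scene must be at least 32 x 32 px")
        if self.n_trichomes < 0:
            raise SceneError("n_trichomes must be >= 0")
        if self.filament_length_mean >= self.height:
            raise SceneError("filament length must be smaller than the image height")
        if not self.filament_lightness < self.background_lightness:
            raise SceneError("filaments must be darker than the background")
        if not 0.0 <= self.occlusion_bias <= 1.0:
            raise SceneError("occlusion_bias must lie in [0, 1]")
        if self.filament_thickness < 1:
            raise SceneError("filament_thickness must be >= 1")

    @classmethod
    def noiseless(cls, n_trichomes: int, seed: int, **overrides) -> "SceneSpec":
        """Verification preset: conditions under which every counting method
        is exact by construction.

        Equal-length, near-vertical filaments on a flat base, no speckles and
        no occlusion.  Equal lengths matter because the contour offset is
        derived from the common band height; with varying lengths the upper
        contour curves pass above the shorter trichomes, an undercount that
        is a property of the method rather than a rendering artifact.
        """
        kwargs = dict(
            n_trichomes=n_trichomes,
            seed=seed,
            filament_length_sd=0.0,
            base_amplitude=0.0,
            angle_sd=2.0,
            filament_curvature=2.0,
            speckle_count=0,
            occlusion_bias=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SceneTruth:
    """Exact ground truth for one rendered scene."""

    count: int
    base_profile: CurveProfile
    oracle_curve: AnnotationCurve
    filament_paths: list[np.ndarray] = field(default_factory=list)  # (N, 2) (col, row)
    noise_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.count != len(self.filament_paths):
            raise SceneError("truth count must equal the number of filament paths")


def _base_rows(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency leaf-surface curve across the bottom third."""
    c = np.arange(spec.width, dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    rows = 0.72 * spec.height + spec.base_amplitude * np.sin(
        2 * np.pi * c / spec.base_wavelength + phase
    )
    return np.clip(rows, 4, spec.height - 5)


def _place_roots(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_trichomes
    lo = spec.edge_margin
    hi = spec.width - 1 - spec.edge_margin
    span = hi - lo
    slack = span - (n - 1) * spec.min_root_spacing
    if slack < 0:
        raise SceneError(
            f"cannot place {n} roots with spacing {spec.min_root_spacing} in {span} px"
        )
    jitter = np.sort(rng.uniform(0, slack, size=n))
    return lo + np.arange(n) * spec.min_root_spacing + jitter


def _bezier(p0, ctrl, p1, n_pts):
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def _stamp_offsets(thickness: int) -> np.ndarray:
    r = thickness / 2.0
    k = int(np.ceil(r))
    dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
    keep = dx**2 + dy**2 <= r**2 + 1e-9
    return np.column_stack([dy[keep], dx[keep]])


def _draw_path(canvas_mask: np.ndarray, path: np.ndarray, offsets: np.ndarray) -> None:
    H, W = canvas_mask.shape
    pts = np.rint(path).astype(int)  # (col, row)
    rr = pts[:, 1][:, None] + offsets[:, 0]
    cc = pts[:, 0][:, None] + offsets[:, 1]
    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    canvas_mask[rr[ok], cc[ok]] = True


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render a scene and its ground truth.

    Returns the 8-bit RGB image (grayscale triples produced by converting
    the lightness canvas through CIE Lab, so the lightness conversion in
    preprocessing is exercised nontrivially) and the :class:`SceneTruth`.
    Deterministic: the same spec yields a bit-identical scene.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    base = _base_rows(spec, rng)

    oracle_off = round(0.3 * spec.filament_length_mean)
    # every filament must rise high enough to cross the oracle curve even
    # where the wavy base is at its lowest
    min_extent = oracle_off + 2 * spec.base_amplitude + 4.0
    if min_extent >= 0.9 * spec.filament_length_mean + 3 * spec.filament_length_sd:
        min_extent = 0.45 * spec.filament_length_mean
    max_angle = np.deg2rad(30.0)

    paths: list[np.ndarray] = []
    extents: list[float] = []
    if spec.n_trichomes > 0:
        roots_x = _place_roots(spec, rng)
        gaps = np.diff(roots_x)
        n = spec.n_trichomes
        lanes = np.empty(n)
        for i in range(n):
            g = min(
                gaps[i - 1] if i > 0 else np.inf,
                gaps[i] if i < n - 1 else np.inf,
            )
            lanes[i] = max((g - _CLEARANCE) / 2.0, 0.5) if np.isfinite(g) else 10.0

        # each filament (after the first) independently rests its tip on its
        # left neighbor with probability occlusion_bias, the way trichome
        # overlap strikes at random in projection
        occluded = {
            i for i in range(1, n) if rng.uniform() < spec.occlusion_bias
        } if spec.occlusion_bias > 0 else set()

        for i in range(n):
            x0 = roots_x[i]
            y0 = base[int(round(x0))]
            length = float(np.clip(
                rng.normal(spec.filament_length_mean, spec.filament_length_sd),
                min_extent / np.cos(max_angle),
                max(y0 - 4.0, min_extent / np.cos(max_angle)),
            ))
            curv = float(rng.uniform(-spec.filament_curvature, spec.filament_curvature))
            curv = float(np.clip(curv, -lanes[i] / 2, lanes[i] / 2))
            theta = np.deg2rad(rng.normal(0.0, spec.angle_sd))
            # stay inside the lane and keep enough vertical extent
            sin_cap = max(lanes[i] - abs(curv), 0.0) / length
            theta_cap = min(
                max_angle,
                np.arcsin(min(sin_cap, 1.0)),
                np.arccos(min(min_extent / length, 1.0)),
            )
            theta = float(np.clip(theta, -theta_cap, theta_cap))

            # a filament can only rest its tip on a neighbor tall enough to
            # host the crossing above the oracle curve; otherwise it grows
            # normally (occluded chains shorten with every link)
            if i in occluded and paths and 0.9 * extents[i - 1] >= min_extent + 2:
                target = paths[i - 1]
                t_root_y = target[0, 1]
                ne = extents[i - 1]
                frac = rng.uniform(0.55, 0.75)
                h_c = float(np.clip(frac * ne, min_extent + 2, 0.9 * ne))
                # tip lands exactly on the neighbor's stalk at height h_c
                j = int(np.argmin(np.abs((t_root_y - target[:, 1]) - h_c)))
                tip = target[j].copy()
            else:
                tip = np.array([x0 + length * np.sin(theta), y0 - length * np.cos(theta)])
            p0 = np.array([x0, y0])
            mid = 0.5 * (p0 + tip)
            ctrl = mid + np.array([curv, 0.0])
            n_pts = max(16, int(2 * np.linalg.norm(tip - p0)))
            paths.append(_bezier(p0, ctrl, tip, n_pts))
            extents.append(float(y0 - tip[1]))

    # --- render -----------------------------------------------------------
    canvas = np.full((H, W), spec.background_lightness, dtype=float)
    strip_th = max(2, spec.filament_thickness)
    cols = np.arange(W)
    base_int = np.rint(base).astype(int)
    for dr in range(strip_th):
        rr = np.clip(base_int + dr, 0, H - 1)
        canvas[rr, cols] = spec.filament_lightness

    fil_mask = np.zeros((H, W), dtype=bool)
    offsets = _stamp_offsets(spec.filament_thickness)
    for path in paths:
        _draw_path(fil_mask, path, offsets)
    canvas[fil_mask] = spec.filament_lightness

    # speckle noise: short dark strokes away from the filaments and the leaf
    noise_mask = np.zeros((H, W), dtype=bool)
    if spec.speckle_count > 0:
        from scipy import ndimage as ndi

        obstacle = ndi.binary_dilation(
            fil_mask | (canvas == spec.filament_lightness), iterations=6
        )
        top = 8
        bottom = int(base_int.min()) - 10
        for _ in range(spec.speckle_count):
            for _attempt in range(100):
                r = rng.integers(top, max(bottom, top + 1))
                c = rng.integers(spec.edge_margin + 5, W - spec.edge_margin - 5)
                if not obstacle[r, c]:
                    break
            else:
                continue
            ang = rng.uniform(0, np.pi)
            p0 = np.array([c - 0.5 * spec.speckle_size * np.cos(ang),
                           r - 0.5 * spec.speckle_size * np.sin(ang)])
            p1 = np.array([c + 0.5 * spec.speckle_size * np.cos(ang),
                           r + 0.5 * spec.speckle_size * np.sin(ang)])
            seg = _bezier(p0, 0.5 * (p0 + p1), p1, max(8, 2 * spec.speckle_size))
            _draw_path(noise_mask, seg, offsets)
            obstacle |= ndi.binary_dilation(noise_mask, iterations=4)
        canvas[noise_mask] = spec.filament_lightness

    # --- truth ------------------------------------------------------------
    oracle_rows = np.clip(base - oracle_off, 1, H - 1)
    step = max(1, W // 80)
    pts_c = np.unique(np.concatenate([np.arange(0, W, step), [W - 1]])).astype(float)
    oracle = AnnotationCurve(
        np.column_stack([pts_c, oracle_rows[pts_c.astype(int)]]),
        kind="intersection",
        source="polyline_file",
    )
    for i, path in enumerate(paths):
        o_at = np.interp(path[:, 0], cols, oracle_rows)
        if not ((path[:, 1] < o_at - 1).any() and (path[:, 1] > o_at + 1).any()):
            raise SceneError(f"internal: filament {i} does not cross the oracle curve")

    truth = SceneTruth(
        count=len(paths),
        base_profile=CurveProfile(base.copy()),
        oracle_curve=oracle,
        filament_paths=paths,
        noise_mask=noise_mask,
    )

    lab = np.zeros((H, W, 3), dtype=float)
    lab[..., 0] = canvas
    rgb = np.clip(np.rint(skcolor.lab2rgb(lab) * 255), 0, 255).astype(np.uint8)
    return rgb, truth


def sweep_specs(
    counts,
    seeds,
    **overrides,
) -> list[SceneSpec]:
    """Cartesian sweep of trichome counts x seeds, with shared overrides."""
    return [
        dataclasses.replace(SceneSpec(**overrides), n_trichomes=int(n), seed=int(s))
        for n in counts
        for s in seeds
    ]


def scene_batch(specs, out_dir: str | Path) -> pd.DataFrame:
    """Render a batch of scenes to disk and return the manifest.

    Writes ``scene_###.png``, ``scene_###.truth.json`` (count, base curve,
    oracle curve, spec fields) and ``manifest.csv`` into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, spec in enumerate(specs):
        img, truth = generate_scene(spec)
        stem = f"scene_{i:03d}"
        img_path = out_dir / f"{stem}.png"
        truth_path = out_dir / f"{stem}.truth.json"
        iio.imwrite(img_path, img)
        truth_path.write_text(json.dumps({
            "count": truth.count,
            "base_rows": truth.base_profile.rows.tolist(),
            "oracle_points": truth.oracle_curve.points.tolist(),
            "spec": dataclasses.asdict(spec),
        }))
        records.append({
            "scene_id": stem,
            "image": img_path.name,
            "truth": truth_path.name,
            "count": truth.count,
            "seed": spec.seed,
            "n_trichomes": spec.n_trichomes,
            "occlusion_bias": spec.occlusion_bias,
            "speckle_count": spec.speckle_count,
            "base_amplitude": spec.base_amplitude,
            "filament_length_mean": spec.filament_length_mean,
        })
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
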