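"""Pressure-distribution image features for posture classification.

A 16 x 16 pressure frame is rendered as a colour map (the form in which
posture is visually distinct), then pushed through the classical chain
grayscale -> 3x3 median filter -> Otsu binarisation -> largest component,
from which 19 features are computed in three groups:

* geometry of the contact blob: circumference (8-connected chain length,
  diagonal steps count sqrt(2)), area (pixel count), roundness
  ``4*pi*A / P**2``, and the seven Hu invariant moments;
* texture: gray-level co-occurrence statistics (energy, entropy, inertia;
  mean and standard deviation across the four distance-1 directions);
* colour: mean red/green/blue over the contact blob.

Features are normalised per column by the maximum absolute value seen in
training (``q* = q / max|q|``), handled by :class:`FeatureScaler`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from scipy.ndimage import median_filter
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "FEATURE_NAMES",
    "RenderedImage",
    "FeatureScaler",
    "render_frame_image",
    "to_grayscale",
    "median_filter3",
    "binarize",
    "largest_component",
    "extract_shape",
    "geometric_features",
    "glcm_features",
    "color_features",
    "extract_feature_vector",
]

#: fixed order of the 19 features; models and scalers are tied to this order
FEATURE_NAMES = (
    "circumference",
    "area",
    "roundness",
    "hu1", "hu2", "hu3", "hu4", "hu5", "hu6", "hu7",
    "energy_mean", "energy_sd",
    "entropy_mean", "entropy_sd",
    "inertia_mean", "inertia_sd",
    "mean_red", "mean_green", "mean_blue",
)

#: voltage range mapped onto the colormap when per-frame normalisation is off
VOLTAGE_RANGE = (0.0, 3.0)

# Blue-to-red pressure colormap with monotonically increasing luminance, so
# the subsequent grayscale/Otsu stage segments the contact blob cleanly.
PRESSURE_CMAP = LinearSegmentedColormap.from_list(
    "pressure",
    [
        (0.00, (0.00, 0.00, 0.30)),
        (0.25, (0.05, 0.20, 0.70)),
        (0.50, (0.50, 0.10, 0.50)),
        (0.75, (0.90, 0.30, 0.15)),
        (1.00, (1.00, 0.55, 0.10)),
    ],
)

# GLCM direction offsets (drow, dcol) for 0, 45, 90, 135 degrees at distance 1
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
_GLCM_LEVELS = 16


@dataclass
class RenderedImage:
    """RGB rendering of a pressure frame (uint8 channels)."""

    rgb: np.ndarray
    colormap_name: str = "pressure"

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must be H x W x 3, got {self.rgb.shape}")


def render_frame_image(frame, upsample: int = 16, per_frame_norm: bool = False) -> RenderedImage:
    """Render a 16 x 16 frame as an RGB colour map.

    Values are rescaled to [0, 1] — over the fixed :data:`VOLTAGE_RANGE` by
    default, or over the frame's own min/max when ``per_frame_norm`` is set —
    bilinearly upsampled by ``upsample`` and mapped through the blue-to-red
    pressure colormap.
    """
    values = np.asarray(getattr(frame, "values", frame), dtype=float)
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if per_frame_norm:
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            hi = lo + 1.0
    else:
        lo, hi = VOLTAGE_RANGE
    v = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    if upsample > 1:
        v = resize(v, (v.shape[0] * upsample, v.shape[1] * upsample),
                   order=1, anti_aliasing=False, mode="edge")
    rgb = np.rint(PRESSURE_CMAP(v)[..., :3] * 255.0).astype(np.uint8)
    return RenderedImage(rgb)


def to_grayscale(image: RenderedImage | np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance: round(0.299 R + 0.587 G + 0.114 B), uint8."""
    rgb = np.asarray(getattr(image, "rgb", image), dtype=float)
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.rint(gray).astype(np.uint8)


def median_filter3(gray: np.ndarray) -> np.ndarray:
    """3x3 median filter with reflected edges."""
    gray = np.asarray(gray)
    if gray.ndim != 2 or min(gray.shape) < 3:
        raise ValueError("median_filter3 requires a 2-D grid of at least 3x3")
    return median_filter(gray, size=3, mode="reflect")


def binarize(gray: np.ndarray) -> tuple[np.ndarray, float]:
    """Otsu threshold; pixels strictly above the threshold are foreground.

    A constant image has no between-class split; by convention it is all
    foreground with threshold ``value - 1``.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if np.all(gray == gray.flat[0]):
        thr = float(gray.flat[0]) - 1.0
        return np.ones_like(gray, dtype=bool), thr
    thr = float(threshold_otsu(gray))
    return gray > thr, thr


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Mask of the largest 8-connected foreground component."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("binary image has no foreground")
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered 8-connected outer boundary of a connected mask (Moore tracing).

    Returns an (L, 2) array of (row, col) pixel coordinates forming a closed
    path (last step returns to the first pixel implicitly).  A single-pixel
    mask yields a single point.
    """
    mask = np.asarray(mask, dtype=bool)
    pad = np.pad(mask, 1)
    rows, cols = np.nonzero(pad)
    if rows.size == 0:
        raise ValueError("empty mask")
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))  # topmost, then leftmost
    if rows.size == 1:
        return np.array([[start[0] - 1, start[1] - 1]])
    # Moore neighbourhood in clockwise order starting from W
    nbrs = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
    contour = [start]
    p = start
    prev_idx = 0  # we "came from" the west, which is background at `start`
    second = None
    for _ in range(8 * pad.size):
        for k in range(1, 9):
            idx = (prev_idx + k) % 8
            c = (p[0] + nbrs[idx][0], p[1] + nbrs[idx][1])
            if pad[c]:
                break
        else:
            break  # isolated pixel
        if p == start:
            if second is None:
                second = c
            elif c == second:
                break  # re-entering the start the same way: loop closed
        # next scan starts at the last background neighbour, seen from c
        last_bg = (p[0] + nbrs[(idx - 1) % 8][0], p[1] + nbrs[(idx - 1) % 8][1])
        prev_idx = nbrs.index((last_bg[0] - c[0], last_bg[1] - c[1]))
        p = c
        contour.append(p)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.asarray(contour) - 1  # undo padding offset


def _chain_length(contour: np.ndarray) -> float:
    """Closed-path length of a boundary: 1 per orthogonal, sqrt(2) per diagonal step."""
    if contour.shape[0] < 2:
        return 0.0
    closed = np.vstack([contour, contour[:1]])
    steps = np.abs(np.diff(closed, axis=0))
    diag = (steps[:, 0] == 1) & (steps[:, 1] == 1)
    return float(np.sum(~diag) + np.sqrt(2.0) * np.sum(diag))


def _min_area_rect(points: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Minimum-area enclosing rectangle of a 2-D point set (rotating calipers).

    Returns the four rectangle corners and the sorted side lengths.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] == 1:
        p = pts[0]
        corners = p + np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, 0.5], [0.5, -0.5]])
        return corners, (1.0, 1.0)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] <= 2 or np.linalg.matrix_rank(uniq - uniq[0]) < 2:
        # collinear: degenerate rectangle along the segment
        d = uniq[-1] - uniq[0]
        length = float(np.linalg.norm(d))
        return np.vstack([uniq[0], uniq[-1], uniq[-1], uniq[0]]), tuple(sorted((0.0, length)))
    hull = uniq[ConvexHull(uniq).vertices]
    best = None
    for i in range(len(hull)):
        edge = hull[(i + 1) % len(hull)] - hull[i]
        edge = edge / np.linalg.norm(edge)
        normal = np.array([-edge[1], edge[0]])
        proj_e = hull @ edge
        proj_n = hull @ normal
        w = proj_e.max() - proj_e.min()
        h = proj_n.max() - proj_n.min()
        if best is None or w * h < best[0]:
            best = (w * h, edge, normal, proj_e.min(), proj_e.max(), proj_n.min(), proj_n.max())
    _, e, n_, e0, e1, n0, n1 = best
    corners = np.array([
        e0 * e + n0 * n_, e1 * e + n0 * n_, e1 * e + n1 * n_, e0 * e + n1 * n_,
    ])
    sides = tuple(sorted((float(e1 - e0), float(n1 - n0))))
    return corners, sides


def extract_shape(binary: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, tuple[float, float]]]:
    """Boundary contour and minimum enclosing rectangle of the largest component.

    The rectangle is computed over the pixel *corner* points (each foreground
    pixel treated as a unit square), so an axis-aligned w x h block yields
    side lengths exactly (w, h).
    """
    comp = largest_component(binary)
    contour = _trace_boundary(comp)
    centers = np.argwhere(comp).astype(float)
    corners_pts = np.concatenate([
        centers + np.array(off)
        for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))
    ])
    rect = _min_area_rect(corners_pts)
    return contour, rect


def geometric_features(binary: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Circumference, area, roundness and Hu moments of the largest component.

    Degenerate blobs whose traced boundary has zero length (single pixel)
    report circumference 0 and roundness 0.
    """
    comp = largest_component(binary)
    area = float(comp.sum())
    contour = _trace_boundary(comp)
    circumference = _chain_length(contour)
    roundness = 4.0 * np.pi * area / circumference**2 if circumference > 0 else 0.0
    m = measure.moments_central(comp.astype(float))
    hu = measure.moments_hu(measure.moments_normalized(m))
    return circumference, area, roundness, hu


def glcm_features(gray: np.ndarray, mask: np.ndarray) -> tuple[float, ...]:
    """Texture statistics from gray-level co-occurrence matrices.

    Gray values (0-255) are quantised to 16 levels; four symmetric normalised
    co-occurrence matrices are tabulated at distance 1 (0/45/90/135 degrees)
    over pixel pairs lying entirely inside ``mask``.  Per matrix: energy
    ``sum p**2``, entropy ``-sum p log2 p`` and inertia ``sum (i-j)**2 p``;
    the mean and (population) standard deviation across the four directions
    are returned as
    ``(energy_mean, energy_sd, entropy_mean, entropy_sd, inertia_mean, inertia_sd)``.
    """
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise ValueError("gray and mask shapes differ")
    if mask.sum() < 2:
        raise ValueError("masked region must contain at least 2 pixels")
    levels = (gray.astype(int) * _GLCM_LEVELS) // 256
    energies, entropies, inertias = [], [], []
    idx = np.arange(_GLCM_LEVELS, dtype=float)
    dij2 = (idx[:, None] - idx[None, :]) ** 2
    for dr, dc in _GLCM_OFFSETS:
        a, am = _shifted(levels, mask, 0, 0, dr, dc)
        b, bm = _shifted(levels, mask, dr, dc, 0, 0)
        valid = am & bm
        if not valid.any():
            raise ValueError("mask admits no pixel pairs in some direction")
        pairs = a[valid] * _GLCM_LEVELS + b[valid]
        counts = np.bincount(pairs, minlength=_GLCM_LEVELS**2).astype(float)
        P = counts.reshape(_GLCM_LEVELS, _GLCM_LEVELS)
        P = P + P.T                      # symmetric
        P = P / P.sum()                  # normalised
        energies.append(float(np.sum(P**2)))
        nz = P[P > 0]
        entropies.append(float(-np.sum(nz * np.log2(nz))))
        inertias.append(float(np.sum(dij2 * P)))
    out = []
    for stat in (energies, entropies, inertias):
        arr = np.asarray(stat)
        out.extend([float(arr.mean()), float(arr.std())])
    return tuple(out)


def _shifted(levels, mask, r0, c0, r1, c1):
    """Crop `levels`/`mask` so that offsetting by (r1-r0, c1-c0) stays in bounds."""
    h, w = levels.shape
    dr, dc = r1 - r0, c1 - c0
    rs = slice(max(0, -dr), min(h, h - dr))
    cs = slice(max(0, -dc), min(w, w - dc))
    rs2 = slice(rs.start + dr, rs.stop + dr)
    cs2 = slice(cs.start + dc, cs.stop + dc)
    return levels[rs2, cs2], mask[rs2, cs2]


def color_features(image: RenderedImage | np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean red/green/blue over masked pixels."""
    rgb = np.asarray(getattr(image, "rgb", image), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rgb.shape[:2]:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("empty mask")
    sel = rgb[mask]
    return tuple(float(x) for x in sel.mean(axis=0))


def extract_feature_vector(frame, upsample: int = 16) -> np.ndarray:
    """Run the full preprocessing chain and return the 19 features in order.

    render -> grayscale -> 3x3 median -> Otsu binarise -> largest component,
    then geometric, texture and colour feature groups over that component.
    """
    image = render_frame_image(frame, upsample=upsample)
    gray = to_grayscale(image)
    filtered = median_filter3(gray)
    binary, _ = binarize(filtered)
    comp = largest_component(binary)
    circumference, area, roundness, hu = geometric_features(comp)
    texture = glcm_features(filtered, comp)
    red, green, blue = color_features(image, comp)
    vec = np.array([circumference, area, roundness, *hu, *texture, red, green, blue])
    assert vec.shape == (len(FEATURE_NAMES),)
    return vec


@dataclass
class FeatureScaler:
    """Per-feature max-|q| normaliser: ``q* = q / max|q|`` (training maxima)."""

    denominators: np.ndarray

    def __post_init__(self) -> None:
        self.denominators = np.asarray(self.denominators, dtype=float)
        if np.any(self.denominators <= 0):
            raise ValueError("denominators must be positive")

    @classmethod
    def fit(cls, features: np.ndarray) -> "FeatureScaler":
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("need at least one feature vector")
        denom = np.abs(X).max(axis=0)
        denom[denom == 0] = 1.0
        return cls(denom)

    def transform(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        return X / self.denominators


def fit_scaler(features: np.ndarray) -> FeatureScaler:
    return FeatureScaler.fit(features)


def apply_scaler(scaler: FeatureScaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(features)
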