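"""Particle morphometry from grayscale SEM images.

Segments particles by grayscale + size thresholding and computes the
shape descriptors used in respirable-dust characterization:

* **ECD** — equivalent circular diameter, ``2 * sqrt(A_p / pi)``;
* **Feret diameters** — minimum and maximum caliper distances over all
  directions, computed on the convex hull of the particle's pixel
  *corner* points by rotating calipers (so a single pixel has extent 1
  pixel, not 0);
* **aspect ratio** — ``D_min / D_max`` in (0, 1], an elongation (form)
  descriptor;
* **solidity** — ``A_p / A_CH`` (particle area over convex-hull area),
  a particle-scale contour-irregularity (roughness) descriptor;
* **perimeter** — Moore border tracing with unit orthogonal and sqrt(2)
  diagonal steps.

Summaries follow Tukey's box-and-whisker convention: median, quartiles
(linear interpolation of order statistics), whiskers at the most extreme
points within 1.5 x IQR of the hinges, points beyond flagged as outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "ParticleImage",
    "SegmentationParams",
    "ParticleRegion",
    "ShapeMetrics",
    "TukeySummary",
    "segment_particles",
    "equivalent_circular_diameter",
    "feret_diameters",
    "shape_metrics",
    "filter_by_ecd",
    "summarize_tukey",
    "summarize_morphometry",
    "measure_image",
    "pixel_corner_hull",
]


@dataclass(frozen=True)
class ParticleImage:
    """A grayscale SEM image with its spatial calibration (μm/pixel)."""

    raster: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.raster, dtype=float)
        if arr.ndim != 2:
            raise ValueError("raster must be 2-D grayscale")
        if not np.all(np.isfinite(arr)):
            raise ValueError("raster contains non-finite intensities")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "raster", arr)


@dataclass(frozen=True)
class SegmentationParams:
    grayscale_threshold: float
    min_area_px: int = 1
    polarity: str = "particles-bright"  # or "particles-dark"

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.polarity not in ("particles-bright", "particles-dark"):
            raise ValueError("polarity must be 'particles-bright' or 'particles-dark'")


@dataclass(frozen=True)
class ParticleRegion:
    """One 8-connected particle: its pixel coordinates and border status."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    touches_border: bool = False
    label: int = 0
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.intp)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValueError("pixels must be a non-empty (n, 2) coordinate array")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "area_px", int(px.shape[0]))

    def mask(self) -> np.ndarray:
        """Minimal bounding-box binary mask of the region."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        m = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
        m[self.pixels[:, 0] - rmin, self.pixels[:, 1] - cmin] = True
        return m


@dataclass(frozen=True)
class ShapeMetrics:
    """Per-particle shape descriptors in physical units (μm, μm²)."""

    area: float
    ecd: float
    d_min: float
    d_max: float
    aspect_ratio: float
    hull_area: float
    solidity: float
    perimeter: float
    touches_border: bool = False
    label: int = 0

    # Digitized solidity can exceed 1 by a hair when a region is its own hull.
    _EPS_PX = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.aspect_ratio <= 1 + 1e-12):
            raise ValueError(f"aspect_ratio {self.aspect_ratio} outside (0, 1]")
        if not (0 < self.solidity <= 1 + self._EPS_PX):
            raise ValueError(f"solidity {self.solidity} outside (0, 1 + eps]")
        if self.d_min > self.d_max * (1 + 1e-12):
            raise ValueError("d_min exceeds d_max")
        if self.ecd <= 0:
            raise ValueError("ecd must be positive")


@dataclass(frozen=True)
class TukeySummary:
    """Five-number Tukey summary with explicit outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


# ---------------------------------------------------------------------------
# segmentation


def segment_particles(
    image: ParticleImage, params: SegmentationParams
) -> list[ParticleRegion]:
    """Threshold, label 8-connected components, and apply the size filter.

    Components with fewer than ``min_area_px`` pixels are discarded;
    components touching the image frame are kept but flagged.
    """
    raster = image.raster
    if params.polarity == "particles-bright":
        binary = raster >= params.grayscale_threshold
    else:
        binary = raster <= params.grayscale_threshold
    labels = measure.label(binary, connectivity=2)
    regions: list[ParticleRegion] = []
    h, w = labels.shape
    for prop in measure.regionprops(labels):
        if prop.area < params.min_area_px:
            continue
        rmin, cmin, rmax, cmax = prop.bbox
        touches = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        regions.append(
            ParticleRegion(pixels=prop.coords, touches_border=touches, label=prop.label)
        )
    return regions


# ---------------------------------------------------------------------------
# geometry helpers


def pixel_corner_hull(region: ParticleRegion) -> np.ndarray:
    """Convex hull (counterclockwise (x, y) vertices) of the region's pixel corners.

    Each pixel (r, c) contributes its four unit-square corners, so the hull
    bounds the pixel area itself rather than the pixel centers.
    """
    px = region.pixels
    r, c = px[:, 0].astype(float), px[:, 1].astype(float)
    # x = column, y = row; corners of the unit square of each pixel
    corners = np.concatenate(
        [
            np.column_stack([c, r]),
            np.column_stack([c + 1, r]),
            np.column_stack([c, r + 1]),
            np.column_stack([c + 1, r + 1]),
        ]
    )
    corners = np.unique(corners, axis=0)
    if len(corners) < 3:
        return corners
    hull = ConvexHull(corners)
    return corners[hull.vertices]  # counterclockwise in (x, y)


def _hull_widths(vertices: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers min width and max diameter of a convex polygon."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    if n == 1:
        return 0.0, 0.0
    if n == 2:
        d = float(np.linalg.norm(v[1] - v[0]))
        return 0.0, d
    # Max Feret: diameter of the hull vertex set.
    diff = v[:, None, :] - v[None, :, :]
    d_max = float(np.sqrt((diff**2).sum(-1)).max())
    # Min Feret: for each hull edge, the farthest vertex distance to that
    # edge's supporting line; the minimum over edges is the caliper width.
    d_min = math.inf
    for i in range(n):
        p, q = v[i], v[(i + 1) % n]
        edge = q - p
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = float(np.abs((v - p) @ normal).max())
        d_min = min(d_min, width)
    return float(d_min), d_max


def feret_diameters(region: ParticleRegion, pixel_size: float = 1.0) -> tuple[float, float]:
    """Minimum and maximum Feret (caliper) diameters of a particle.

    Measured on the convex hull of the pixel corner points, so even a
    single pixel has a finite extent (``d_min = 1 px``).
    """
    hull = pixel_corner_hull(region)
    d_min, d_max = _hull_widths(hull)
    return d_min * pixel_size, d_max * pixel_size


def equivalent_circular_diameter(region: ParticleRegion, pixel_size: float) -> float:
    """ECD = 2 sqrt(A_p / pi) with A_p = area_px * pixel_size**2, in μm."""
    area = region.area_px * pixel_size * pixel_size
    return 2.0 * math.sqrt(area / math.pi)


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


_MOORE_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)


def _trace_perimeter(mask: np.ndarray) -> float:
    """Moore border tracing: orthogonal steps 1, diagonal steps sqrt(2), in px.

    Traces the outer boundary of the (single, 8-connected) foreground
    component; interior holes are ignored.  A 1-px region returns 4 by the
    unit-square convention.
    """
    coords = np.argwhere(mask)
    if len(coords) == 1:
        return 4.0
    padded = np.pad(mask, 1)
    start = tuple(np.argwhere(padded)[0])  # topmost, then leftmost (C order)
    # Jacob's stopping criterion: stop on re-entering start from the initial direction.
    perimeter = 0.0
    current = start
    backtrack = 6  # came from the left (west) of the top-left-most pixel
    first_move: tuple[tuple[int, int], int] | None = None
    while True:
        found = None
        for k in range(8):
            idx = (backtrack + 1 + k) % 8
            dr, dc = _MOORE_OFFSETS[idx]
            nxt = (current[0] + dr, current[1] + dc)
            if padded[nxt]:
                found = (nxt, idx)
                break
        if found is None:  # isolated pixel among padding (shouldn't happen for n>1)
            return 4.0
        nxt, idx = found
        step = math.sqrt(2.0) if idx % 2 == 1 else 1.0
        if first_move is None:
            first_move = (nxt, idx)
        elif current == start and (nxt, idx) == first_move:
            break
        perimeter += step
        backtrack = (idx + 4) % 8
        current = nxt
        if perimeter > 8.0 * mask.size:  # defensive: malformed mask
            break
    return perimeter


def shape_metrics(region: ParticleRegion, pixel_size: float) -> ShapeMetrics:
    """All shape descriptors of one particle, in physical units."""
    area = region.area_px * pixel_size * pixel_size
    ecd = equivalent_circular_diameter(region, pixel_size)
    if region.area_px == 1:
        # degenerate single pixel: aspect ratio and solidity 1 by convention
        return ShapeMetrics(
            area=area,
            ecd=ecd,
            d_min=pixel_size,
            d_max=pixel_size,
            aspect_ratio=1.0,
            hull_area=area,
            solidity=1.0,
            perimeter=4.0 * pixel_size,
            touches_border=region.touches_border,
            label=region.label,
        )
    hull = pixel_corner_hull(region)
    d_min_px, d_max_px = _hull_widths(hull)
    hull_area_px = _shoelace(hull) if len(hull) >= 3 else float(region.area_px)
    solidity = min(region.area_px / hull_area_px, 1.0 + ShapeMetrics._EPS_PX)
    perimeter_px = _trace_perimeter(region.mask())
    return ShapeMetrics(
        area=area,
        ecd=ecd,
        d_min=d_min_px * pixel_size,
        d_max=d_max_px * pixel_size,
        aspect_ratio=d_min_px / d_max_px,
        hull_area=hull_area_px * pixel_size * pixel_size,
        solidity=solidity,
        perimeter=perimeter_px * pixel_size,
        touches_border=region.touches_border,
        label=region.label,
    )


def filter_by_ecd(metrics: Iterable[ShapeMetrics], min_ecd: float = 0.5) -> list[ShapeMetrics]:
    """Keep particles with ECD strictly greater than ``min_ecd`` (μm)."""
    return [m for m in metrics if m.ecd > min_ecd]


# ---------------------------------------------------------------------------
# summaries


def summarize_tukey(values: Sequence[float]) -> TukeySummary:
    """Tukey box-plot summary: hinges at Q1/Q3, whiskers at 1.5 x IQR."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear (type-7) interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return TukeySummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(x) for x in np.sort(outliers)),
        n=int(arr.size),
    )


def measure_image(
    image: ParticleImage,
    params: SegmentationParams,
    min_ecd: float = 0.5,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Segment, measure and filter a whole image; one row per particle."""
    regions = segment_particles(image, params)
    metrics = [shape_metrics(r, image.pixel_size) for r in regions]
    metrics = filter_by_ecd(metrics, min_ecd)
    rows = [
        {
            "id": m.label,
            "area_um2": m.area,
            "ecd_um": m.ecd,
            "dmin_um": m.d_min,
            "dmax_um": m.d_max,
            "aspect_ratio": m.aspect_ratio,
            "solidity": m.solidity,
            "perimeter_um": m.perimeter,
            "border_flag": m.touches_border,
        }
        for m in metrics
        if not (exclude_border and m.touches_border)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "area_um2",
            "ecd_um",
            "dmin_um",
            "dmax_um",
            "aspect_ratio",
            "solidity",
            "perimeter_um",
            "border_flag",
        ],
    )


def summarize_morphometry(per_particle: pd.DataFrame) -> pd.DataFrame:
    """Tukey summaries of aspect ratio and solidity (plus ECD) per image."""
    rows = []
    for metric in ("aspect_ratio", "solidity", "ecd_um"):
        if metric not in per_particle or per_particle[metric].empty:
            continue
        s = summarize_tukey(per_particle[metric].to_numpy())
        rows.append(
            {
                "metric": metric,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": len(s.outliers),
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def load_particle_image(path: str | Path, pixel_size: float) -> ParticleImage:
    """Read a grayscale TIFF/PNG into a calibrated :class:`ParticleImage`."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(f"non-grayscale input: {Path(path).name}")
    return ParticleImage(raster=arr, pixel_size=pixel_size)
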