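"""Synthetic scenes, silhouettes and series with analytic ground truth.

Every analysis module in this package can be exercised without any
instrument data: this module generates

* multi-phase EDS scenes — geometric regions with per-element mean
  intensities plus Gaussian noise, with a pixel-exact truth label map;
* particle silhouettes (disk, ellipse, rectangle, plus-sign, star) with
  closed-form area, Feret diameters, aspect ratio and solidity where
  those exist, rasterized by 4x supersampled area coverage;
* lognormal binned size distributions whose volume-basis D50 equals the
  generating geometric mean;
* linear reagent-depletion time series with optional Gaussian noise.

All generators are pure functions of (spec, seed): the same inputs give
byte-identical outputs.  The synthetic data emulate the *geometry* and
*noise level* of real acquisitions, not the physics (no X-ray spectral
overlap, no optical diffraction model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assay import DepletionSeries
from .morphometry import ParticleImage
from .phasemap import ElementMapStack, PhaseDefinition, PhaseMap, assemble_phase_map, PhaseMask
from .psd import BinnedPSD

__all__ = [
    "PhaseRegion",
    "SceneSpec",
    "Primitive",
    "ShapeSpec",
    "make_element_stack",
    "make_shape_image",
    "make_lognormal_psd",
    "make_depletion_series",
    "default_palette",
]

_PALETTE = (
    (230, 60, 60),
    (60, 130, 230),
    (70, 190, 90),
    (240, 180, 40),
    (170, 80, 200),
    (90, 200, 200),
    (240, 120, 180),
    (150, 150, 60),
)


def default_palette(n: int) -> list[tuple[int, int, int]]:
    """Distinct RGB triples for up to ``len(_PALETTE)`` phases (cycled beyond)."""
    return [_PALETTE[i % len(_PALETTE)] for i in range(n)]


# ---------------------------------------------------------------------------
# EDS scenes


@dataclass(frozen=True)
class PhaseRegion:
    """A geometric region with an element intensity signature.

    ``geometry`` is ``("rect", r0, c0, r1, c1)`` (half-open pixel rows/cols)
    or ``("disk", r, c, radius)`` in pixel units.
    """

    name: str
    signature: Mapping[str, float]  # element -> mean intensity inside
    geometry: tuple

    def __post_init__(self) -> None:
        if not self.signature:
            raise ValueError(f"region {self.name!r}: empty element signature")
        if any(v < 0 for v in self.signature.values()):
            raise ValueError(f"region {self.name!r}: signatures must be non-negative")
        object.__setattr__(self, "signature", dict(self.signature))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        kind = self.geometry[0]
        out = np.zeros(shape, dtype=bool)
        if kind == "rect":
            _, r0, c0, r1, c1 = self.geometry
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise ValueError(f"region {self.name!r} lies outside the canvas")
            out[r0:r1, c0:c1] = True
        elif kind == "disk":
            _, r, c, radius = self.geometry
            if r - radius < 0 or c - radius < 0 or r + radius > shape[0] or c + radius > shape[1]:
                raise ValueError(f"region {self.name!r} lies outside the canvas")
            rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
            out = (rr + 0.5 - r) ** 2 + (cc + 0.5 - c) ** 2 <= radius**2
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")
        return out


@dataclass(frozen=True)
class SceneSpec:
    """A synthetic multi-phase EDS scene."""

    shape: tuple[int, int]
    regions: Sequence[PhaseRegion]
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    pixel_size: float | None = None


def make_element_stack(spec: SceneSpec) -> tuple[ElementMapStack, PhaseMap]:
    """Render a scene to per-element rasters plus the truth phase map.

    Region signatures are painted on a uniform background and Gaussian
    noise of ``noise_sd`` is added (clipped at zero to keep intensities
    valid).  Overlapping regions are rejected: the truth labeling would
    be ambiguous without an explicit precedence.
    """
    shape = spec.shape
    masks = [(reg, reg.mask(shape)) for reg in spec.regions]
    occupancy = np.zeros(shape, dtype=int)
    for _, m in masks:
        occupancy += m
    if occupancy.max() > 1:
        raise ValueError("overlapping regions without an explicit precedence")

    elements = sorted({el for reg in spec.regions for el in reg.signature})
    rng = np.random.default_rng(spec.seed)
    maps = {}
    for el in elements:
        raster = np.full(shape, float(spec.background))
        for reg, m in masks:
            if el in reg.signature:
                raster[m] = reg.signature[el]
        if spec.noise_sd > 0:
            raster = raster + rng.normal(0.0, spec.noise_sd, size=shape)
        maps[el] = np.clip(raster, 0.0, None)
    stack = ElementMapStack(maps=maps, pixel_size=spec.pixel_size, sample_id="synthetic")

    colors = default_palette(len(spec.regions))
    defs = [
        PhaseDefinition(
            name=reg.name,
            elements=frozenset(reg.signature),
            threshold=0.0,
            denoise_radius=0,
            color=colors[i],
        )
        for i, reg in enumerate(spec.regions)
    ]
    truth_masks = [PhaseMask(phase_name=reg.name, mask=m) for reg, m in masks]
    truth = assemble_phase_map(truth_masks, defs, pixel_size=spec.pixel_size, sample_id="truth")
    return stack, truth


# ---------------------------------------------------------------------------
# particle silhouettes


@dataclass(frozen=True)
class Primitive:
    """One particle silhouette with analytic truth where closed forms exist.

    Kinds and parameters (lengths in pixels, angles in radians):
    ``disk(r)``, ``ellipse(a, b, theta)`` (semi-axes), ``rect(w, h, theta)``,
    ``plus(arm)`` (five ``arm x arm`` squares), ``star(k, r_in, r_out)``.
    """

    kind: str
    center: tuple[float, float]  # (x, y) pixel coordinates
    params: tuple

    def _inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        dx, dy = x - cx, y - cy
        if self.kind == "disk":
            (r,) = self.params
            return dx**2 + dy**2 <= r**2
        if self.kind == "ellipse":
            a, b, theta = self.params
            u = dx * math.cos(theta) + dy * math.sin(theta)
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            return (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if self.kind == "rect":
            w, h, theta = self.params
            u = dx * math.cos(theta) + dy * math.sin(theta)
            v = -dx * math.sin(theta) + dy * math.cos(theta)
            return (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
        if self.kind == "plus":
            # five arm x arm squares: horizontal bar 3 arm x arm, vertical likewise
            (arm,) = self.params
            h = arm / 2.0
            in_h = (np.abs(dx) <= 1.5 * arm) & (np.abs(dy) <= h)
            in_v = (np.abs(dy) <= 1.5 * arm) & (np.abs(dx) <= h)
            return in_h | in_v
        if self.kind == "star":
            k, r_in, r_out = self.params
            ang = np.arctan2(dy, dx)
            radius = np.sqrt(dx**2 + dy**2)
            # piecewise-linear star boundary between alternating outer/inner tips
            phase = (ang % (2 * math.pi)) * k / (2 * math.pi)
            frac = np.abs((phase % 1.0) - 0.5) * 2.0  # 1 at outer tip, 0 at inner
            return radius <= r_in + (r_out - r_in) * frac
        raise ValueError(f"unknown primitive kind {self.kind!r}")

    def truth(self, pixel_size: float) -> dict[str, float | None]:
        """Analytic area / Feret / aspect-ratio / solidity where closed-form."""
        s = pixel_size
        if self.kind == "disk":
            (r,) = self.params
            return {
                "area": math.pi * r * r * s * s,
                "d_min": 2 * r * s,
                "d_max": 2 * r * s,
                "aspect_ratio": 1.0,
                "solidity": 1.0,
            }
        if self.kind == "ellipse":
            a, b, _ = self.params
            lo, hi = min(a, b), max(a, b)
            return {
                "area": math.pi * a * b * s * s,
                "d_min": 2 * lo * s,
                "d_max": 2 * hi * s,
                "aspect_ratio": lo / hi,
                "solidity": 1.0,
            }
        if self.kind == "rect":
            w, h, _ = self.params
            return {
                "area": w * h * s * s,
                "d_min": min(w, h) * s,
                "d_max": math.hypot(w, h) * s,
                "aspect_ratio": min(w, h) / math.hypot(w, h),
                "solidity": 1.0,
            }
        if self.kind == "plus":
            (arm,) = self.params
            # five arm x arm squares; hull is the octagon of area 7 arm².
            # Caliper width is smallest across the octagon's diagonal edges
            # (2*sqrt(2) arm) and largest between opposite tips (sqrt(10) arm).
            return {
                "area": 5 * arm * arm * s * s,
                "d_min": 2 * math.sqrt(2) * arm * s,
                "d_max": math.sqrt(10) * arm * s,
                "aspect_ratio": math.sqrt(8.0 / 10.0),
                "solidity": 5.0 / 7.0,
            }
        k, r_in, r_out = self.params
        return {
            "area": None,
            "d_min": None,
            "d_max": 2 * r_out * s if k % 2 == 0 else None,
            "aspect_ratio": None,
            "solidity": None,
        }


@dataclass(frozen=True)
class ShapeSpec:
    """A canvas of non-overlapping particle silhouettes."""

    shape: tuple[int, int]
    primitives: Sequence[Primitive]
    pixel_size: float = 1.0
    foreground: float = 200.0
    background: float = 20.0
    supersample: int = 4


def make_shape_image(spec: ShapeSpec) -> tuple[ParticleImage, list[dict]]:
    """Rasterize silhouettes (supersampled area coverage >= 50%) plus truth.

    Returns the grayscale image (particles bright) and one truth record per
    primitive: its analytic metrics and its rasterized pixel count.
    """
    h, w = spec.shape
    n = spec.supersample
    # subpixel sample points at cell centers of an n x n grid per pixel
    offs = (np.arange(n) + 0.5) / n
    ys = (np.arange(h)[:, None] + offs[None, :]).ravel()
    xs = (np.arange(w)[:, None] + offs[None, :]).ravel()
    X, Y = np.meshgrid(xs, ys)

    raster = np.full((h, w), float(spec.background))
    truth: list[dict] = []
    occupancy = np.zeros((h, w), dtype=int)
    for prim in spec.primitives:
        inside = prim._inside(X, Y)
        coverage = inside.reshape(h, n, w, n).mean(axis=(1, 3))
        mask = coverage >= 0.5
        if not mask.any():
            raise ValueError(f"primitive {prim.kind} rasterizes to nothing")
        edge = np.zeros((h, w), dtype=bool)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        if (mask & edge).any():
            raise ValueError(f"primitive {prim.kind} extends outside the canvas")
        occupancy += mask
        raster[mask] = spec.foreground
        rec = prim.truth(spec.pixel_size)
        rec.update(kind=prim.kind, center=prim.center, area_px=int(mask.sum()))
        truth.append(rec)
    if occupancy.max() > 1:
        raise ValueError("primitives overlap")
    return ParticleImage(raster=raster, pixel_size=spec.pixel_size), truth


# ---------------------------------------------------------------------------
# size distributions


def make_lognormal_psd(
    geometric_mean: float,
    gsd: float,
    n_bins: int = 64,
    d_range: tuple[float, float] | None = None,
    basis: str = "volume",
) -> BinnedPSD:
    """Binned lognormal distribution on a log-spaced grid.

    The bin fractions are CDF differences of a lognormal with median
    ``geometric_mean`` (μm) and geometric standard deviation ``gsd``, so
    the truth D50 on the generated basis equals ``geometric_mean``.
    Truncation beyond the grid (kept < 1% by the default +/- 4 log-sigma
    range) is renormalized away.
    """
    if gsd <= 1:
        raise ValueError("gsd must be > 1")
    sigma = math.log(gsd)
    if d_range is None:
        d_range = (geometric_mean * math.exp(-4 * sigma), geometric_mean * math.exp(4 * sigma))
    edges = np.geomspace(d_range[0], d_range[1], n_bins + 1)
    dist = stats.lognorm(s=sigma, scale=geometric_mean)
    cdf = dist.cdf(edges)
    captured = cdf[-1] - cdf[0]
    if captured < 0.99:
        import warnings

        warnings.warn(f"size range truncates {100 * (1 - captured):.1f}% of the mass")
    fracs = np.diff(cdf)
    return BinnedPSD(bin_edges=edges, fractions=fracs / fracs.sum(), basis=basis)


# ---------------------------------------------------------------------------
# depletion series


def make_depletion_series(
    a0: float,
    rate: float,
    times: Sequence[float] = (0.0, 15.0, 30.0),
    sd: float = 0.0,
    seed: int = 0,
    reagent: str = "DTT",
    well_mass: float = 2.0,
) -> DepletionSeries:
    """Linear depletion ``a0 - rate * t`` with optional Gaussian noise.

    The noise-free trajectory must stay non-negative over the time grid
    (i.e. ``a0 > rate * max(times)``); noisy draws are clipped at zero.
    """
    t = np.asarray(times, dtype=float)
    if a0 <= rate * t.max():
        raise ValueError("a0 must exceed rate * max(time): amounts would go negative")
    amounts = a0 - rate * t
    if sd > 0:
        rng = np.random.default_rng(seed)
        amounts = np.clip(amounts + rng.normal(0.0, sd, size=t.shape), 0.0, None)
    return DepletionSeries(times=t, amounts=amounts, reagent=reagent, well_mass=well_mass)
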