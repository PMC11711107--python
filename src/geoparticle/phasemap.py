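"""SEM-EDS phase mapping.

A scanning electron microscope fitted with an EDS detector produces one
grayscale intensity map per chemical element over the same field of view.
A mineral *phase* (quartz, feldspar, calcite, volcanic glass, ...) lights
up in a characteristic combination of those element maps.  This module
turns a stack of co-registered element maps into a labeled phase map and
a table of phase area fractions:

1. the element maps selected for a phase are *flattened* into one image
   by taking the per-pixel median across the selected maps;
2. a binary threshold plus a despeckling (binary median) filter turns the
   flattened image into a phase mask;
3. the masks are painted onto a composite in order of **descending** mask
   area, so that where masks overlap the smallest claimant phase wins —
   large phases cannot mask small ones;
4. area fractions are measured on the final labels, conserving
   phase % + unassigned % = 100.

Phase recipes (element sets, thresholds, denoise radii, colors) are
declarative — a YAML file or `PhaseDefinition` objects — so a mapping is
fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

__all__ = [
    "ElementMapStack",
    "PhaseDefinition",
    "PhaseMask",
    "PhaseMap",
    "PhaseProportionTable",
    "AnalystComparison",
    "UNASSIGNED",
    "load_element_maps",
    "load_recipe",
    "load_presets",
    "flatten_median",
    "make_phase_mask",
    "assemble_phase_map",
    "map_phases",
    "measure_area_fractions",
    "compare_analysts",
    "render_legend",
]

#: Label value reserved for pixels claimed by no phase.
UNASSIGNED = 0


@dataclass(frozen=True)
class ElementMapStack:
    """Co-registered per-element grayscale rasters.

    Parameters
    ----------
    maps
        Mapping from element symbol (e.g. ``"Si"``) to a 2-D array of
        non-negative intensities.  All rasters must share one shape.
    pixel_size
        Physical edge length of one pixel in μm, if the maps are
        calibrated.
    sample_id
        Free-text identifier carried through to output tables.
    """

    maps: Mapping[str, np.ndarray]
    pixel_size: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("no element maps found: a stack needs at least one element")
        shapes = {np.asarray(m).shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError(f"dimension mismatch among element maps: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("element maps must be 2-D single-channel rasters")
        clean = {}
        for sym, m in self.maps.items():
            arr = np.asarray(m, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite intensities in element map {sym!r}")
            if arr.min() < 0:
                raise ValueError(f"negative intensities in element map {sym!r}")
            clean[sym] = arr
        object.__setattr__(self, "maps", clean)
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    @property
    def elements(self) -> set[str]:
        return set(self.maps)


@dataclass(frozen=True)
class PhaseDefinition:
    """Recipe for one phase: which element maps, threshold, despeckle, color."""

    name: str
    elements: frozenset[str]
    threshold: float
    denoise_radius: int = 1
    color: tuple[int, int, int] = (255, 255, 255)
    preset: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", frozenset(self.elements))
        if not self.elements:
            raise ValueError(f"phase {self.name!r}: element set is empty")
        if self.threshold < 0:
            raise ValueError(f"phase {self.name!r}: threshold must be >= 0")
        if self.denoise_radius < 0:
            raise ValueError(f"phase {self.name!r}: denoise_radius must be >= 0")
        color = tuple(int(c) for c in self.color)
        if len(color) != 3 or any(c < 0 or c > 255 for c in color):
            raise ValueError(f"phase {self.name!r}: color must be an RGB triple in 0..255")
        object.__setattr__(self, "color", color)


@dataclass(frozen=True)
class PhaseMask:
    """Binary mask for one phase, before composite assembly."""

    phase_name: str
    mask: np.ndarray
    area_px: int = field(init=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "area_px", int(mask.sum()))


@dataclass(frozen=True)
class PhaseMap:
    """Composite labeled raster plus its legend.

    ``labels`` holds :data:`UNASSIGNED` (0) for unclaimed pixels and
    ``1..n`` for phases; ``legend[i]`` describes label ``i + 1`` and is
    ordered by descending area fraction.  Legend rows are
    ``(name, elements, color, area_pct)``.
    """

    labels: np.ndarray
    legend: tuple[tuple[str, frozenset[str], tuple[int, int, int], float], ...]
    pixel_size: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        n = len(self.legend)
        if labels.size and (labels.min() < 0 or labels.max() > n):
            raise ValueError("labels contain values outside 0..n_phases")
        total = sum(row[3] for row in self.legend) + self.unassigned_pct
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"area fractions sum to {total}, not 100 +/- 0.01")

    @property
    def unassigned_pct(self) -> float:
        labels = self.labels
        return 100.0 * float(np.count_nonzero(labels == UNASSIGNED)) / labels.size

    @property
    def phase_names(self) -> tuple[str, ...]:
        return tuple(row[0] for row in self.legend)


@dataclass(frozen=True)
class PhaseProportionTable:
    """Per-phase area percentages of a mapped scene.

    ``rows`` are percentages of the full frame (so they sum with
    ``unassigned_pct`` to 100); ``rows_of_quantified`` renormalizes to the
    assigned (particle) area only, when any pixel is assigned.
    """

    rows: Mapping[str, float]
    unassigned_pct: float
    total_area_quantified: float
    area_unit: str  # "um2" or "px"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rows.values()):
            raise ValueError("area percentages must be >= 0")
        total = sum(self.rows.values()) + self.unassigned_pct
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"area fractions sum to {total}, not 100 +/- 0.01")
        object.__setattr__(self, "rows", dict(self.rows))

    @property
    def rows_of_quantified(self) -> dict[str, float]:
        assigned = sum(self.rows.values())
        if assigned == 0:
            return {name: 0.0 for name in self.rows}
        return {name: 100.0 * pct / assigned for name, pct in self.rows.items()}

    def to_frame(self) -> pd.DataFrame:
        quant = self.rows_of_quantified
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "phase": list(self.rows),
                "area_pct": list(self.rows.values()),
                "area_pct_of_quantified": [quant[p] for p in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample": self.sample_id,
            "rows": self.rows,
            "rows_of_quantified": self.rows_of_quantified,
            "unassigned_pct": self.unassigned_pct,
            "total_area_quantified": self.total_area_quantified,
            "area_unit": self.area_unit,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str = "") -> "PhaseProportionTable":
        df = pd.read_csv(path)
        rows = dict(zip(df["phase"], df["area_pct"].astype(float)))
        unassigned = 100.0 - sum(rows.values())
        return cls(
            rows=rows,
            unassigned_pct=max(unassigned, 0.0),
            total_area_quantified=float("nan"),
            area_unit="px",
            sample_id=sample_id or (str(df["sample"].iloc[0]) if "sample" in df and len(df) else ""),
        )


@dataclass(frozen=True)
class AnalystComparison:
    """Per-phase absolute differences between two analysts' proportion tables."""

    per_phase_abs_diff: Mapping[str, float]
    phases_only_in_one: frozenset[str]

    @property
    def max_diff(self) -> float:
        return max(self.per_phase_abs_diff.values(), default=0.0)


# ---------------------------------------------------------------------------
# operations


def load_element_maps(
    source: str | Path | Sequence[str | Path],
    pixel_size: float | None = None,
    sample_id: str = "",
) -> ElementMapStack:
    """Read per-element rasters into a stack.

    ``source`` is a directory or an explicit list of files; each file must
    be a single-channel TIFF/PNG whose stem is the element symbol
    (``Si.tif`` → ``Si``).
    """
    import imageio.v3 as iio

    if isinstance(source, (str, Path)):
        directory = Path(source)
        if not directory.is_dir():
            raise FileNotFoundError(f"missing file or directory: {directory}")
        files = sorted(
            p for p in directory.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
    else:
        files = [Path(p) for p in source]
        for p in files:
            if not p.exists():
                raise FileNotFoundError(f"missing file: {p}")
    if not files:
        raise ValueError("no element maps found")

    maps: dict[str, np.ndarray] = {}
    for p in files:
        arr = np.asarray(iio.imread(p))
        if arr.ndim == 3:
            if arr.shape[2] == 1:
                arr = arr[..., 0]
            else:
                raise ValueError(f"non-grayscale input: {p.name} has {arr.shape[2]} channels")
        maps[p.stem] = arr
    return ElementMapStack(maps=maps, pixel_size=pixel_size, sample_id=sample_id or "")


def load_recipe(path: str | Path) -> list[PhaseDefinition]:
    """Load phase definitions from a YAML recipe.

    Layout::

        phases:
          quartz: {elements: [Si], threshold: 120, denoise_radius: 1, color: [230, 60, 60]}
          calcite: {elements: [Ca], threshold: 110, color: [60, 60, 230]}
    """
    doc = yaml.safe_load(Path(path).read_text())
    phases = doc.get("phases", doc)
    defs = []
    for name, spec in phases.items():
        defs.append(
            PhaseDefinition(
                name=str(name),
                elements=frozenset(spec["elements"]),
                threshold=float(spec["threshold"]),
                denoise_radius=int(spec.get("denoise_radius", 1)),
                color=tuple(spec.get("color", (255, 255, 255))),
                preset=spec.get("preset"),
            )
        )
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("phase names must be unique within a recipe")
    return defs


def load_presets() -> dict[str, list[str]]:
    """Named element-set presets for common phases (editable package data)."""
    text = resources.files("geoparticle.data").joinpath("phase_presets.yaml").read_text()
    return {k: list(v) for k, v in yaml.safe_load(text).items()}


def flatten_median(stack: ElementMapStack, elements: Iterable[str]) -> np.ndarray:
    """Collapse the selected element maps to one image by per-pixel median."""
    elements = sorted(set(elements))
    if not elements:
        raise ValueError("no elements selected for flattening")
    unknown = [e for e in elements if e not in stack.maps]
    if unknown:
        raise KeyError(f"unknown element symbol(s): {', '.join(unknown)}")
    sub = np.stack([stack.maps[e] for e in elements], axis=0)
    return np.median(sub, axis=0)


def make_phase_mask(flat: np.ndarray, definition: PhaseDefinition) -> PhaseMask:
    """Threshold a flattened image (inclusive ``>=``) and despeckle it.

    Despeckling is a binary median filter over a ``(2r+1) x (2r+1)``
    square neighborhood with reflect padding; radius 0 is the identity.
    """
    flat = np.asarray(flat, dtype=float)
    if not np.all(np.isfinite(flat)):
        raise ValueError("flattened image contains non-finite values")
    mask = flat >= definition.threshold
    r = definition.denoise_radius
    if r > 0:
        size = 2 * r + 1
        mask = ndimage.median_filter(mask.astype(np.uint8), size=size, mode="reflect") > 0
    return PhaseMask(phase_name=definition.name, mask=mask)


def _painting_order(masks: Sequence[PhaseMask]) -> list[PhaseMask]:
    # Descending area, name tiebreak: painted later = smaller = wins overlaps.
    return sorted(masks, key=lambda m: (-m.area_px, m.phase_name))


def assemble_phase_map(
    masks: Sequence[PhaseMask],
    definitions: Sequence[PhaseDefinition],
    pixel_size: float | None = None,
    sample_id: str = "",
) -> PhaseMap:
    """Paint phase masks onto a composite, smaller phases overwriting larger.

    Painting proceeds in strictly descending mask-area order (ties broken
    lexicographically by phase name), so a pixel claimed by several phases
    ends up labeled with its smallest-area claimant.  The legend is built
    from the *final* labels and ordered by descending area fraction.
    """
    by_name = {d.name: d for d in definitions}
    if len(by_name) != len(definitions):
        raise ValueError("phase names must be unique")
    if set(by_name) != {m.phase_name for m in masks}:
        raise ValueError("masks and definitions must cover the same phase names")
    shapes = {m.mask.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"dimension mismatch among masks: {sorted(shapes)}")

    ordered = _painting_order(masks)
    shape = ordered[0].mask.shape
    labels = np.full(shape, UNASSIGNED, dtype=np.int32)
    paint_index = {m.phase_name: i + 1 for i, m in enumerate(ordered)}
    for m in ordered:
        labels[m.mask] = paint_index[m.phase_name]

    total_px = labels.size
    final_area = {
        m.phase_name: int(np.count_nonzero(labels == paint_index[m.phase_name])) for m in ordered
    }
    # Legend (and label values) ordered by descending final area fraction.
    display = sorted(ordered, key=lambda m: (-final_area[m.phase_name], m.phase_name))
    relabel = np.zeros(len(ordered) + 1, dtype=np.int32)
    for new_i, m in enumerate(display, start=1):
        relabel[paint_index[m.phase_name]] = new_i
    labels = relabel[labels]
    legend = tuple(
        (
            m.phase_name,
            by_name[m.phase_name].elements,
            by_name[m.phase_name].color,
            100.0 * final_area[m.phase_name] / total_px,
        )
        for m in display
    )
    return PhaseMap(labels=labels, legend=legend, pixel_size=pixel_size, sample_id=sample_id)


def map_phases(
    stack: ElementMapStack, definitions: Sequence[PhaseDefinition], sample_id: str | None = None
) -> PhaseMap:
    """Full pipeline: flatten, threshold/despeckle and assemble every phase."""
    masks = [make_phase_mask(flatten_median(stack, d.elements), d) for d in definitions]
    return assemble_phase_map(
        masks,
        definitions,
        pixel_size=stack.pixel_size,
        sample_id=stack.sample_id if sample_id is None else sample_id,
    )


def measure_area_fractions(
    phase_map: PhaseMap, pixel_size: float | None = None
) -> PhaseProportionTable:
    """Tabulate per-phase area percentages from a composite phase map."""
    labels = phase_map.labels
    total_px = labels.size
    rows = {row[0]: 100.0 * float(np.count_nonzero(labels == i + 1)) / total_px
            for i, row in enumerate(phase_map.legend)}
    px = pixel_size if pixel_size is not None else phase_map.pixel_size
    if px is not None:
        total_area = total_px * px * px
        unit = "um2"
    else:
        total_area = float(total_px)
        unit = "px"
    return PhaseProportionTable(
        rows=rows,
        unassigned_pct=phase_map.unassigned_pct,
        total_area_quantified=total_area,
        area_unit=unit,
        sample_id=phase_map.sample_id,
    )


def compare_analysts(a: PhaseProportionTable, b: PhaseProportionTable) -> AnalystComparison:
    """Quantify inter-analyst error as |Δ area %| per shared phase."""
    shared = set(a.rows) & set(b.rows)
    only_one = set(a.rows) ^ set(b.rows)
    diffs = {name: abs(a.rows[name] - b.rows[name]) for name in sorted(shared)}
    return AnalystComparison(per_phase_abs_diff=diffs, phases_only_in_one=frozenset(only_one))


def phase_map_to_rgb(phase_map: PhaseMap, background: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Colorize the label raster using the legend's RGB triples (bit-exact)."""
    palette = np.zeros((len(phase_map.legend) + 1, 3), dtype=np.uint8)
    palette[0] = background
    for i, (_, _, color, _) in enumerate(phase_map.legend, start=1):
        palette[i] = color
    return palette[phase_map.labels]


def render_legend(phase_map: PhaseMap, out_path: str | Path) -> Path:
    """Write the colorized phase map with a legend panel to a PNG.

    Legend rows are ordered by descending area fraction; swatch colors
    match the phase definitions bit-exactly.  Rendering is deterministic:
    identical maps produce byte-identical files.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    out_path = Path(out_path)
    rgb = phase_map_to_rgb(phase_map)
    fig, (ax_img, ax_leg) = plt.subplots(
        1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [2, 1]}
    )
    ax_img.imshow(rgb, interpolation="nearest")
    ax_img.set_axis_off()
    handles = [
        Patch(
            facecolor=np.array(color) / 255.0,
            label=f"{name} ({'+'.join(sorted(elements))}): {pct:.1f}%",
        )
        for name, elements, color, pct in phase_map.legend
    ]
    handles.append(Patch(facecolor="black", label=f"unassigned: {phase_map.unassigned_pct:.1f}%"))
    ax_leg.legend(handles=handles, loc="center left", frameon=False)
    ax_leg.set_axis_off()
    fig.savefig(out_path, dpi=100, metadata={"Software": "geoparticle"})
    plt.close(fig)
    return out_path
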