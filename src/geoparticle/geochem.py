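"""Bulk oxide-composition bookkeeping and TAS classification.

Whole-rock major-element analyses report oxide weight percentages
(SiO2, Al2O3, Fe2O3, ...) plus loss on ignition (LOI) at 110°C (adsorbed
water) and 1000°C (structural volatiles and carbonate CO2).  The helpers
here compute analytical totals, total alkali (Na2O + K2O), and classify
volcanic compositions on the total-alkali–silica (TAS) diagram of
Le Bas et al., whose field polygons ship as editable package data.

Boundary points are assigned deterministically to the lower-alkali /
lower-silica neighbouring field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

__all__ = [
    "OxideComposition",
    "MAJOR_OXIDES",
    "total",
    "total_alkali",
    "tas_classify",
    "tas_fields",
    "read_oxide_csv",
    "classify_table",
]

MAJOR_OXIDES = (
    "SiO2",
    "Al2O3",
    "Fe2O3",
    "MgO",
    "CaO",
    "Na2O",
    "K2O",
    "TiO2",
    "MnO",
    "P2O5",
    "Other",
)


@dataclass(frozen=True)
class OxideComposition:
    """One sample's oxide wt.% values plus loss on ignition."""

    oxides: Mapping[str, float]
    loi_110: float = 0.0
    loi_1000: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name, value in self.oxides.items():
            if value < 0 or value >= 100:
                raise ValueError(f"{name} = {value} wt.% outside [0, 100)")
        for name, value in (("loi_110", self.loi_110), ("loi_1000", self.loi_1000)):
            if value < 0 or value >= 100:
                raise ValueError(f"{name} = {value} wt.% outside [0, 100)")
        object.__setattr__(self, "oxides", dict(self.oxides))

    def __getitem__(self, oxide: str) -> float:
        return self.oxides.get(oxide, 0.0)


def total(comp: OxideComposition) -> float:
    """Analytical total: Σ oxides + LOI(110) + LOI(1000), to one decimal."""
    return round(sum(comp.oxides.values()) + comp.loi_110 + comp.loi_1000, 1)


def total_alkali(comp: OxideComposition) -> float:
    """Total alkali Na2O + K2O (wt.%), the TAS ordinate."""
    return comp["Na2O"] + comp["K2O"]


@lru_cache(maxsize=1)
def tas_fields() -> dict[str, Polygon]:
    """TAS field polygons keyed by rock name, from package data."""
    text = resources.files("geoparticle.data").joinpath("tas_fields.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: Polygon(vertices) for name, vertices in raw.items()}


def tas_classify(sio2: float, alkali: float) -> str:
    """Name the TAS field containing (SiO2, Na2O+K2O) in wt.%.

    Points on a shared boundary go to the field whose centroid has the
    lower alkali, then lower silica (a fixed, documented tie rule);
    points inside no shipped field return ``"unclassified"``.
    """
    for value, name in ((sio2, "SiO2"), (alkali, "total alkali")):
        if value < 0 or value >= 100:
            raise ValueError(f"{name} = {value} wt.% outside [0, 100)")
    point = Point(sio2, alkali)
    fields = tas_fields()
    order = sorted(fields, key=lambda n: (fields[n].centroid.y, fields[n].centroid.x))
    for name in order:
        if fields[name].covers(point):
            return name
    return "unclassified"


def classify(comp: OxideComposition) -> str:
    return tas_classify(comp["SiO2"], total_alkali(comp))


# ---------------------------------------------------------------------------
# tabular interface


def read_oxide_csv(path: str | Path) -> list[OxideComposition]:
    """Read one sample per row; columns = sample, oxides..., LOI110, LOI1000."""
    df = pd.read_csv(path)
    comps = []
    for _, row in df.iterrows():
        oxides = {ox: float(row[ox]) for ox in MAJOR_OXIDES if ox in row and pd.notna(row[ox])}
        comps.append(
            OxideComposition(
                oxides=oxides,
                loi_110=float(row.get("LOI110", 0.0)),
                loi_1000=float(row.get("LOI1000", 0.0)),
                sample_id=str(row.get("sample", "")),
            )
        )
    return comps


def classify_table(comps: list[OxideComposition]) -> pd.DataFrame:
    """Totals, total alkali and TAS class for a batch of samples."""
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in comps],
            "SiO2": [c["SiO2"] for c in comps],
            "total_alkali": [round(total_alkali(c), 2) for c in comps],
            "total": [total(c) for c in comps],
            "tas_class": [classify(c) for c in comps],
        }
    )
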