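"""Binned particle-size-distribution metrics.

Laser-diffraction sizing exports a binned distribution of particle
diameter, usually on a volume (mass) basis.  This module computes the
standard summary metrics on either basis:

* the median diameter D50, located by linear interpolation of the
  cumulative fraction against log10(diameter);
* sub-cutoff fractions (e.g. % of particles finer than 10, 4, 2.5 and
  1 μm — the respirable and fine fractions);
* volume <-> number basis conversion under the sphere assumption
  (number weight per bin proportional to volume fraction / d̄³, with d̄
  the geometric mean of the bin edges).

Because a few large particles dominate the volume but few of the counts,
the number-basis D50 of any polydisperse sample sits below its
volume-basis D50.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinnedPSD",
    "PSDMetrics",
    "volume_to_number",
    "number_to_volume",
    "median_diameter",
    "fraction_below",
    "metrics_table",
    "read_psd_csv",
    "write_psd_csv",
    "DEFAULT_CUTOFFS",
]

#: Cutoffs (μm) reported by default: thoracic (10), respirable-fine (4),
#: fine (2.5) and submicron (1) conventions.
DEFAULT_CUTOFFS = (10.0, 4.0, 2.5, 1.0)


@dataclass(frozen=True)
class BinnedPSD:
    """A binned size distribution: n+1 edges (μm), n fractions summing to 1."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    basis: str  # "volume" | "number"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        fracs = np.asarray(self.fractions, dtype=float)
        if self.basis not in ("volume", "number"):
            raise ValueError("basis must be 'volume' or 'number'")
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("need at least two bin edges")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be positive and strictly increasing")
        if len(fracs) != len(edges) - 1:
            raise ValueError("need exactly one fraction per bin")
        if np.any(fracs < 0):
            raise ValueError("fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {fracs.sum()}, not 1 +/- 1e-9")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "fractions", fracs)

    @property
    def geometric_midpoints(self) -> np.ndarray:
        """Representative bin diameters: geometric mean of the edges."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class PSDMetrics:
    d50: float
    frac_below: dict[float, float]  # cutoff μm -> %
    basis: str

    def __post_init__(self) -> None:
        cuts = sorted(self.frac_below)
        vals = [self.frac_below[c] for c in cuts]
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("frac_below must be non-decreasing in the cutoff")


def _basis_convert(psd: BinnedPSD, power: float, new_basis: str) -> BinnedPSD:
    d = psd.geometric_midpoints
    w = psd.fractions * d**power
    total = w.sum()
    if total == 0:
        raise ValueError("distribution has no mass")
    return BinnedPSD(bin_edges=psd.bin_edges, fractions=w / total, basis=new_basis)


def volume_to_number(psd: BinnedPSD) -> BinnedPSD:
    """Convert a volume-basis PSD to number basis (spheres: weight ∝ v/d̄³)."""
    if psd.basis != "volume":
        raise ValueError("volume_to_number expects a volume-basis distribution")
    return _basis_convert(psd, -3.0, "number")


def number_to_volume(psd: BinnedPSD) -> BinnedPSD:
    """Inverse of :func:`volume_to_number` (weight ∝ n·d̄³)."""
    if psd.basis != "number":
        raise ValueError("number_to_volume expects a number-basis distribution")
    return _basis_convert(psd, 3.0, "volume")


def _cumulative_at(psd: BinnedPSD, diameter: float) -> float:
    """Cumulative fraction below ``diameter``, log-linear within the bin."""
    edges = psd.bin_edges
    cum = np.concatenate([[0.0], np.cumsum(psd.fractions)])
    if diameter <= edges[0]:
        return 0.0
    if diameter >= edges[-1]:
        return float(cum[-1])
    return float(np.interp(np.log10(diameter), np.log10(edges), cum))


def fraction_below(psd: BinnedPSD, cutoff: float) -> float:
    """Percent of the distribution finer than ``cutoff`` μm."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return 100.0 * _cumulative_at(psd, cutoff)


def median_diameter(psd: BinnedPSD) -> float:
    """D50: diameter at cumulative fraction 0.5, log-linear interpolation."""
    edges = psd.bin_edges
    cum = np.concatenate([[0.0], np.cumsum(psd.fractions)])
    cum = cum / cum[-1]
    # first edge index with cumulative >= 0.5; interpolate within [i-1, i]
    log_d50 = np.interp(0.5, cum, np.log10(edges))
    return float(10.0**log_d50)


def metrics_table(psd: BinnedPSD, cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS) -> PSDMetrics:
    """D50 plus the sub-cutoff percentages, on the distribution's basis."""
    return PSDMetrics(
        d50=median_diameter(psd),
        frac_below={c: fraction_below(psd, c) for c in cutoffs},
        basis=psd.basis,
    )


def metrics_both_bases(
    psd: BinnedPSD, cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
) -> dict[str, PSDMetrics]:
    """Metrics on the native basis and on the sphere-converted other basis."""
    other = volume_to_number(psd) if psd.basis == "volume" else number_to_volume(psd)
    return {
        psd.basis: metrics_table(psd, cutoffs),
        other.basis: metrics_table(other, cutoffs),
    }


# ---------------------------------------------------------------------------
# CSV interface: `edge_low_um, edge_high_um, fraction` with a `# basis=` header


def read_psd_csv(path: str | Path) -> BinnedPSD:
    text = Path(path).read_text()
    basis = "volume"
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip().lstrip("#").strip()
        if stripped.startswith("basis="):
            basis = stripped.split("=", 1)[1].strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    lows = df["edge_low_um"].to_numpy(float)
    highs = df["edge_high_um"].to_numpy(float)
    if not np.allclose(lows[1:], highs[:-1]):
        raise ValueError("bins must be contiguous (edge_high of one row = edge_low of the next)")
    edges = np.concatenate([lows, highs[-1:]])
    fracs = df["fraction"].to_numpy(float)
    return BinnedPSD(bin_edges=edges, fractions=fracs / fracs.sum(), basis=basis)


def write_psd_csv(psd: BinnedPSD, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "edge_low_um": psd.bin_edges[:-1],
            "edge_high_um": psd.bin_edges[1:],
            "fraction": psd.fractions,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# basis={psd.basis}\n")
        df.to_csv(fh, index=False)


def metrics_to_frame(metrics: dict[str, PSDMetrics]) -> pd.DataFrame:
    """Lay out per-basis metrics one row per basis, cutoffs as columns."""
    rows = []
    for basis, m in metrics.items():
        row: dict[str, float | str] = {"basis": basis, "d50_um": m.d50}
        for cutoff in sorted(m.frac_below, reverse=True):
            row[f"pct_below_{cutoff:g}um"] = m.frac_below[cutoff]
        rows.append(row)
    return pd.DataFrame(rows)
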