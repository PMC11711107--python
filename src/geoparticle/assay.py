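"""Oxidative-potential and exposure-assay arithmetic.

The oxidative potential (OP) of a particulate sample is measured as the
rate at which its extract depletes an antioxidant reagent — dithiothreitol
(DTT) or ascorbic acid (AA) — followed over time in a well plate:

* the depletion rate is minus the OLS slope of remaining reagent amount
  (nmol) against time (min), optionally restricted to the most linear
  contiguous window;
* the mean of laboratory blank rates is subtracted, and the limit of
  detection (LOD) is three times the sample standard deviation (n-1) of
  the blank rates;
* the blank-corrected rate is normalized by the particle mass in the
  well, giving OP in nmol/min/μg.

Also included: reagent-amount bookkeeping (μL x mM = nmol), deposition
dose for air–liquid-interface (ALI) exposures (μg deposited per cm² of
insert growth area), cell seeding density, and protein-normalized
cytokine fold change of treated over untreated cultures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepletionSeries",
    "BlankSet",
    "OPResult",
    "ExposureDose",
    "CytokineMeasurement",
    "depletion_rate",
    "blank_correct",
    "limit_of_detection",
    "mass_normalize",
    "op_result",
    "reagent_amount",
    "deposition_dose",
    "seeding_density",
    "fold_change",
    "process_plate",
]


@dataclass(frozen=True)
class DepletionSeries:
    """Remaining reagent amount (nmol) over reaction time (min) for one well."""

    times: np.ndarray
    amounts: np.ndarray
    reagent: str = "DTT"  # "DTT" | "AA"
    well_mass: float = 2.0  # μg of particles in the well

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amounts, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(a) != len(t):
            raise ValueError("times and amounts must have equal length")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("amounts must be finite and >= 0")
        if self.reagent not in ("DTT", "AA"):
            raise ValueError("reagent must be 'DTT' or 'AA'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amounts", a)


@dataclass(frozen=True)
class BlankSet:
    """Depletion rates (nmol/min) of the laboratory blanks of one plate."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        if len(rates) < 3:
            raise ValueError("a blank set needs at least three blanks")
        object.__setattr__(self, "rates", rates)

    @property
    def mean(self) -> float:
        return float(np.mean(self.rates))

    @property
    def sd(self) -> float:
        return float(np.std(self.rates, ddof=1))


@dataclass(frozen=True)
class OPResult:
    """Fully processed oxidative-potential result for one well."""

    raw_rate: float  # nmol/min
    blank_corrected_rate: float  # nmol/min
    lod: float  # nmol/min
    above_lod: bool
    mass_normalized: float  # nmol/min/μg
    reagent: str = "DTT"
    window: tuple[int, int] | None = None  # index window used for the fit


@dataclass(frozen=True)
class ExposureDose:
    """ALI deposition dose from a pipetted suspension."""

    suspension_conc: float  # μg/mL
    applied_volume: float  # mL
    growth_area: float  # cm²

    def __post_init__(self) -> None:
        if min(self.suspension_conc, self.applied_volume, self.growth_area) <= 0:
            raise ValueError("concentration, volume and area must all be > 0")

    @property
    def areal_dose(self) -> float:
        return self.suspension_conc * self.applied_volume / self.growth_area


@dataclass(frozen=True)
class CytokineMeasurement:
    """One supernatant measurement, normalized to total protein."""

    cytokine_conc: float  # pg/mL
    total_protein: float  # μg/mL
    condition: str = "treated"  # "treated" | "untreated"

    def __post_init__(self) -> None:
        if self.total_protein <= 0:
            raise ValueError("total_protein must be > 0")
        if self.cytokine_conc < 0:
            raise ValueError("cytokine_conc must be >= 0")

    @property
    def normalized(self) -> float:
        """pg cytokine per μg total protein."""
        return self.cytokine_conc / self.total_protein


# ---------------------------------------------------------------------------
# depletion-rate pipeline


def _ols_rate(t: np.ndarray, a: np.ndarray) -> float:
    if np.ptp(t) == 0:
        raise ValueError("zero time variance: cannot fit a slope")
    slope = stats.linregress(t, a).slope
    return -float(slope)


def _best_window(t: np.ndarray, a: np.ndarray, min_points: int = 3) -> tuple[int, int]:
    """Contiguous index window [i, j) of >= min_points maximizing OLS R².

    Ties (within 1e-12) prefer the longer window, then the earlier start,
    so the choice is deterministic.
    """
    n = len(t)
    if n < min_points:
        raise ValueError(f"need at least {min_points} points for automatic windowing")
    best = (0, n)
    best_r2 = -math.inf
    for length in range(min_points, n + 1):
        for start in range(0, n - length + 1):
            seg_t, seg_a = t[start : start + length], a[start : start + length]
            if np.ptp(seg_a) == 0:
                r2 = 1.0  # a perfectly flat segment is perfectly linear
            else:
                r2 = float(stats.linregress(seg_t, seg_a).rvalue ** 2)
            better = r2 > best_r2 + 1e-12
            tie = abs(r2 - best_r2) <= 1e-12
            cur_len = best[1] - best[0]
            if better or (tie and (length > cur_len or (length == cur_len and start < best[0]))):
                best, best_r2 = (start, start + length), r2
    return best


def depletion_rate(
    series: DepletionSeries, window: str | tuple[int, int] | None = None
) -> tuple[float, tuple[int, int]]:
    """Depletion rate (nmol/min) as minus the OLS slope of amount vs time.

    ``window`` selects the linear section: ``None`` uses all points,
    ``"auto"`` picks the contiguous >= 3-point run maximizing R², and an
    explicit ``(i, j)`` index pair uses ``times[i:j]``.
    Returns ``(rate, window_used)``.
    """
    t, a = series.times, series.amounts
    if window is None:
        idx = (0, len(t))
    elif window == "auto":
        idx = _best_window(t, a)
    else:
        idx = (int(window[0]), int(window[1]))
        if idx[1] - idx[0] < 2:
            raise ValueError("window must contain at least two points")
    rate = _ols_rate(t[idx[0] : idx[1]], a[idx[0] : idx[1]])
    return rate, idx


def blank_correct(sample_rate: float, blanks: BlankSet) -> float:
    """Subtract the mean blank rate; negative results are kept (flagged later)."""
    return sample_rate - blanks.mean


def limit_of_detection(blanks: BlankSet) -> float:
    """LOD = 3 x sample SD (n-1 denominator) of the blank rates, nmol/min."""
    return 3.0 * blanks.sd


def mass_normalize(rate: float, well_mass: float) -> float:
    """Express a rate relative to the particle mass in the well (nmol/min/μg)."""
    if well_mass <= 0:
        raise ValueError("well_mass must be > 0")
    return rate / well_mass


def op_result(
    series: DepletionSeries,
    blanks: BlankSet,
    window: str | tuple[int, int] | None = None,
) -> OPResult:
    """Full per-well pipeline: rate, blank correction, LOD flag, mass norm."""
    raw, idx = depletion_rate(series, window)
    corrected = blank_correct(raw, blanks)
    lod = limit_of_detection(blanks)
    return OPResult(
        raw_rate=raw,
        blank_corrected_rate=corrected,
        lod=lod,
        above_lod=corrected > lod,
        mass_normalized=mass_normalize(corrected, series.well_mass),
        reagent=series.reagent,
        window=idx,
    )


# ---------------------------------------------------------------------------
# dose and response arithmetic


def reagent_amount(volume_ul: float, molarity_mm: float) -> float:
    """Reagent amount in nmol from volume (μL) and molarity (mM)."""
    if volume_ul < 0 or molarity_mm < 0:
        raise ValueError("volume and molarity must be >= 0")
    return volume_ul * molarity_mm


def deposition_dose(conc_ug_ml: float, volume_ml: float, area_cm2: float) -> float:
    """Areal deposition dose (μg/cm²) of a pipetted particle suspension."""
    return ExposureDose(conc_ug_ml, volume_ml, area_cm2).areal_dose


def seeding_density(cells: float, area_cm2: float) -> float:
    """Cells per cm² of insert growth area, to 3 significant figures."""
    if cells <= 0 or area_cm2 <= 0:
        raise ValueError("cells and area must be > 0")
    density = cells / area_cm2
    return float(f"{density:.3g}")


def fold_change(treated: CytokineMeasurement, untreated: CytokineMeasurement) -> float:
    """Protein-normalized cytokine fold change, treated / untreated.

    Raises ``ValueError`` when the untreated baseline is unquantifiable
    (zero), mirroring how such replicates must be excluded rather than
    silently imputed.
    """
    if untreated.normalized <= 0:
        raise ValueError("not computable: untreated baseline is unquantifiable")
    return treated.normalized / untreated.normalized


# ---------------------------------------------------------------------------
# plate-level tabular interface
# long format: well, reagent, time_min, amount_nmol, well_mass_ug, is_blank


def process_plate(
    plate: pd.DataFrame | str | Path, window: str | tuple[int, int] | None = None
) -> pd.DataFrame:
    """Process a long-format plate table into per-well OP results.

    Blank wells (``is_blank`` truthy) define the blank set per reagent;
    sample wells are blank-corrected, LOD-flagged and mass-normalized.
    """
    if not isinstance(plate, pd.DataFrame):
        plate = pd.read_csv(plate)
    results = []
    for reagent, group in plate.groupby("reagent"):
        rates: dict[str, tuple[float, DepletionSeries, tuple[int, int]]] = {}
        blanks_rates = []
        for well, wg in group.groupby("well"):
            wg = wg.sort_values("time_min")
            series = DepletionSeries(
                times=wg["time_min"].to_numpy(float),
                amounts=wg["amount_nmol"].to_numpy(float),
                reagent=str(reagent),
                well_mass=float(wg["well_mass_ug"].iloc[0]) if not wg["is_blank"].iloc[0] else 1.0,
            )
            rate, idx = depletion_rate(series, window)
            if wg["is_blank"].iloc[0]:
                blanks_rates.append(rate)
            else:
                rates[str(well)] = (rate, series, idx)
        blanks = BlankSet(rates=tuple(blanks_rates))
        lod = limit_of_detection(blanks)
        for well, (rate, series, idx) in rates.items():
            corrected = blank_correct(rate, blanks)
            results.append(
                {
                    "well": well,
                    "reagent": reagent,
                    "raw_rate_nmol_min": rate,
                    "blank_corrected_rate_nmol_min": corrected,
                    "lod_nmol_min": lod,
                    "above_lod": corrected > lod,
                    "op_nmol_min_ug": mass_normalize(corrected, series.well_mass),
                    "fit_window": f"{idx[0]}:{idx[1]}",
                }
            )
    return pd.DataFrame(results)
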