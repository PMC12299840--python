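"""Closed-form conversions for cellulose hydrolysis and adsorption readouts.

Three small pure functions plus TSV helpers:

* glucan conversion — percent of loaded anhydroglucan released as soluble
  sugar, with anhydro-correction factors 0.9 (glucose) and 0.95 (cellobiose)
  compensating for the water added on glycosidic-bond hydrolysis;
* Segal crystallinity index — peak-height CrI from an X-ray diffractogram of
  cellulose, 100 x (I002 - Iam) / I002;
* band relative abundance — gel-band intensities normalized to the 0 h lane
  (set to 100%); the drop from 100% is the enzyme-adsorption readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GLUCOSE_CORRECTION = 0.9
CELLOBIOSE_CORRECTION = 0.95

# Conventional 2-theta windows (degrees, Cu K-alpha) for cellulose I-beta:
# the (002) crystalline peak and the amorphous trough.
DEFAULT_CRYSTALLINE_WINDOW = (21.5, 23.5)
DEFAULT_AMORPHOUS_WINDOW = (17.5, 19.0)


@dataclass(frozen=True)
class SugarMeasurement:
    """Soluble sugar concentrations at one timepoint of a hydrolysis run."""

    glucose: float  # g/L
    cellobiose: float  # g/L
    glucan_load: float  # g/L
    timepoint: float = 0.0  # hours

    def __post_init__(self) -> None:
        if self.glucose < 0 or self.cellobiose < 0:
            raise ValueError("sugar concentrations must be >= 0")
        if self.glucan_load <= 0:
            raise ValueError("glucan load must be > 0")


def glucan_conversion(m: SugarMeasurement) -> float:
    """Percent glucan conversion: 100 x (0.9 glucose + 0.95 cellobiose) / load.

    Values above 100% (possible with measurement noise) warn but are
    returned uncapped.
    """
    pct = 100.0 * (
        GLUCOSE_CORRECTION * m.glucose + CELLOBIOSE_CORRECTION * m.cellobiose
    ) / m.glucan_load
    if pct > 100.0:
        warnings.warn(f"glucan conversion {pct:.2f}% exceeds 100%", stacklevel=2)
    return pct


@dataclass
class XrdProfile:
    """An X-ray diffractogram with the two Segal windows (degrees 2-theta)."""

    two_theta: np.ndarray
    intensity: np.ndarray
    crystalline_window: tuple[float, float] = DEFAULT_CRYSTALLINE_WINDOW
    amorphous_window: tuple[float, float] = DEFAULT_AMORPHOUS_WINDOW

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.two_theta.shape != self.intensity.shape:
            raise ValueError("two_theta and intensity differ in length")
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("two_theta must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


def segal_cri(profile: XrdProfile) -> float:
    """Segal peak-height crystallinity index, percent.

    CrI = 100 x (I002 - Iam) / I002 with I002 the maximum intensity in the
    crystalline window and Iam the minimum in the amorphous window.
    """
    def window(lo_hi: tuple[float, float]) -> np.ndarray:
        lo, hi = lo_hi
        mask = (profile.two_theta >= lo) & (profile.two_theta <= hi)
        if not mask.any():
            raise ValueError(f"no data points in 2-theta window {lo}-{hi}")
        return profile.intensity[mask]

    i002 = float(window(profile.crystalline_window).max())
    iam = float(window(profile.amorphous_window).min())
    if i002 <= 0:
        raise ValueError("crystalline peak intensity must be > 0")
    return 100.0 * (i002 - iam) / i002


@dataclass
class BandIntensitySeries:
    """Gel-band intensities over time for one lane series, with a 0 h lane."""

    timepoints: list[float]
    intensities: list[float]
    lane: str = ""

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.intensities):
            raise ValueError("timepoints and intensities differ in length")
        if 0.0 not in self.timepoints:
            raise ValueError("series lacks the 0 h reference lane")
        i0 = self.intensities[self.timepoints.index(0.0)]
        if i0 <= 0:
            raise ValueError("0 h intensity must be > 0")


def relative_abundance(series: BandIntensitySeries) -> dict[float, float]:
    """Percent band intensity remaining at each timepoint, 0 h set to 100%.

    100 minus the returned value is the reduction attributed to enzyme
    adsorption onto the insoluble substrate.
    """
    i0 = series.intensities[series.timepoints.index(0.0)]
    return {t: 100.0 * i / i0 for t, i in zip(series.timepoints, series.intensities)}


# --- TSV helpers ----------------------------------------------------------


def sugar_table_conversions(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``conversion_pct`` column to a sugar table.

    Expects columns sample, time_h, glucose_gL, cellobiose_gL, glucan_gL.
    """
    required = {"sample", "time_h", "glucose_gL", "cellobiose_gL", "glucan_gL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sugar table missing columns: {sorted(missing)}")
    out = df.copy()
    out["conversion_pct"] = [
        glucan_conversion(
            SugarMeasurement(r.glucose_gL, r.cellobiose_gL, r.glucan_gL, r.time_h)
        )
        for r in df.itertuples()
    ]
    return out


def band_table_abundance(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``relative_pct`` per lane, normalized to each lane's 0 h row."""
    required = {"lane", "time_h", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    parts = []
    for lane, grp in df.groupby("lane", sort=True):
        series = BandIntensitySeries(
            timepoints=list(grp["time_h"]), intensities=list(grp["intensity"]), lane=str(lane)
        )
        rel = relative_abundance(series)
        g = grp.copy()
        g["relative_pct"] = [rel[t] for t in grp["time_h"]]
        parts.append(g)
    return pd.concat(parts, ignore_index=True)
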