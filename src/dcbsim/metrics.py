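"""Summary pharmacokinetic quantities of a simulated drug state.

Tissue content is the total drug mass (free + receptor-bound + ECM-bound)
per unit tissue mass,

    C_tissue(t) = D_MW / (rho_t A) * integral_{Omega_T} (c_t + b_R + b_E) dA,

and the fractional effects are the area-averaged occupancies of the two
binding-site populations, FE_R = <b_R / B_Rm> and FE_E = <b_E / B_Em>.
Integrals use the midpoint rule on pixel centers, consistent with the
pixel-as-control-volume convention of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .geometry import TissueLabelGrid, UndefinedMetricError
from .parameters import ModelParameters

__all__ = ["TimeSeriesResult", "tissue_content", "fractional_effect",
           "averaged_concentration", "percent_decrease"]

_SPECIES_ATTR = {"free": "c", "REC": "bR", "ECM": "bE"}


def _tissue_values(state, grid: TissueLabelGrid, attr: str) -> np.ndarray:
    mask = grid.tissue_mask
    if not mask.any():
        raise UndefinedMetricError("empty tissue domain")
    arr = np.asarray(getattr(state, attr))
    if arr.shape != grid.shape:
        raise ValueError(f"state field {attr!r} shape {arr.shape} does not "
                         f"match grid {grid.shape}")
    return arr[mask]


def tissue_content(state, grid: TissueLabelGrid,
                   params: ModelParameters) -> float:
    """Total drug mass per unit tissue mass, g drug / g tissue."""
    total = (_tissue_values(state, grid, "c")
             + _tissue_values(state, grid, "bR")
             + _tissue_values(state, grid, "bE")).sum() * grid.pixel_area
    return float(params.D_MW / (params.rho_t * grid.tissue_area) * total)


def fractional_effect(state, grid: TissueLabelGrid, which: str,
                      params: ModelParameters) -> float:
    """Area-averaged binding-site occupancy, in [0, 1].

    ``which`` selects the receptor ("REC") or extracellular-matrix
    ("ECM") population.
    """
    if which == "REC":
        b, bmax = _tissue_values(state, grid, "bR"), params.B_Rm
    elif which == "ECM":
        b, bmax = _tissue_values(state, grid, "bE"), params.B_Em
    else:
        raise ValueError(f"which must be 'REC' or 'ECM', got {which!r}")
    return float(np.mean(b / bmax))


def averaged_concentration(state, grid: TissueLabelGrid,
                           species: str = "free") -> float:
    """Arithmetic mean concentration over tissue pixels, mol/mm^3."""
    if species not in _SPECIES_ATTR:
        raise ValueError(f"species must be one of {list(_SPECIES_ATTR)}")
    return float(np.mean(_tissue_values(state, grid,
                                        _SPECIES_ATTR[species])))


@dataclass
class TimeSeriesResult:
    """Time-stamped averaged concentrations and summary metrics."""

    times: np.ndarray
    mean_ct: np.ndarray
    mean_bR: np.ndarray
    mean_bE: np.ndarray
    tissue_content: np.ndarray
    FE_R: np.ndarray
    FE_E: np.ndarray
    provenance: Dict[str, object] = field(default_factory=dict)
    budget: pd.DataFrame | None = None
    snapshots: List[tuple] = field(default_factory=list)
    failure: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.times,
            "mean_ct": self.mean_ct,
            "mean_bR": self.mean_bR,
            "mean_bE": self.mean_bE,
            "tissue_content_g_per_g": self.tissue_content,
            "FE_R": self.FE_R,
            "FE_E": self.FE_E,
        })

    def column(self, name: str) -> np.ndarray:
        if not hasattr(self, name):
            raise KeyError(name)
        return np.asarray(getattr(self, name))


def percent_decrease(series: TimeSeriesResult, t_query: float,
                     t_ref: float | None = None,
                     column: str = "mean_ct") -> float:
    """Percent decrease of a series column between two instants.

    ``t_ref`` defaults to the balloon deflation time recorded in the
    series provenance (the concentration peak).  Values are linearly
    interpolated between samples.
    """
    if t_ref is None:
        t_ref = series.provenance.get("t0")
        if t_ref is None:
            raise ValueError("no t_ref given and no t0 in provenance")
    times = series.times
    for t in (t_ref, t_query):
        if not (times[0] <= t <= times[-1]):
            raise ValueError(f"time {t} s outside series range "
                             f"[{times[0]}, {times[-1]}]")
    values = series.column(column)
    x_ref = float(np.interp(t_ref, times, values))
    x_query = float(np.interp(t_query, times, values))
    if x_ref == 0.0:
        raise UndefinedMetricError("reference value is zero")
    return 100.0 * (x_ref - x_query) / x_ref
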