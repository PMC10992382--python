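"""Convert raw fermentation time courses into specific rates.

The capture phase is a resting-cell batch: biomass stays near its initial
OD600 and concentrations change (approximately) linearly, so a specific rate
over a window is a concentration difference quotient divided by biomass dry
weight.  Rates come out in mmol gDCW^-1 h^-1, the unit used throughout the
ledgers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import (
    CONSUMPTION,
    PRODUCTION,
    NetworkConstants,
    RateMeasurement,
)

__all__ = [
    "TimeCourse",
    "convert_concentration",
    "specific_rate",
    "label_fraction_from_timecourse",
]

LABELED_LACTATE = "lactate13C"


@dataclass
class TimeCourse:
    """A sampled fermentation: times (h), OD600 and concentration series.

    ``concentrations`` maps species name to a per-sample array; ``units`` maps
    the same names to ``"g/L"`` or ``"mM"``.  The labeled-lactate series, when
    present, is stored under the species name ``"lactate13C"`` with the same
    unit as lactate.
    """

    times: np.ndarray
    od600: np.ndarray
    concentrations: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two sample times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.od600) != len(self.times):
            raise ValueError("od600 length differs from times")
        if np.any(self.od600 <= 0):
            raise ValueError("od600 must be positive")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        for name, series in self.concentrations.items():
            if len(series) != len(self.times):
                raise ValueError(f"series {name!r} length differs from times")
            if np.any(series < 0):
                raise ValueError(f"negative concentration in series {name!r}")
            if name not in self.units:
                raise ValueError(f"no unit declared for series {name!r}")
            if self.units[name] not in ("g/L", "mM"):
                raise ValueError(f"unknown unit {self.units[name]!r} for {name!r}")

    @property
    def labeled_lactate(self) -> Optional[np.ndarray]:
        return self.concentrations.get(LABELED_LACTATE)

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        if t0 >= t1:
            raise ValueError("window start must precede window end")
        mask = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        idx = np.nonzero(mask)[0]
        if len(idx) < 2:
            raise ValueError("window must contain at least two samples")
        return idx

    def default_window(self, span: float = 12.0) -> tuple[float, float]:
        """The last ``span`` hours of the series (the analysis window used
        for all reference computations)."""
        return (self.times[-1] - span, self.times[-1])


def convert_concentration(
    value, unit: str, species: str, constants: NetworkConstants
):
    """Convert a concentration to mM.  g/L inputs need a molar mass entry."""
    arr = np.asarray(value, dtype=float)
    if unit == "mM":
        out = arr
    elif unit == "g/L":
        base = species[:-3] if species.endswith("13C") else species
        if base not in constants.molar_mass:
            raise ValueError(f"no molar mass for species {species!r}")
        out = arr / constants.molar_mass[base] * 1000.0
    else:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return float(out) if np.isscalar(value) else out


def specific_rate(
    tc: TimeCourse,
    species: str,
    window: Optional[tuple[float, float]] = None,
    constants: Optional[NetworkConstants] = None,
    biomass_mode: str = "constant",
    estimator: str = "endpoint",
) -> RateMeasurement:
    """Specific rate of a species over a window, mmol gDCW^-1 h^-1.

    Parameters
    ----------
    window : (t_start, t_end), optional
        Defaults to the last 12 h of the series.
    biomass_mode : {"constant", "per_sample"}
        "constant" (default, resting-cell assumption) divides by the
        window-mean OD; "per_sample" divides each increment by its local
        mean OD before summing.
    estimator : {"endpoint", "regression"}
        "endpoint" (default) is |ΔC|/Δt between the window endpoints;
        "regression" uses the least-squares slope over all window samples.

    The direction is set by the sign of the concentration change: a
    decreasing series is a consumption.
    """
    constants = constants or NetworkConstants()
    if window is None:
        window = tc.default_window()
    idx = tc.window_indices(window)
    if species not in tc.concentrations:
        raise ValueError(f"species {species!r} not in time course")
    conc_mm = convert_concentration(
        tc.concentrations[species][idx], tc.units[species], species, constants
    )
    t = tc.times[idx]
    od = tc.od600[idx]
    mean_od = float(np.mean(od))
    if mean_od <= 0:
        raise ValueError("zero biomass in window")
    biomass = mean_od * constants.dcw_per_od  # gDCW/L

    if estimator == "endpoint":
        slope = (conc_mm[-1] - conc_mm[0]) / (t[-1] - t[0])  # mM/h
        if biomass_mode == "per_sample":
            # per-increment biomass weighting
            dc = np.diff(conc_mm)
            dt = np.diff(t)
            local_b = 0.5 * (od[1:] + od[:-1]) * constants.dcw_per_od
            rate = float(np.sum(dc / local_b) / np.sum(dt))
        else:
            rate = slope / biomass
    elif estimator == "regression":
        slope = float(np.polyfit(t, conc_mm, 1)[0])
        rate = slope / biomass
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    direction = CONSUMPTION if rate < 0 else PRODUCTION
    return RateMeasurement(species=species, value=abs(rate), direction=direction)


def label_fraction_from_timecourse(
    tc: TimeCourse,
    window: Optional[tuple[float, float]] = None,
    control_tc: Optional[TimeCourse] = None,
    constants: Optional[NetworkConstants] = None,
) -> float:
    """Background-corrected molar fraction of 13C-labeled lactate.

    R = (labeled lactate accumulated over the window − background
    accumulation from the control strain over the same window) / total
    lactate accumulated over the window, all in mM.  Without a control the
    fraction is uncorrected.  A negative corrected numerator is clipped to 0.
    """
    constants = constants or NetworkConstants()
    if window is None:
        window = tc.default_window()

    def _accum(course: TimeCourse, species: str) -> float:
        if species not in course.concentrations:
            raise ValueError(f"series {species!r} missing from time course")
        idx = course.window_indices(window)
        mm = convert_concentration(
            course.concentrations[species][idx], course.units[species], species, constants
        )
        return float(mm[-1] - mm[0])

    total = _accum(tc, "lactate")
    if total <= 0:
        raise ValueError("total lactate accumulation over window is not positive")
    labeled = _accum(tc, LABELED_LACTATE)
    background = _accum(control_tc, LABELED_LACTATE) if control_tc is not None else 0.0
    corrected = labeled - background
    if corrected < 0:
        corrected = 0.0
    return corrected / total
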