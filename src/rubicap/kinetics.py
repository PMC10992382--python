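"""Rubisco carboxylation enzymology: Michaelis–Menten fitting and the
expression/activity quantities derived from CABP active-site titration.

The carboxylation assay measures per-active-site rates v(c) at a grid of
dissolved-CO2 concentrations c (μM); nonlinear least squares against

    v = kcat_c · c / (K_M_c + c)

gives the turnover number kcat_c (s^-1) and Michaelis constant K_M_c (μM).
The catalytic efficiency kcat/K_M is reported in s^-1 mM^-1.  Active sites
are counted by stoichiometric binding of the transition-state analog CABP,
which titrates sites rather than holoenzymes — hence the per-site mass
convention for the soluble-protein percentage (%CSP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from lmfit import Model as _LmModel

__all__ = [
    "KineticDataset",
    "KineticParams",
    "ExpressionQuant",
    "michaelis_menten",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "relative_change",
    "turnover_number",
    "csp_fraction",
    "specific_activity",
    "expression_quant",
    "HEXAMER_MASS_DA",
    "PER_SITE_MASS_DA",
]

#: holoenzyme molar mass of the hexameric Form II enzyme, g/mol
HEXAMER_MASS_DA = 322_000.0
#: default per-active-site mass: one large subunit of the hexamer
PER_SITE_MASS_DA = HEXAMER_MASS_DA / 6.0


@dataclass
class KineticDataset:
    """A carboxylation assay: CO2 concentrations (μM) and per-site rates (s^-1)."""

    co2_concs: np.ndarray
    rates: np.ndarray
    replicate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.co2_concs = np.asarray(self.co2_concs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.co2_concs.shape != self.rates.shape:
            raise ValueError("co2_concs and rates must have the same shape")
        if np.any(self.co2_concs <= 0):
            raise ValueError("CO2 concentrations must be positive")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if len(np.unique(self.co2_concs)) < 2:
            raise ValueError("need at least two distinct CO2 concentrations")


@dataclass(frozen=True)
class KineticParams:
    """Fitted carboxylation parameters with standard errors."""

    kcat_c: float
    kcat_c_sd: float
    km_c: float
    km_c_sd: float
    efficiency: float
    efficiency_sd: float
    covar: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kcat_c <= 0 or self.km_c <= 0:
            raise ValueError("kcat and K_M must be positive")


@dataclass(frozen=True)
class ExpressionQuant:
    """Expression and activity quantities from a CABP titration."""

    active_sites: float  # nmol
    site_molar_mass: float  # g/mol attributed per site
    total_csp: float  # mg
    csp_percent: float
    specific_activity: float  # nmol CO2 min^-1 mg^-1 CSP


def michaelis_menten(c, kcat, km):
    """v = kcat·c/(K_M + c)."""
    c = np.asarray(c, dtype=float)
    return kcat * c / (km + c)


def fit_michaelis_menten(
    data: KineticDataset, init: Optional[tuple[float, float]] = None
) -> KineticParams:
    """Nonlinear least-squares fit of the Michaelis–Menten curve.

    Initialisation defaults to kcat0 = max observed rate and K_M0 = the
    concentration nearest half-max; both parameters are bounded positive.
    Standard errors come from the fit covariance; the catalytic efficiency
    SD uses first-order propagation including the kcat/K_M covariance.
    """
    c = data.co2_concs
    v = data.rates
    if len(np.unique(c)) < 3:
        warnings.warn(
            "fewer than 3 distinct concentrations: K_M weakly identified",
            stacklevel=2,
        )
    if init is None:
        kcat0 = float(np.max(v)) or 1.0
        half = kcat0 / 2.0
        km0 = float(c[np.argmin(np.abs(v - half))])
        init = (kcat0, max(km0, np.min(c)))
    model = _LmModel(michaelis_menten, independent_vars=["c"])
    params = model.make_params(kcat=init[0], km=init[1])
    params["kcat"].set(min=1e-12)
    params["km"].set(min=1e-12)
    result = model.fit(v, params, c=c)
    if not result.success:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {result.message}")
    kcat = float(result.params["kcat"].value)
    km = float(result.params["km"].value)
    kcat_sd = float(result.params["kcat"].stderr or 0.0)
    km_sd = float(result.params["km"].stderr or 0.0)
    covar = result.covar
    eff = catalytic_efficiency(kcat, km)
    # first-order propagation of eff = 1000·kcat/km
    if covar is not None and covar.shape == (2, 2):
        g = np.array([1000.0 / km, -1000.0 * kcat / km**2])
        var = float(g @ covar @ g)
        eff_sd = float(np.sqrt(max(var, 0.0)))
    else:
        eff_sd = eff * float(
            np.sqrt((kcat_sd / kcat) ** 2 + (km_sd / km) ** 2)
        )
    return KineticParams(
        kcat_c=kcat,
        kcat_c_sd=kcat_sd,
        km_c=km,
        km_c_sd=km_sd,
        efficiency=eff,
        efficiency_sd=eff_sd,
        covar=covar,
    )


def catalytic_efficiency(kcat_c: float, km_c: float) -> float:
    """kcat/K_M with μM→mM conversion, s^-1 mM^-1."""
    if km_c <= 0:
        raise ValueError("K_M must be positive")
    return kcat_c / km_c * 1000.0


def relative_change(a: float, b: float) -> float:
    """(a − b)/b as a percentage."""
    if b == 0:
        raise ValueError("reference value is zero")
    return (a - b) / b * 100.0


def turnover_number(fixed_co2: float, active_sites: float, duration: float) -> float:
    """Per-site turnover, s^-1: nmol CO2 fixed / nmol sites / seconds."""
    if active_sites <= 0:
        raise ValueError("active sites must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return fixed_co2 / active_sites / duration


def csp_fraction(
    active_sites: float,
    site_molar_mass: float = PER_SITE_MASS_DA,
    total_csp: float = 1.0,
) -> float:
    """Enzyme soluble protein as % of total cellular soluble protein.

    sites (nmol) × per-site mass (g/mol == µg/nmol) gives µg of enzyme;
    divide by total soluble protein (mg → µg) and scale to percent.
    """
    if total_csp <= 0:
        raise ValueError("total soluble protein must be positive")
    if active_sites < 0 or site_molar_mass < 0:
        raise ValueError("sites and mass must be non-negative")
    enzyme_ug = active_sites * site_molar_mass * 1e-3  # nmol × g/mol × 1e-3 = µg
    return enzyme_ug / (total_csp * 1000.0) * 100.0


def specific_activity(fixed_co2: float, duration: float, total_csp: float) -> float:
    """Crude-extract activity, nmol CO2 min^-1 mg^-1 soluble protein."""
    if duration <= 0 or total_csp <= 0:
        raise ValueError("duration and protein must be positive")
    return fixed_co2 / duration / total_csp


def expression_quant(
    active_sites: float,
    total_csp: float,
    fixed_co2: float,
    duration_min: float,
    site_molar_mass: float = PER_SITE_MASS_DA,
) -> ExpressionQuant:
    """Bundle the CABP-derived expression and activity quantities."""
    return ExpressionQuant(
        active_sites=active_sites,
        site_molar_mass=site_molar_mass,
        total_csp=total_csp,
        csp_percent=csp_fraction(active_sites, site_molar_mass, total_csp),
        specific_activity=specific_activity(fixed_co2, duration_min, total_csp),
    )
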