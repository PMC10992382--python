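"""Domain types and physical constants for the engineered-strain capture network.

The network is the small fixed topology of the xylose/glycerol -> d-lactate
fermentation with a phosphoribulokinase (PRK) + Rubisco bypass: xylose is
split between the pentose-phosphate route and the bypass, glycerol feeds in
at glyceraldehyde-3-phosphate (G3P), and the only products tracked are
d-lactate, acetate and ethanol.  Everything downstream (flux partition,
carbon and NADH ledgers) consumes the types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "NetworkConstants",
    "StrainConfig",
    "RateMeasurement",
    "StrainRateTable",
    "validate_rate_table",
    "CONSUMPTION",
    "PRODUCTION",
]

CONSUMPTION = "consumption"
PRODUCTION = "production"

#: species tracked on the consumption side of the network
SUBSTRATES = ("xylose", "glycerol")
#: species tracked on the production side
PRODUCTS = ("lactate", "acetate", "ethanol")


def _default_carbon_atoms() -> dict[str, int]:
    return {
        "xylose": 5,
        "glycerol": 3,
        "lactate": 3,
        "acetate": 2,
        "ethanol": 2,
        "co2": 1,
    }


def _default_molar_mass() -> dict[str, float]:
    # g/mol
    return {
        "lactate": 90.08,
        "xylose": 150.13,
        "glycerol": 92.09,
        "acetate": 60.05,
        "ethanol": 46.07,
    }


@dataclass(frozen=True)
class NetworkConstants:
    """Stoichiometric and unit-conversion constants of the capture network.

    Parameters
    ----------
    carbon_atoms : dict
        Carbon atoms per molecule for every tracked species.
    nadh_consumed_per : dict
        NADH molecules consumed per product molecule formed.  One per lactate
        (lactate dehydrogenase) and one per ethanol: the accounting convention
        is one NADH event per reaction, which is the convention that closes
        the redox ledger for all reference strains.
    nadh_produced_per : dict
        NADH produced per reaction event: one per glycerol oxidised
        (glycerol -> glycerone) and one per G3P through GAPDH.
    dcw_per_od : float
        Dry-cell-weight conversion, gDCW L^-1 per OD600 unit.
    molar_mass : dict
        g/mol, used to convert g/L concentrations to mM.
    """

    carbon_atoms: dict[str, int] = field(default_factory=_default_carbon_atoms)
    nadh_consumed_per: dict[str, int] = field(
        default_factory=lambda: {"lactate": 1, "ethanol": 1}
    )
    nadh_produced_per: dict[str, int] = field(
        default_factory=lambda: {"glycerol_oxidation": 1, "gapdh": 1}
    )
    dcw_per_od: float = 0.3
    molar_mass: dict[str, float] = field(default_factory=_default_molar_mass)

    def __post_init__(self) -> None:
        if self.dcw_per_od <= 0:
            raise ValueError("dcw_per_od must be > 0")
        for name, count in {**self.carbon_atoms}.items():
            if not (isinstance(count, (int,)) and count > 0):
                raise ValueError(
                    f"carbon_atoms[{name!r}] must be a positive integer, got {count!r}"
                )
        for table in (self.nadh_consumed_per, self.nadh_produced_per):
            for name, count in table.items():
                if not (isinstance(count, int) and count > 0):
                    raise ValueError(
                        f"NADH coefficient for {name!r} must be a positive integer"
                    )

    def with_overrides(self, **kwargs) -> "NetworkConstants":
        """Return a copy with selected fields replaced (config-file overrides)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StrainConfig:
    """Identity and genotype flags of an analysed strain.

    ``rubisco_active``/``prk_active`` mark whether the bypass can carry flux;
    the control strain (both inactive) is the source of the labeled-lactate
    background correction.
    """

    strain_id: str
    rubisco_active: bool = True
    prk_active: bool = True
    notes: str = ""

    @property
    def is_control(self) -> bool:
        return not (self.rubisco_active and self.prk_active)


@dataclass(frozen=True)
class RateMeasurement:
    """A specific rate in mmol gDCW^-1 h^-1 with its standard deviation.

    Rates are stored unsigned; the flow direction is explicit so ledger code
    never has to guess sign conventions.
    """

    species: str
    value: float
    sd: float = 0.0
    direction: str = PRODUCTION

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative rate for {self.species!r}: {self.value}")
        if self.sd < 0:
            raise ValueError(f"negative sd for {self.species!r}: {self.sd}")
        if self.direction not in (CONSUMPTION, PRODUCTION):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class StrainRateTable:
    """Per-strain specific consumption/production rates.

    ``co2_uptake`` may be absent, meaning the bypass flux is still to be
    inferred from the labeled-lactate fraction; ``label_fraction`` is the
    background-corrected molar fraction of singly 13C-labeled lactate.
    """

    strain: StrainConfig
    xylose: RateMeasurement
    glycerol: RateMeasurement
    lactate: RateMeasurement
    acetate: RateMeasurement
    ethanol: RateMeasurement
    co2_uptake: Optional[RateMeasurement] = None
    label_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label_fraction is not None and not (0 <= self.label_fraction < 1):
            raise ValueError("label_fraction must lie in [0, 1)")

    def measurements(self) -> dict[str, RateMeasurement]:
        out = {
            "xylose": self.xylose,
            "glycerol": self.glycerol,
            "lactate": self.lactate,
            "acetate": self.acetate,
            "ethanol": self.ethanol,
        }
        if self.co2_uptake is not None:
            out["co2"] = self.co2_uptake
        return out


def validate_rate_table(
    table: StrainRateTable, constants: NetworkConstants
) -> StrainRateTable:
    """Check a rate table against the network constants and return it unchanged.

    Raises
    ------
    ValueError
        If a species lacks a carbon-atom entry, a rate or sd is negative, or
        a measurement's direction contradicts its role in the network.
    """
    expected = {
        "xylose": CONSUMPTION,
        "glycerol": CONSUMPTION,
        "co2": CONSUMPTION,
        "lactate": PRODUCTION,
        "acetate": PRODUCTION,
        "ethanol": PRODUCTION,
    }
    for species, meas in table.measurements().items():
        if species not in constants.carbon_atoms:
            raise ValueError(f"unknown species {species!r}: no carbon_atoms entry")
        if meas.direction != expected[species]:
            raise ValueError(
                f"direction mismatch for {species!r}: expected {expected[species]}, "
                f"got {meas.direction}"
            )
        # value/sd sign invariants are enforced at construction; re-checked
        # here so tables built by other paths cannot sneak through
        if meas.value < 0:
            raise ValueError(f"negative rate for {species!r}")
        if meas.sd < 0:
            raise ValueError(f"negative sd for {species!r}")
    return table
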