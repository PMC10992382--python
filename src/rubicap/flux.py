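"""Partition xylose flux between the pentose-phosphate pathway and the
PRK/Rubisco bypass from the 13C-labeled lactate fraction.

The model: xylose uptake ``xyl_total`` splits into a pentose-phosphate
branch ``x1`` and a bypass branch ``x2`` (which equals the CO2-uptake flux,
since each bypass turn carboxylates one RuBP).  Carbon rearrangement through
the pentose-phosphate pathway turns ``x1`` xylose (5C) into ``(5/6)·x1``
fructose-6-phosphate (6C), each of which yields two G3P; glycerol enters the
G3P pool directly:

    xyl_total = x1 + x2
    x3        = (5/3)·x1 + gly_total

Each carboxylation produces two 3PGA, exactly one of which carries the
labeled carboxyl carbon, so the labeled fraction of the 3PGA pool — and of
the lactate made from it — is

    r = x2 / (x3 + 2·x2)

Inverting this for ``x2`` given measured r is a one-line closed form; both
directions are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FluxPartition",
    "forward_label_fraction",
    "infer_flux_partition",
    "bypass_fraction",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FluxPartition:
    """A complete flux partition, mmol gDCW^-1 h^-1.

    Attributes
    ----------
    x1 : pentose-phosphate xylose flux
    x2 : bypass xylose flux == CO2-uptake flux
    x3 : G3P flux entering lower glycolysis
    r_3pga : labeled fraction of the 3PGA pool (== labeled lactate fraction)
    xyl_total, gly_total : the substrate uptake fluxes
    """

    x1: float
    x2: float
    x3: float
    r_3pga: float
    xyl_total: float
    gly_total: float

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be non-negative")
        scale = max(abs(self.xyl_total), 1.0)
        if abs(self.x1 + self.x2 - self.xyl_total) > _REL_TOL * scale:
            raise ValueError("x1 + x2 must equal xyl_total")


def forward_label_fraction(
    x2: float, xyl_total: float, gly_total: float
) -> FluxPartition:
    """Evaluate the label fraction produced by a given bypass flux.

    Raises if ``x2`` exceeds the xylose supply or if all fluxes are zero
    (fraction undefined).
    """
    if not (0 <= x2 <= xyl_total * (1 + _REL_TOL)):
        raise ValueError(
            f"bypass flux x2={x2} outside [0, xyl_total={xyl_total}]"
        )
    if gly_total < 0:
        raise ValueError("gly_total must be non-negative")
    x1 = xyl_total - x2
    x3 = (5.0 / 3.0) * x1 + gly_total
    denom = x3 + 2.0 * x2
    if denom <= 0:
        raise ValueError("label fraction undefined: all fluxes are zero")
    r = x2 / denom
    return FluxPartition(
        x1=x1, x2=x2, x3=x3, r_3pga=r, xyl_total=xyl_total, gly_total=gly_total
    )


def infer_flux_partition(
    xyl_total: float, gly_total: float, r_lactate: float
) -> FluxPartition:
    """Closed-form inversion: bypass flux from the measured label fraction.

    Substituting x1 = xyl − x2 into r = x2/(x3 + 2 x2) and solving gives

        x2 = r·((5/3)·xyl_total + gly_total) / (1 − r/3)

    Raises if the inferred x2 exceeds the xylose supply (a label fraction
    inconsistent with the substrate fluxes) or r is outside [0, 1).
    """
    if not (0 <= r_lactate < 1):
        raise ValueError("label fraction must lie in [0, 1)")
    if xyl_total <= 0 and gly_total <= 0:
        raise ValueError("at least one substrate flux must be positive")
    if xyl_total <= 0 and r_lactate > 0:
        # a labeled pool requires xylose-derived RuBP to carboxylate
        raise ValueError("nonzero label fraction with no xylose supply")
    x2 = r_lactate * ((5.0 / 3.0) * xyl_total + gly_total) / (1.0 - r_lactate / 3.0)
    if x2 > xyl_total * (1 + _REL_TOL):
        raise ValueError(
            f"label fraction inconsistent with substrate supply: inferred "
            f"x2={x2:.4g} exceeds xyl_total={xyl_total:.4g}"
        )
    x2 = min(x2, xyl_total)
    return forward_label_fraction(x2, xyl_total, gly_total)


def bypass_fraction(p: FluxPartition) -> float:
    """Fraction of xylose consumed through the CO2-fixation bypass, x2/xyl."""
    if p.xyl_total <= 0:
        raise ValueError("bypass fraction undefined for zero xylose flux")
    return p.x2 / p.xyl_total
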