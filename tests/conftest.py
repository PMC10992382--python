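import numpy as np
import pytest

from rubicap import (
    NetworkConstants,
    RateMeasurement,
    StrainConfig,
    StrainRateTable,
    reference_rate_tables,
)
from rubicap.constants import CONSUMPTION


@pytest.fixture(scope="session")
def constants():
    return NetworkConstants()


@pytest.fixture(scope="session")
def reference_tables():
    """The packaged three-strain rate table (control, 7002, RPE)."""
    return reference_rate_tables()


@pytest.fixture
def rpe_table(reference_tables):
    return reference_tables["RPE"]


def make_table(
    xyl=0.50, gly=0.46, lac=1.01, ace=0.18, eth=0.06, co2=0.18,
    strain_id="t", label_fraction=None, sds=None,
):
    sds = sds or {}
    return StrainRateTable(
        strain=StrainConfig(strain_id),
        xylose=RateMeasurement("xylose", xyl, sds.get("xylose", 0.0), CONSUMPTION),
        glycerol=RateMeasurement("glycerol", gly, sds.get("glycerol", 0.0), CONSUMPTION),
        lactate=RateMeasurement("lactate", lac, sds.get("lactate", 0.0)),
        acetate=RateMeasurement("acetate", ace, sds.get("acetate", 0.0)),
        ethanol=RateMeasurement("ethanol", eth, sds.get("ethanol", 0.0)),
        co2_uptake=(
            None if co2 is None
            else RateMeasurement("co2", co2, sds.get("co2", 0.0), CONSUMPTION)
        ),
        label_fraction=label_fraction,
    )
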