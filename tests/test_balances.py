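"""Carbon and NADH ledgers against the published three-strain table, and
Monte-Carlo uncertainty propagation against closed forms."""

import numpy as np
import pytest

from rubicap import (
    carbon_ledger,
    forward_label_fraction,
    monte_carlo_propagate,
    partition_for_table,
    redox_ledger,
    strain_summary,
)
from rubicap.balances import round_half_away
from rubicap.simulate import ideal_stoichiometry_table

from conftest import make_table

# strain id -> (consumption, production, released CO2, recovery, NADH ratio)
PRINTED = {
    "197-2021": (2.59, 2.07, 0.12, 0.80, 0.56),
    "7002": (4.24, 3.18, 0.17, 0.75, 0.60),
    "RPE": (4.06, 3.75, 0.24, 0.92, 0.74),
}


class TestCarbonLedger:
    @pytest.mark.parametrize("strain", list(PRINTED))
    def test_printed_carbon_rows_reproduced(self, reference_tables, constants, strain):
        led = carbon_ledger(reference_tables[strain], constants)
        cons, prod, rel, rec, _ = PRINTED[strain]
        assert round_half_away(led.total_consumption, 2) == cons
        assert round_half_away(led.total_production, 2) == prod
        assert round_half_away(led.released_co2, 2) == rel
        assert round_half_away(led.recovery, 2) == rec

    def test_ideal_stoichiometry_closes_exactly(self, constants):
        led = carbon_ledger(ideal_stoichiometry_table(), constants)
        assert led.total_consumption == pytest.approx(12.0)
        assert led.recovery == pytest.approx(1.0, rel=1e-12)

    def test_missing_co2_uptake_rejected(self, constants):
        with pytest.raises(ValueError, match="co2_uptake missing"):
            carbon_ledger(make_table(co2=None), constants)

    def test_recovery_scale_invariant(self, constants):
        base = carbon_ledger(make_table(), constants)
        scaled = carbon_ledger(
            make_table(xyl=1.5, gly=1.38, lac=3.03, ace=0.54, eth=0.18, co2=0.54),
            constants,
        )
        assert scaled.recovery == pytest.approx(base.recovery, rel=1e-12)


class TestRedoxLedger:
    @pytest.mark.parametrize("strain", list(PRINTED))
    def test_printed_nadh_ratio_reproduced(self, reference_tables, constants, strain):
        table = reference_tables[strain]
        led = redox_ledger(table, partition_for_table(table), constants)
        assert round_half_away(led.ratio, 2) == PRINTED[strain][4]
        assert led.feasible

    def test_ideal_table_sits_on_feasibility_boundary(self, constants):
        table = ideal_stoichiometry_table()
        led = redox_ledger(table, partition_for_table(table), constants)
        assert led.ratio == pytest.approx(1.0, rel=1e-12)
        assert led.feasible

    def test_zero_products_feasible(self, constants):
        table = make_table(lac=0.0, ace=0.0, eth=0.0, co2=0.0)
        led = redox_ledger(table, partition_for_table(table), constants)
        assert led.ratio == 0.0 and led.feasible

    def test_consumption_without_production_errors(self, constants):
        table = make_table(xyl=0.0, gly=0.0, lac=1.0, ace=0.0, eth=0.0, co2=0.0)
        partition = forward_label_fraction(0.0, 0.0, 0.0001)
        bare = make_table(xyl=0.0, gly=0.0, lac=1.0, ace=0.0, eth=0.0, co2=0.0)
        zero_partition = type(partition)(
            x1=0.0, x2=0.0, x3=0.0, r_3pga=0.0, xyl_total=0.0, gly_total=0.0
        )
        with pytest.raises(ValueError, match="zero production"):
            redox_ledger(bare, zero_partition, constants)


class TestStrainSummary:
    def test_partition_inferred_from_label_fraction(self, constants):
        r = forward_label_fraction(0.18, 0.50, 0.46).r_3pga
        inferred = strain_summary(make_table(co2=None, label_fraction=r), constants)
        direct = strain_summary(make_table(), constants)
        for key in ("co2_uptake", "carbon_recovery", "nadh_ratio"):
            assert inferred[key] == pytest.approx(direct[key], rel=1e-9)

    def test_summary_homogeneous_degree_zero(self, constants):
        a = strain_summary(make_table(), constants)
        b = strain_summary(
            make_table(xyl=1.0, gly=0.92, lac=2.02, ace=0.36, eth=0.12, co2=0.36),
            constants,
        )
        for key in ("carbon_recovery", "nadh_ratio", "bypass_fraction", "label_fraction"):
            assert b[key] == pytest.approx(a[key], rel=1e-12)


class TestMonteCarlo:
    def test_zero_sds_give_zero_spread(self, constants):
        out = monte_carlo_propagate(make_table(), constants, n_draws=1000, seed=1)
        for mean, sd in out.values():
            assert sd == 0.0

    def test_deterministic_given_seed(self, constants):
        table = make_table(sds={"xylose": 0.11, "lactate": 0.11})
        a = monte_carlo_propagate(table, constants, n_draws=1000, seed=7)
        b = monte_carlo_propagate(table, constants, n_draws=1000, seed=7)
        assert a == b

    def test_sum_of_independent_normals(self, constants):
        """SD of a sum of two N(1, 0.1^2) draws is sqrt(0.02)."""
        table = make_table(
            xyl=1.0, gly=1.0, lac=0.5, ace=0.0, eth=0.0, co2=0.0,
            sds={"xylose": 0.1, "glycerol": 0.1},
        )
        fn = lambda t, c: {"sum": t.xylose.value + t.glycerol.value}
        out = monte_carlo_propagate(table, constants, n_draws=100_000, seed=3, fn=fn)
        mean, sd = out["sum"]
        # 3 sigma of the SD estimator at n = 1e5: sd/sqrt(2n) ~ 3.2e-4
        assert sd == pytest.approx(np.sqrt(0.02), abs=3 * np.sqrt(0.02) / np.sqrt(2e5))

    def test_ratio_matches_delta_method(self, constants):
        """SD of N(2,0.1^2)/N(4,0.2^2) ~ first-order delta method 0.0559."""
        table = make_table(
            xyl=2.0, gly=4.0, lac=0.5, ace=0.0, eth=0.0, co2=0.0,
            sds={"xylose": 0.1, "glycerol": 0.2},
        )
        fn = lambda t, c: {"ratio": t.xylose.value / t.glycerol.value}
        out = monte_carlo_propagate(table, constants, n_draws=100_000, seed=5, fn=fn)
        delta_sd = (2 / 4) * np.sqrt((0.1 / 2) ** 2 + (0.2 / 4) ** 2)
        assert out["ratio"][1] == pytest.approx(delta_sd, rel=0.05)

    def test_too_few_draws_rejected(self, constants):
        with pytest.raises(ValueError, match="at least 1000"):
            monte_carlo_propagate(make_table(), constants, n_draws=10)


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(0.745, 2, 0.75), (0.7449, 2, 0.74), (-0.745, 2, -0.75), (2.585, 2, 2.59)],
    )
    def test_round_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected
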