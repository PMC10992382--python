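"""Synthetic-data generator: ground-truth identities, determinism, and
full-pipeline parameter recovery."""

import numpy as np
import pytest

from rubicap import (
    SimulationConfig,
    carbon_ledger,
    ideal_stoichiometry_table,
    infer_flux_partition,
    label_fraction_from_timecourse,
    partition_for_table,
    redox_ledger,
    simulate_fermentation,
    simulate_kinetic_assay,
    specific_rate,
)
from rubicap.kinetics import michaelis_menten


def analyse(tc, control_tc=None, window=None):
    """Run the measurement pipeline on a simulated course."""
    window = window or tc.default_window()
    xyl = specific_rate(tc, "xylose", window).value
    gly = specific_rate(tc, "glycerol", window).value
    r = label_fraction_from_timecourse(tc, window, control_tc=control_tc)
    return infer_flux_partition(xyl, gly, r)


class TestFermentation:
    def test_noiseless_pipeline_recovers_true_bypass_flux(self):
        cfg = SimulationConfig(noise_cv=0.0, background_label_rate=0.0)
        tc, truth = simulate_fermentation(cfg)
        p = analyse(tc)
        assert p.x2 == pytest.approx(truth.co2_uptake.value, rel=1e-9)

    def test_background_correction_against_control_course(self):
        cfg = SimulationConfig(noise_cv=0.0)
        ctrl_cfg = SimulationConfig(
            x2=0.0, xyl_total=0.41, gly_total=0.18, lactate_rate=0.57,
            acetate_rate=0.11, ethanol_rate=0.01, noise_cv=0.0,
            rubisco_active=False, prk_active=False, strain_id="control",
        )
        tc, truth = simulate_fermentation(cfg)
        ctrl_tc, _ = simulate_fermentation(ctrl_cfg)
        p = analyse(tc, control_tc=ctrl_tc)
        assert p.x2 == pytest.approx(truth.co2_uptake.value, rel=1e-9)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(noise_cv=0.05, seed=99)
        tc1, _ = simulate_fermentation(cfg)
        tc2, _ = simulate_fermentation(SimulationConfig(noise_cv=0.05, seed=99))
        for sp in tc1.concentrations:
            np.testing.assert_array_equal(tc1.concentrations[sp], tc2.concentrations[sp])

    def test_different_seeds_differ(self):
        tc1, _ = simulate_fermentation(SimulationConfig(noise_cv=0.05, seed=1))
        tc2, _ = simulate_fermentation(SimulationConfig(noise_cv=0.05, seed=2))
        assert not np.array_equal(
            tc1.concentrations["lactate"], tc2.concentrations["lactate"]
        )

    def test_infeasible_product_split_rejected(self):
        with pytest.raises(ValueError, match="exceeds substrate"):
            SimulationConfig(xyl_total=0.1, gly_total=0.0, x2=0.0, lactate_rate=5.0)

    def test_bypass_above_xylose_rejected(self):
        with pytest.raises(ValueError, match="cannot exceed"):
            SimulationConfig(xyl_total=0.1, x2=0.2)

    def test_noiseless_model_consistent_recovery_is_exact(self, constants):
        """Any model-consistent split (C2 products + their released CO2
        compensate) closes carbon exactly."""
        for ace, eth in [(0.0, 0.0), (0.18, 0.06), (0.3, 0.0)]:
            c_in = 5 * 0.50 + 3 * 0.46 + 0.18
            lac = (c_in - 3 * (ace + eth)) / 3.0
            cfg = SimulationConfig(
                lactate_rate=lac, acetate_rate=ace, ethanol_rate=eth, noise_cv=0.0
            )
            _, truth = simulate_fermentation(cfg)
            led = carbon_ledger(truth, constants)
            assert led.recovery == pytest.approx(1.0, rel=1e-9)

    def test_parameter_recovery_under_noise(self):
        """Median |x2_hat − x2| over seeded 5%-CV runs stays below 10%.

        Under noise the whole batch is analysed (rates are constant
        throughout a simulated course, so the full span is the efficient
        window)."""
        errors = []
        for seed in range(100):
            cfg = SimulationConfig(noise_cv=0.05, background_label_rate=0.0, seed=seed)
            tc, truth = simulate_fermentation(cfg)
            try:
                p = analyse(tc, window=(float(tc.times[0]), float(tc.times[-1])))
            except ValueError:
                continue  # rare infeasible draw
            errors.append(abs(p.x2 - truth.co2_uptake.value) / truth.co2_uptake.value)
        assert len(errors) > 90
        assert np.median(errors) < 0.10

    def test_errors_shrink_with_noise(self):
        def median_err(cv):
            errs = []
            for seed in range(60):
                cfg = SimulationConfig(noise_cv=cv, background_label_rate=0.0, seed=seed)
                tc, truth = simulate_fermentation(cfg)
                try:
                    p = analyse(tc, window=(float(tc.times[0]), float(tc.times[-1])))
                except ValueError:
                    continue
                errs.append(abs(p.x2 - truth.co2_uptake.value))
            return np.median(errs)

        assert median_err(0.01) < median_err(0.08)


class TestKineticAssay:
    GRID = np.linspace(30, 1800, 13)

    def test_noiseless_equals_curve(self):
        data = simulate_kinetic_assay(16.4, 172.4, self.GRID, noise_cv=0.0)
        np.testing.assert_allclose(
            data.rates, michaelis_menten(self.GRID, 16.4, 172.4), rtol=1e-12
        )

    def test_half_saturation_identity(self):
        data = simulate_kinetic_assay(16.4, 172.4, np.array([172.4, 1800.0]), noise_cv=0.0)
        assert data.rates[0] == pytest.approx(8.2, rel=1e-12)

    def test_seeded_reproducibility(self):
        a = simulate_kinetic_assay(16.4, 172.4, self.GRID, 0.05, 3, seed=4)
        b = simulate_kinetic_assay(16.4, 172.4, self.GRID, 0.05, 3, seed=4)
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_noise_has_unit_mean(self):
        data = simulate_kinetic_assay(
            16.4, 172.4, np.array([250.0, 500.0]), noise_cv=0.10, replicates=4000, seed=8
        )
        clean = michaelis_menten(500.0, 16.4, 172.4)
        at_500 = data.rates[data.co2_concs == 500.0]
        assert np.mean(at_500) == pytest.approx(clean, rel=0.01)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_kinetic_assay(16.4, 172.4, np.array([]))


class TestIdealStoichiometry:
    def test_carbon_conservation(self, constants):
        led = carbon_ledger(ideal_stoichiometry_table(), constants)
        assert led.total_consumption == pytest.approx(12.0)
        assert led.total_production == pytest.approx(12.0)

    def test_all_xylose_through_bypass(self):
        table = ideal_stoichiometry_table()
        p = partition_for_table(table)
        assert p.x1 == 0.0
        assert p.x2 / p.xyl_total == 1.0

    def test_label_fraction_is_one_quarter(self):
        assert partition_for_table(ideal_stoichiometry_table()).r_3pga == pytest.approx(0.25)
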