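"""Flux terms, presets, insulin superposition and summary statistics."""

import numpy as np
import pytest

from glucosim.model import (
    DaySeries,
    ModelConstants,
    ModelError,
    PatientParameters,
    glucose_step,
    hba1c_estimate,
    insulin_day_profiles,
    mean_bg,
    net_hepatic_balance,
    peripheral_utilization_rate,
    preset_lookup,
    renal_excretion_rate,
)
from glucosim.profiles import GRID_POINTS, get_preparation


@pytest.fixture(scope="module")
def patient():
    return PatientParameters(weight_kg=70.0)


class TestPresets:
    @pytest.mark.parametrize("parameter,category,expected", [
        ("RTG", "low_reduced", 7.0),
        ("RTG", "normal", 9.0),
        ("RTG", "high_increased", 11.0),
        ("CCR", "low_reduced", 40.0),
        ("CCR", "normal", 100.0),
        ("hepatic_sensitivity", "low_reduced", 0.2),
        ("hepatic_sensitivity", "normal", 0.5),
        ("hepatic_sensitivity", "high_increased", 0.8),
        ("peripheral_sensitivity", "high_increased", 0.8),
    ])
    def test_preset_values(self, parameter, category, expected):
        assert preset_lookup(parameter, category) == expected

    def test_no_increased_ccr_preset(self):
        with pytest.raises(ModelError, match="CCR"):
            preset_lookup("CCR", "high_increased")


class TestRenalExcretion:
    def test_zero_at_and_below_threshold(self, patient):
        assert renal_excretion_rate(8.0, patient) == 0.0
        assert renal_excretion_rate(9.0, patient) == 0.0

    def test_linear_above_threshold(self, patient):
        # CCR 100 mL/min = 6 L/h; 6 * (11 - 9) = 12 mmol/h
        assert renal_excretion_rate(11.0, patient) == pytest.approx(12.0)

    def test_continuous_at_threshold(self, patient):
        eps = 1e-9
        assert renal_excretion_rate(9.0 + eps, patient) == pytest.approx(0.0, abs=1e-6)


class TestPeripheralUtilization:
    def test_zero_glucose_gives_zero(self, patient, constants):
        assert peripheral_utilization_rate(0.0, 50.0, patient, constants) == 0.0

    def test_monotone_in_insulin(self, patient, constants):
        grid = np.linspace(0, 80, 30)
        rates = peripheral_utilization_rate(8.0, grid, patient, constants)
        assert (np.diff(rates) >= 0).all()
        assert peripheral_utilization_rate(8.0, 20.0, patient, constants) <= \
            peripheral_utilization_rate(8.0, 40.0, patient, constants)

    def test_saturates_to_plateau(self, patient, constants):
        ia = 30.0
        plateau = (constants.util_base_mmol_per_h
                   + patient.peripheral_sensitivity * constants.util_insulin_slope * ia)
        huge_g = 1e6 * constants.km_mmol_per_l
        assert peripheral_utilization_rate(huge_g, ia, patient, constants) == \
            pytest.approx(plateau, rel=1e-5)


class TestNetHepaticBalance:
    def test_node_values_reproduced(self, patient, constants):
        # interpolation at a grid node returns the tabulated value; Sh=0.5
        # so probe with Ia = node/Sh
        xs = constants.nhgb_insulin_nodes
        gs = constants.nhgb_glucose_nodes
        grid = np.asarray(constants.nhgb_values)
        for i in (0, 2, len(xs) - 1):
            for j in (0, 3, len(gs) - 1):
                got = net_hepatic_balance(gs[j], xs[i] / 0.5, patient, constants)
                assert got == pytest.approx(grid[i, j], abs=1e-9)

    def test_high_insulin_never_raises_balance(self, patient, constants):
        for g in constants.nhgb_glucose_nodes:
            assert net_hepatic_balance(g, 80.0, patient, constants) <= \
                net_hepatic_balance(g, 0.0, patient, constants)

    def test_production_at_zero_insulin_euglycaemia(self, patient, constants):
        assert net_hepatic_balance(5.0, 0.0, patient, constants) > 0

    def test_arguments_clamped_not_extrapolated(self, patient, constants):
        inside = net_hepatic_balance(30.0, 1000.0, patient, constants)
        edge = net_hepatic_balance(30.0, 160.0, patient, constants)  # Sh*160 = 80
        assert inside == pytest.approx(edge)


class TestInsulinDayProfiles:
    def test_no_injections_gives_zero(self, tables, constants):
        plasma, active = insulin_day_profiles([], tables, 70.0, constants)
        assert not plasma.values.any() and not active.values.any()

    def test_time_shift_rotates_periodic_profile(self, tables, constants):
        # the daily-repetition steady state makes the profile equivariant
        # under circular time shifts: moving the injection two grid steps
        # rotates the series, with the tail wrapping past midnight
        prep = get_preparation("Actrapid")
        a, _ = insulin_day_profiles([(480.0, 8.0, prep)], tables, 70.0, constants)
        b, _ = insulin_day_profiles([(510.0, 8.0, prep)], tables, 70.0, constants)
        np.testing.assert_allclose(b.values[:-1], np.roll(a.values[:-1], 2))

    def test_late_injection_tail_wraps_to_morning(self, tables, constants):
        prep = get_preparation("Actrapid")
        plasma, _ = insulin_day_profiles([(23 * 60.0, 8.0, prep)], tables, 70.0, constants)
        assert plasma.values[0] > 0  # mass carried over midnight

    def test_split_basal_mass_balance(self, tables, constants):
        # 4 IU at 07:00 + 6 IU at 19:00 of a long-acting preparation inject
        # 10 IU/day; at periodic steady state elimination balances input:
        # mean plasma (mU/L) * ke * 24 h * Vi * weight = absorbed mass
        prep = get_preparation("Ultratard")
        weight = 70.0
        plasma, _ = insulin_day_profiles(
            [(7 * 60.0, 4.0, prep), (19 * 60.0, 6.0, prep)], tables, weight, constants)
        mean_mu = plasma.values[:-1].mean()
        eliminated_iu = (mean_mu / 1000.0 * constants.vi_l_per_kg * weight
                        * constants.k_insulin_elim_per_h * 24.0)
        assert eliminated_iu == pytest.approx(10.0, rel=0.02)

    def test_biphasic_counts_as_one_injection(self, tables, constants):
        prep = get_preparation("Mixtard 30/70")
        injections = [(float(h * 60), 10.0, prep) for h in (7, 12, 17, 22)]
        plasma, _ = insulin_day_profiles(injections, tables, 70.0, constants)
        assert plasma.values.max() > 0

    def test_fifth_injection_rejected(self, tables, constants):
        prep = get_preparation("Actrapid")
        injections = [(float(h * 60), 4.0, prep) for h in (7, 11, 15, 19, 23)]
        with pytest.raises(ModelError, match="4"):
            insulin_day_profiles(injections, tables, 70.0, constants)

    def test_overdose_rejected(self, tables, constants):
        prep = get_preparation("Actrapid")
        with pytest.raises(ModelError, match="40"):
            insulin_day_profiles([(480.0, 41.0, prep)], tables, 70.0, constants)


class TestGlucoseStep:
    def test_zero_fluxes_leave_glucose_unchanged(self, patient, constants):
        assert glucose_step(7.0, (0, 0, 0, 0), patient, constants) == 7.0

    def test_hand_computed_increment(self, constants):
        # 12 mmol/h into Vg*weight = 15.4 L for 15 min: +0.1948 mmol/L
        patient = PatientParameters(weight_kg=70.0)
        g1 = glucose_step(5.0, (12.0, 0.0, 0.0, 0.0), patient, constants, dt=15.0)
        assert g1 - 5.0 == pytest.approx(12.0 * 0.25 / 15.4, rel=1e-9)

    def test_nan_flux_raises(self, patient, constants):
        with pytest.raises(ModelError):
            glucose_step(7.0, (float("nan"), 0, 0, 0), patient, constants)

    def test_floor_applied(self, patient, constants):
        g = glucose_step(0.6, (0.0, 0.0, 500.0, 0.0), patient, constants)
        assert g == constants.bg_floor_mmol_per_l


class TestSummaries:
    def test_mean_of_constant_series(self):
        series = DaySeries(np.full(GRID_POINTS, 6.5), "mmol/L")
        assert mean_bg(series) == pytest.approx(6.5)

    def test_mean_of_alternating_series(self):
        values = np.where(np.arange(GRID_POINTS) % 2 == 0, 4.0, 8.0)
        values[-1] = values[0]
        assert mean_bg(DaySeries(values, "mmol/L")) == pytest.approx(6.0)

    def test_hba1c_examples(self):
        assert hba1c_estimate(200.0) == pytest.approx(8.59, abs=0.01)
        assert hba1c_estimate(113.8) == pytest.approx(6.0, abs=0.01)

    def test_hba1c_strictly_increasing(self):
        means = np.linspace(60, 350, 25)
        values = [hba1c_estimate(m) for m in means]
        assert (np.diff(values) > 0).all()
        eag = [hba1c_estimate(m, "eag") for m in means]
        assert (np.diff(eag) > 0).all()

    def test_hba1c_rejects_nonpositive(self):
        with pytest.raises(ModelError):
            hba1c_estimate(0.0)
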