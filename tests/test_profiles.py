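"""Absorption kinetics, lookup tables and the nine-file ASCII round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucosim.profiles import (
    GRID_POINTS,
    PROFILE_FILE_NAMES,
    AbsorptionClass,
    AbsorptionClassParams,
    InsulinCategory,
    ProfileError,
    ProfileFileSetError,
    absorption_fraction,
    absorption_rate,
    biphasic_split,
    build_carb_table,
    build_insulin_tables,
    gastric_emptying_profile,
    get_preparation,
    load_registry,
    read_profile_files,
    single_injection_response,
    write_profile_files,
)

ACTRAPID = AbsorptionClassParams(AbsorptionClass.ACTRAPID_LIKE, 2.0, 0.05, 1.5)


class TestAbsorptionFraction:
    def test_zero_at_injection_time(self):
        for dose in (1, 8, 40):
            assert absorption_fraction(0.0, dose, ACTRAPID) == 0.0

    def test_half_absorbed_at_t50(self):
        for dose in (1.0, 10.0, 40.0):
            t50 = ACTRAPID.t50(dose)
            assert absorption_fraction(t50, dose, ACTRAPID) == pytest.approx(0.5)

    def test_four_fifths_at_twice_t50_with_shape_two(self):
        # (2T)^2 / (T^2 + (2T)^2) = 4/5
        t50 = ACTRAPID.t50(8.0)
        assert absorption_fraction(2 * t50, 8.0, ACTRAPID) == pytest.approx(0.8)

    @pytest.mark.parametrize("dose", [0, -1, 40.5, 100])
    def test_dose_out_of_range_rejected(self, dose):
        with pytest.raises(ProfileError):
            absorption_fraction(1.0, dose, ACTRAPID)

    def test_negative_time_rejected(self):
        with pytest.raises(ProfileError):
            absorption_fraction(-0.1, 8.0, ACTRAPID)

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(0, 48), dt=st.floats(0, 12), dose=st.floats(0.5, 40))
    def test_monotone_nondecreasing_in_time(self, t, dt, dose):
        assert (absorption_fraction(t + dt, dose, ACTRAPID)
                >= absorption_fraction(t, dose, ACTRAPID))

    def test_approaches_one(self):
        assert absorption_fraction(1e6, 40.0, ACTRAPID) == pytest.approx(1.0, abs=1e-6)


class TestSingleInjectionResponse:
    def test_zero_dose_gives_zero_series(self, constants):
        plasma, active = single_injection_response(0.0, ACTRAPID, constants)
        assert not plasma.any() and not active.any()

    @pytest.mark.parametrize("cls", list(AbsorptionClass))
    @pytest.mark.parametrize("dose", [1.0, 10.0, 40.0])
    def test_absorbed_mass_converges_to_dose(self, cls, dose, config, constants):
        # independent oracle: numeric integration of the absorption-rate curve
        params = config.class_params[cls]
        t = np.arange(0, 144, 1 / 60.0)
        absorbed = np.trapezoid(absorption_rate(t, dose, params), t)
        assert absorbed == pytest.approx(dose, rel=0.01)

    def test_short_acting_peaks_before_long_acting(self, config, constants):
        fast, _ = single_injection_response(
            8.0, config.class_params[AbsorptionClass.ACTRAPID_LIKE], constants)
        slow, _ = single_injection_response(
            8.0, config.class_params[AbsorptionClass.ULTRALENTE_LIKE], constants)
        assert np.argmax(fast) < np.argmax(slow)

    def test_nonnegative_everywhere(self, config, constants):
        plasma, active = single_injection_response(
            12.0, config.class_params[AbsorptionClass.NPH_LIKE], constants)
        assert (plasma >= 0).all() and (active >= 0).all()


class TestInsulinTables:
    def test_dimensions_and_zero_row(self, tables):
        for stem in ("Actrapid", "NPH", "Lente", "UltraLente"):
            for suffix in ("_pa", "_act"):
                table = tables[stem + suffix]
                assert table.values.shape == (41, GRID_POINTS)
                assert not table.values[0].any()

    def test_dose_kinetics_are_nonlinear(self, config, constants):
        # T50 grows with dose, so row(2d) is not 2*row(d)
        pa, _ = build_insulin_tables(
            config.class_params[AbsorptionClass.ACTRAPID_LIKE], constants)
        assert not np.allclose(pa.values[20], 2 * pa.values[10], rtol=1e-3)

    def test_periodic_closure_of_rows(self, tables):
        table = tables["UltraLente_pa"].values
        np.testing.assert_array_equal(table[:, 0], table[:, -1])


class TestCarbProfiles:
    def test_zero_grams_is_zero(self, constants):
        assert not gastric_emptying_profile(0, constants).any()

    @pytest.mark.parametrize("grams", [1, 40, 60, 80])
    def test_appearance_integral_matches_load(self, grams, constants):
        profile = gastric_emptying_profile(grams, constants)
        total = profile[:-1].sum() * 0.25  # mmol over the periodic day
        assert total == pytest.approx(grams * constants.carb_mmol_per_g, rel=0.01)

    def test_over_limit_rejected(self, constants):
        with pytest.raises(ProfileError, match="80"):
            gastric_emptying_profile(81, constants)
        with pytest.raises(ProfileError):
            gastric_emptying_profile(-1, constants)

    def test_table_shape_and_monotone_totals(self, tables):
        car = tables["CAR"].values
        assert car.shape == (81, GRID_POINTS)
        totals = car[:, :-1].sum(axis=1)
        assert (np.diff(totals) > 0).all()


class TestBiphasicSplit:
    @pytest.mark.parametrize("name,dose,expected", [
        ("Mixtard 30/70", 10.0, (3.0, 7.0)),
        ("Humulin 50/50", 10.0, (5.0, 5.0)),
        ("Mixtard 30/70", 0.0, (0.0, 0.0)),
    ])
    def test_split_ratio(self, name, dose, expected):
        short, inter = biphasic_split(dose, get_preparation(name))
        assert (short, inter) == expected

    def test_non_biphasic_rejected(self):
        with pytest.raises(ProfileError):
            biphasic_split(10.0, get_preparation("Actrapid"))


class TestRegistry:
    def test_category_cardinalities(self):
        registry = load_registry()
        counts = {}
        for prep in registry.values():
            counts[prep.category] = counts.get(prep.category, 0) + 1
        assert counts[InsulinCategory.SHORT] == 10
        assert counts[InsulinCategory.INTERMEDIATE] == 19
        assert counts[InsulinCategory.LONG] == 4
        assert counts[InsulinCategory.BIPHASIC] == 18

    def test_every_brand_resolves_once(self):
        registry = load_registry()
        assert len(registry) == 51
        for prep in registry.values():
            if prep.category is InsulinCategory.BIPHASIC:
                assert prep.absorption_class is None
                assert 1 <= prep.percent_short <= 99
            else:
                assert prep.absorption_class is not None

    def test_unknown_brand_raises(self):
        with pytest.raises(ProfileError, match="Novolog"):
            get_preparation("Novolog")


class TestFileRoundTrip:
    def test_write_then_read_is_identity(self, tables, tmp_path):
        fileset = write_profile_files(tables, tmp_path)
        assert sorted(p.name for p in tmp_path.iterdir()) == sorted(PROFILE_FILE_NAMES)
        back = read_profile_files(tmp_path)
        for name in PROFILE_FILE_NAMES:
            np.testing.assert_allclose(
                back[name].values, tables[name].values, atol=1e-9)
            assert back[name].kind == tables[name].kind

    def test_missing_member_is_named(self, tables, tmp_path):
        write_profile_files(tables, tmp_path)
        (tmp_path / "NPH_act").unlink()
        with pytest.raises(ProfileFileSetError, match="NPH_act"):
            read_profile_files(tmp_path)

    def test_malformed_row_reports_line(self, tables, tmp_path):
        write_profile_files(tables, tmp_path)
        path = tmp_path / "CAR"
        lines = path.read_text().splitlines()
        lines[3] = "1.0 2.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ProfileFileSetError, match="line 4"):
            read_profile_files(tmp_path)

    def test_incomplete_set_rejected_on_write(self, tables, tmp_path):
        partial = {k: v for k, v in tables.items() if k != "CAR"}
        with pytest.raises(ProfileFileSetError, match="CAR"):
            write_profile_files(partial, tmp_path)
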