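import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shelfbed.nutrients import (
    NUTRIENTS,
    LayerStructure,
    NutrientBedState,
    denitrification,
    nitrate_penetration,
    nitrification,
    oxygen_penetration,
    phosphate_partition,
    porewater_profile,
    rebin_layers,
    relax_exchange,
    silicate_dissolution,
    total_oxygen_uptake,
)


class TestOxygenPenetration:
    def test_anoxic_bottom_water(self):
        assert oxygen_penetration(1e-9, 0.0, 1e-3) == 0.0

    def test_closed_form_oracle(self):
        # sqrt(2 * 1e-9 * 250 / 1.25e-3) = sqrt(4e-4) = 0.02 m
        assert oxygen_penetration(1e-9, 250.0, 1.25e-3) == pytest.approx(0.02)

    def test_square_root_law_in_diffusivity(self):
        d1 = oxygen_penetration(1e-9, 250.0, 1.25e-3)
        d4 = oxygen_penetration(4e-9, 250.0, 1.25e-3)
        assert d4 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_zero_demand_caps_at_bed_depth(self):
        assert oxygen_penetration(1e-9, 250.0, 0.0, z_bed=0.25) == 0.25

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            oxygen_penetration(0.0, 250.0, 1e-3)
        with pytest.raises(ValueError):
            oxygen_penetration(1e-9, -1.0, 1e-3)


class TestTotalOxygenUptake:
    def test_zero(self):
        assert total_oxygen_uptake(0.0, 0.0, 0.0) == 0.0

    def test_carbon_conversion_oracle(self):
        # 0.06 g C / 12.011 g/mol * 1000 = 4.995 mmol O2 (1 mol O2 : 1 mol C)
        assert total_oxygen_uptake(0.06, 0.0, 0.0) == pytest.approx(4.9954, abs=1e-3)

    def test_nitrification_stoichiometry(self):
        base = total_oxygen_uptake(0.06, 0.0, 0.0)
        assert total_oxygen_uptake(0.06, 1.0, 0.0) == pytest.approx(base + 2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_oxygen_uptake(-0.1, 0.0, 0.0)


class TestNitrogenFluxes:
    def test_nitrification_zero_ammonium(self):
        assert nitrification(0.0, 0.1, 0.01) == 0.0

    def test_nitrification_product_oracle(self):
        assert nitrification(50.0, 0.1, 0.01) == pytest.approx(0.05)

    def test_denitrification_zero_biomass(self):
        # the winter nitrate build-up mechanism: no anaerobes, no removal
        assert denitrification(0.0, 40.0, 1e-3) == 0.0

    def test_denitrification_product_oracle(self):
        assert denitrification(0.5, 40.0, 1e-3) == pytest.approx(0.02)


class TestSilicateAndPhosphate:
    def test_dissolution_zero(self):
        assert silicate_dissolution(0.0, 0.005) == 0.0

    def test_dissolution_product(self):
        assert silicate_dissolution(100.0, 0.005) == pytest.approx(0.5)

    def test_partition_all_dissolved(self):
        assert phosphate_partition(100.0, 1.0) == (100.0, 0.0)

    def test_partition_oxic_example(self):
        dissolved, adsorbed = phosphate_partition(100.0, 0.2)
        assert dissolved == pytest.approx(20.0)
        assert adsorbed == pytest.approx(80.0)

    @settings(max_examples=30, deadline=None)
    @given(
        total=st.floats(min_value=0.0, max_value=1e4),
        pc=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_partition_conserves(self, total, pc):
        dissolved, adsorbed = phosphate_partition(total, pc)
        assert dissolved + adsorbed == pytest.approx(total, rel=1e-12, abs=1e-12)


class TestRelaxExchange:
    def test_at_equilibrium_nothing_happens(self):
        new, flux = relax_exchange(50.0, 50.0, 10.0, 1.0)
        assert new == 50.0 and flux == 0.0

    def test_long_step_reaches_equilibrium(self):
        new, _ = relax_exchange(100.0, 50.0, 1.0, 1000.0)
        assert new == pytest.approx(50.0)

    def test_closed_form_oracle(self):
        # 50 + 50 e^-0.1 = 95.2419
        new, flux = relax_exchange(100.0, 50.0, 10.0, 1.0)
        assert new == pytest.approx(95.2419, abs=1e-4)
        assert flux == pytest.approx(100.0 - new)  # positive out of the bed

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            relax_exchange(1.0, 0.0, 0.0, 1.0)


class TestNitratePenetration:
    def test_no_nitrate_collapses_to_d1(self):
        assert nitrate_penetration(0.0, 1e-6, 1e-9, 0.02) == 0.02

    def test_no_consumption_caps_at_bed_depth(self):
        assert nitrate_penetration(50.0, 0.0, 1e-9, 0.02, z_bed=0.25) == 0.25

    def test_square_root_law_in_consumption(self):
        d_a = nitrate_penetration(50.0, 1e-6, 1e-9, 0.02, z_bed=10.0) - 0.02
        d_b = nitrate_penetration(50.0, 4e-6, 1e-9, 0.02, z_bed=10.0) - 0.02
        assert d_b == pytest.approx(d_a / 2.0, rel=1e-12)


class TestPorewaterProfile:
    STRUCT = LayerStructure(D1=0.05, D2=0.1, z_bed=0.25, porosity=0.5)

    def test_uniform_layer_concentration(self):
        # 10 mmol/m^2 dissolved in a 0.1 m layer at porosity 0.5 -> 200 mmol/m^3
        struct = LayerStructure(D1=0.1, D2=0.2, z_bed=0.25, porosity=0.5)
        conc = porewater_profile(np.array([10.0, 0.0, 0.0]), struct, np.array([0.05]))
        assert conc[0] == pytest.approx(200.0)

    def test_depth_integral_recovers_content(self):
        contents = np.array([3.0, 7.0, 2.0])
        z = np.linspace(0.0, 0.25, 100_001)
        conc = porewater_profile(contents, self.STRUCT, z)
        total = np.trapezoid(conc * self.STRUCT.porosity, z)
        assert total == pytest.approx(contents.sum(), rel=1e-3)

    def test_grid_outside_bed_rejected(self):
        with pytest.raises(ValueError):
            porewater_profile(np.zeros(3), self.STRUCT, np.array([0.3]))

    def test_degenerate_layer_uses_neighbour(self):
        struct = LayerStructure(D1=0.0, D2=0.1, z_bed=0.25, porosity=0.5)
        conc = porewater_profile(np.array([0.0, 5.0, 0.0]), struct, np.array([0.0]))
        assert conc[0] == pytest.approx(5.0 / (0.5 * 0.1))


class TestRebinLayers:
    @settings(max_examples=40, deadline=None)
    @given(
        c=st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=3, max_size=3),
        d1=st.floats(min_value=0.005, max_value=0.1),
        d2=st.floats(min_value=0.11, max_value=0.24),
    )
    def test_mass_conserved(self, c, d1, d2):
        old = np.array([0.0, 0.02, 0.05, 0.25])
        new = np.array([0.0, d1, d2, 0.25])
        out = rebin_layers(np.array(c), old, new)
        assert out.sum() == pytest.approx(sum(c), rel=1e-9, abs=1e-9)
        assert np.all(out >= -1e-12)

    def test_identity_when_bounds_unchanged(self):
        bounds = np.array([0.0, 0.02, 0.05, 0.25])
        contents = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(rebin_layers(contents, bounds, bounds), contents)


class TestNutrientBedState:
    def test_mixing_conserves_and_smooths(self):
        struct = LayerStructure(D1=0.02, D2=0.05, z_bed=0.25, porosity=0.5)
        state = NutrientBedState()
        state.contents["NH4"] = np.array([10.0, 1.0, 1.0])
        before_total = state.total("NH4")
        before_spread = np.ptp(state.dissolved_conc("NH4", struct))
        state.mix_interlayer(struct, 1e-4, 1.0)
        assert state.total("NH4") == pytest.approx(before_total, rel=1e-12)
        assert np.ptp(state.dissolved_conc("NH4", struct)) <= before_spread

    def test_equilibrium_content_definition(self):
        struct = LayerStructure(D1=0.02, D2=0.05, z_bed=0.25, porosity=0.5)
        state = NutrientBedState()
        # dissolved equilibrium = bw * porosity * thickness; total = /pc
        eq = state.equilibrium_content("PO4", 1.0, struct)
        assert eq == pytest.approx(1.0 * 0.5 * 0.02 / state.partition["PO4"][0])

    def test_layer_structure_validation(self):
        with pytest.raises(ValueError):
            LayerStructure(D1=0.1, D2=0.05)
        with pytest.raises(ValueError):
            LayerStructure(porosity=1.5)
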