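import dataclasses

import numpy as np
import pytest

from shelfbed.biota import (
    GROUPS,
    BiotaState,
    GroupParams,
    StepSizeError,
    bioturbation_index,
    default_group_params,
    redfield_biomass,
    step_biota,
    temperature_factor,
    uptake_flux,
)
from shelfbed.organic_matter import OMPools, element_vector


def _forcing(detritus=0.0, temp=10.0):
    n_flux = detritus * 83.26 * 16 / 106
    return {
        "bottom_temperature": temp,
        "detritus_C_flux": detritus,
        "detritus_N_flux": n_flux,
        "detritus_P_flux": n_flux / 16.0,
        "detritus_Si_flux": detritus * 83.26 * 15 / 106,
    }


def _om(dom=1.0, semi=2.0, refr=10.0):
    def pool(c):
        v = redfield_biomass(c)
        v[3] = c * 10.0
        return v

    return OMPools(
        dom_labile=pool(dom), pom_semilabile=pool(semi), pom_refractory=pool(refr)
    )


class TestUptakeFlux:
    def test_zero_resources(self):
        params = default_group_params()["deposit_feeders"]
        out = uptake_flux(1.0, {}, params, 10.0)
        assert all(v == 0.0 for v in out.values())

    def test_saturation_limit(self):
        params = GroupParams(
            max_uptake_rate=0.5,
            half_saturation=1.0,
            assimilation_efficiency=0.5,
            basal_respiration=0.0,
            background_mortality=0.0,
            diet=(("pom_semilabile", 1.0),),
        )
        out = uptake_flux(2.0, {"pom_semilabile": 1e9}, params, 10.0)
        assert out["pom_semilabile"] == pytest.approx(0.5 * 2.0, rel=1e-6)

    def test_reference_temperature_factor(self):
        assert temperature_factor(2.0, 10.0) == 1.0
        assert temperature_factor(2.0, 20.0) == 2.0


class TestStepBiota:
    def test_all_rates_zero_leaves_state_unchanged(self):
        params = {
            g: GroupParams(
                max_uptake_rate=0.0,
                half_saturation=1.0,
                assimilation_efficiency=0.5,
                basal_respiration=0.0,
                background_mortality=0.0,
                diet=(("pom_semilabile", 1.0),),
            )
            for g in GROUPS
        }
        state = BiotaState()
        om = _om()
        new, om2, fx = step_biota(state, om, _forcing(), params=params)
        for g in GROUPS:
            np.testing.assert_allclose(new.pools[g], state.pools[g])
        np.testing.assert_allclose(om2.pom_semilabile, om.pom_semilabile)
        assert fx.respiration_aerobic_C == 0.0

    def test_carbon_budget_closes(self):
        state = BiotaState()
        om = _om()
        f = _forcing(detritus=0.5, temp=12.0)
        before = state.total()[0] + om.total()[0]
        new, om2, fx = step_biota(state, om, f, dt=1.0, D1=0.02)
        after = new.total()[0] + om2.total()[0]
        respired = fx.respiration_aerobic_C + fx.respiration_anaerobic_C
        consumed = fx.detritus_consumed[0]
        assert after - before == pytest.approx(consumed - respired, abs=1e-10)

    def test_nitrogen_budget_closes(self):
        state = BiotaState()
        om = _om()
        f = _forcing(detritus=0.5, temp=12.0)
        before = state.total()[1] + om.total()[1]
        new, om2, fx = step_biota(state, om, f, dt=1.0, D1=0.02)
        after = new.total()[1] + om2.total()[1]
        excreted = (
            fx.excretion_NH4_oxic + fx.excretion_NH4_deep
        )
        assert after - before == pytest.approx(
            fx.detritus_consumed[1] - excreted, abs=1e-10
        )

    def test_nonnegative_after_heavy_grazing(self):
        state = BiotaState(pools={g: redfield_biomass(50.0) for g in GROUPS})
        om = _om(dom=0.01, semi=0.01, refr=0.01)
        new, om2, _ = step_biota(state, om, _forcing(temp=20.0))
        for g in GROUPS:
            assert new.pools[g][0] >= 0.0
        assert om2.dom_labile[0] >= 0.0
        assert om2.pom_semilabile[0] >= 0.0

    def test_step_size_guard(self):
        with pytest.raises(StepSizeError):
            step_biota(BiotaState(), _om(), _forcing(), dt=5.0)

    def test_higher_mortality_lowers_deposit_feeder_equilibrium(self):
        # x4 mortality (0.001 -> 0.004, the published scenario delta) must
        # strictly lower the equilibrium biomass under fixed forcing
        def run(mort):
            params = default_group_params()
            params["deposit_feeders"] = dataclasses.replace(
                params["deposit_feeders"], background_mortality=mort
            )
            state, om = BiotaState(), _om(dom=0.5, semi=4.0, refr=10.0)
            f = _forcing(detritus=0.05)
            for _ in range(1500):
                om.dom_labile += element_vector(C=0.005)
                om.pom_semilabile += redfield_biomass(0.03)
                state, om, _ = step_biota(state, om, f, params=params)
            return state.biomass("deposit_feeders")

        assert run(0.004) < run(0.001)


class TestBioturbationIndex:
    def test_zero_fauna(self):
        state = BiotaState(pools={g: redfield_biomass(0.0) for g in GROUPS})
        assert bioturbation_index(state) == 0.0

    def test_single_weight_selects_deposit_feeders(self):
        state = BiotaState()
        idx = bioturbation_index(state, weights=(1.0, 0.0, 0.0))
        assert idx == pytest.approx(state.biomass("deposit_feeders"))

    def test_linearity(self):
        s1 = BiotaState(pools={g: redfield_biomass(0.2) for g in GROUPS})
        s2 = BiotaState(pools={g: redfield_biomass(0.4) for g in GROUPS})
        assert bioturbation_index(s2) == pytest.approx(2 * bioturbation_index(s1))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            bioturbation_index(BiotaState(), weights=(-1.0, 0.0, 0.0))


class TestGroupParamsValidation:
    def test_efficiency_bounds(self):
        with pytest.raises(ValueError):
            GroupParams(
                max_uptake_rate=0.1,
                half_saturation=1.0,
                assimilation_efficiency=1.5,
                basal_respiration=0.0,
                background_mortality=0.0,
            )

    def test_diet_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GroupParams(
                max_uptake_rate=0.1,
                half_saturation=1.0,
                assimilation_efficiency=0.5,
                basal_respiration=0.0,
                background_mortality=0.0,
                diet=(("dom_labile", 0.5), ("pom_semilabile", 0.3)),
            )
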