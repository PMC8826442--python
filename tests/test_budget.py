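"""Allometric chain: individual laws, unit conversions, community aggregation."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spongeground as sg
from spongeground.budget import AllometryParams, calibrate_unit_scales, community_budget


class TestIndividualBiomass:
    def test_cubic_law(self):
        assert sg.individual_biomass(10.0).ww_kg == pytest.approx(0.3)

    def test_full_chain_at_median_size(self):
        b = sg.individual_biomass(17.0)
        assert b.ww_kg == pytest.approx(1.4739, abs=1e-4)
        assert b.dw_kg == pytest.approx(0.2756, abs=1e-4)
        assert b.c_kg == pytest.approx(0.0827, abs=1e-4)
        assert b.volume_L == pytest.approx(1.4739, abs=1e-4)

    def test_vanishing_limit(self):
        b = sg.individual_biomass(1e-6)
        assert b.ww_kg < 1e-15 and b.c_kg < 1e-15

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            sg.individual_biomass(0.0)

    def test_volume_interpretation_switch(self):
        p = AllometryParams(length_law_output="volume_L", ww_per_litre=1.1)
        b = sg.individual_biomass(10.0, p)
        assert b.volume_L == pytest.approx(0.3)
        assert b.ww_kg == pytest.approx(0.33)


class TestRateLaws:
    def test_pumping_identity_at_unit_volume(self):
        assert sg.individual_pumping(1.0) == pytest.approx(0.4952)

    def test_pumping_total_increases_with_volume(self):
        vols = np.linspace(0.1, 50, 40)
        totals = [sg.individual_pumping(v) for v in vols]
        assert np.all(np.diff(totals) > 0)

    def test_respiration_identity_at_unit_volume(self):
        assert sg.individual_respiration(1.0) == pytest.approx(25.5)

    def test_respiration_at_six_litres(self):
        total = sg.individual_respiration(6.0)
        assert total / 6.0 == pytest.approx(16.88, abs=0.01)  # volume-specific
        assert total == pytest.approx(101.3, abs=0.1)

    def test_doubling_volume_scales_by_net_exponent(self):
        ratio = sg.individual_respiration(2.0) / sg.individual_respiration(1.0)
        assert ratio == pytest.approx(2**0.77, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            sg.individual_pumping(-1.0)
        with pytest.raises(ValueError):
            sg.individual_respiration(0.0)


class TestScalarConversions:
    @pytest.mark.parametrize(
        "flux,rq,expected",
        [(25.0, 1.0, 109.60), (25.0, 0.77, 84.39), (0.0, 1.0, 0.0)],
    )
    def test_annual_carbon_demand(self, flux, rq, expected):
        assert sg.annual_carbon_demand(flux, rq) == pytest.approx(expected, abs=0.01)

    @given(f=st.floats(0, 100), rq=st.floats(0.1, 1.5))
    def test_demand_is_bilinear(self, f, rq):
        base = sg.annual_carbon_demand(1.0, 1.0)
        assert sg.annual_carbon_demand(f, rq) == pytest.approx(f * rq * base, rel=1e-12)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError):
            sg.annual_carbon_demand(-1.0)

    def test_water_column_height(self):
        assert sg.water_column_height(1640.0) == pytest.approx(598.6)
        assert sg.water_column_height(0.0) == 0.0
        assert sg.water_column_height(1e6 / 365.0) == pytest.approx(1000.0, rel=1e-12)

    def test_export_coverage(self):
        assert sg.export_coverage(110.0, 1.0) == pytest.approx(0.909, abs=1e-3)
        assert sg.export_coverage(110.0, 0.0) == 0.0
        assert sg.export_coverage(110.0, 110.0) == 100.0
        with pytest.raises(ValueError):
            sg.export_coverage(0.0, 1.0)


class TestCommunityBudget:
    def test_single_median_sponge_carbon_stock(self, image_factory):
        rep = community_budget([image_factory([17.0], area=1.0)])
        assert rep.overall.c_g_m2 == pytest.approx(82.69, abs=0.01)

    def test_chain_identities_exact(self, image_factory):
        images = [
            image_factory([12.0, 30.0, 55.0], area=4.0, category="c", image_id="c1"),
            image_factory([8.0, 17.0], area=4.0, category="d", image_id="d1"),
        ]
        p = AllometryParams()
        rep = community_budget(images, p, areas={"c": 15.0, "d": 2.5})
        for cb in [*rep.per_category.values(), rep.overall]:
            assert cb.dw_kg_m2 == pytest.approx(cb.ww_kg_m2 * p.dw_ww_ratio, rel=1e-12)
            assert cb.c_g_m2 == pytest.approx(
                cb.dw_kg_m2 * p.c_dw_frac * 1000.0, rel=1e-12
            )

    def test_adding_individual_strictly_increases_totals(self, image_factory):
        small = community_budget([image_factory([17.0])])
        big = community_budget([image_factory([17.0, 5.0])])
        for attr in ("c_g_m2", "pumping_L_m2_d", "respiration_mmol_m2_d"):
            assert getattr(big.overall, attr) > getattr(small.overall, attr)

    def test_doubling_density_doubles_per_m2_rates(self, image_factory):
        lengths = [10.0, 20.0, 35.0]
        one = community_budget([image_factory(lengths, area=2.0)])
        two = community_budget([image_factory(lengths * 2, area=2.0)])
        for attr in ("ww_kg_m2", "c_g_m2", "pumping_L_m2_d", "respiration_mmol_m2_d"):
            assert getattr(two.overall, attr) == pytest.approx(
                2 * getattr(one.overall, attr), rel=1e-12
            )

    def test_zero_density_category_contributes_nothing(self, image_factory):
        im_empty = image_factory([], category="b", image_id="b1")
        rep = community_budget([im_empty])
        assert rep.overall.c_g_m2 == 0.0
        assert rep.overall.respiration_mmol_m2_d == 0.0

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError):
            community_budget([])


class TestCalibration:
    def test_targets_hit_and_recorded(self, categories):
        df = sg.generate_survey(categories, n_images=100, seed=13)
        from spongeground.survey import images_from_table

        images = images_from_table(df)
        areas = {c.label: c.area_km2 for c in categories}
        params = calibrate_unit_scales(images, AllometryParams(), areas)
        assert params.resp_unit_scale > 1.0  # raw law units underestimate the flux
        cd = [im for im in images if im.category in ("c", "d")]
        rep = community_budget(cd, params, areas={"c": 15.0, "d": 2.5})
        assert rep.overall.respiration_mmol_m2_d == pytest.approx(25.0, rel=1e-9)
        d_only = community_budget(
            [im for im in images if im.category == "d"], params, areas={"d": 2.5}
        )
        assert d_only.overall.pumping_L_m2_d == pytest.approx(1640.0, rel=1e-9)
        assert rep.metadata["resp_unit_scale"] == params.resp_unit_scale

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AllometryParams(dw_ww_ratio=1.5)
        with pytest.raises(ValueError):
            AllometryParams(rq=0.0)
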