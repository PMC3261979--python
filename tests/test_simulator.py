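"""Simulation: conservation laws, solver quality, variant equivalences."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mixkin import (
    ConfigurationError,
    DomainError,
    ExposureScenario,
    MicroconstantSet,
    SolverSettings,
    build_type1_pathway,
    build_type2_pathway,
    build_type3_pathway,
    compose,
    default_physiology,
    default_transport,
    michaelis_reduction,
    mixture_interaction_ratio,
    simulate,
)
from mixkin.pbpk import PhysiologyParams, derive_dependent_params


def _compose_single(pathway, totals):
    return compose([pathway], default_physiology(),
                   {pathway.chemical_id: default_transport(pathway.chemical_id)}, totals)


class TestScenario:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ConfigurationError):
            ExposureScenario({"benzene": ((0.0, 100.0, 50.0), (50.0, 150.0, 50.0))}, 200.0)

    def test_negative_ppm_rejected(self):
        with pytest.raises(ConfigurationError):
            ExposureScenario({"benzene": ((0.0, 100.0, -1.0),)}, 200.0)

    def test_ppm_lookup_half_open(self):
        s = ExposureScenario.constant({"benzene": 100.0}, 240.0, 360.0)
        assert s.ppm_at("benzene", 239.99) == 100.0
        assert s.ppm_at("benzene", 240.0) == 0.0


class TestBasicSimulation:
    def test_zero_exposure_stays_zero(self, benzene_model):
        scen = ExposureScenario.constant({"benzene": 0.0}, 240.0, 360.0)
        res = simulate(benzene_model, scen, grid=60.0)
        assert np.all(res.venous("benzene") == 0.0)
        assert np.all(res.states[:, :6] == 0.0)

    def test_cumulative_metabolized_nondecreasing(self, btex_model):
        scen = ExposureScenario.constant({c: 50.0 for c in btex_model.chemicals})
        res = simulate(btex_model, scen, grid=10.0)
        for c in btex_model.chemicals:
            met = res.cumulative_metabolized(c)
            assert np.all(np.diff(met) >= -1e-9 * met[-1])

    def test_states_nonnegative_within_tolerance(self, btex_model):
        scen = ExposureScenario.constant({c: 50.0 for c in btex_model.chemicals})
        res = simulate(btex_model, scen, grid=10.0)
        assert res.diagnostics["min_state"] > -1e-6

    def test_mg_per_l_conversion(self, benzene_model):
        scen = ExposureScenario.constant({"benzene": 100.0})
        res = simulate(benzene_model, scen, grid=[0.0, 240.0, 360.0])
        np.testing.assert_allclose(res.venous_mg_per_l("benzene"),
                                   res.venous("benzene") * 78.11e-3)

    def test_unknown_scenario_chemical_rejected(self, benzene_model):
        scen = ExposureScenario.constant({"toluene": 100.0})
        with pytest.raises(ConfigurationError):
            simulate(benzene_model, scen)


class TestConservation:
    def test_enzyme_conservation_along_trajectory(self, btex_model):
        scen = ExposureScenario.constant(
            {"benzene": 100.0, "toluene": 50.0, "ethylbenzene": 50.0, "m_xylene": 50.0})
        res = simulate(btex_model, scen, grid=5.0)
        assert res.enzyme_conservation_residual() < 1e-6

    def test_mass_balance_against_quadrature(self, benzene_model):
        """Inhaled-minus-exhaled integral matches body burden to < 0.1%."""
        scen = ExposureScenario.constant({"benzene": 100.0})
        res = simulate(benzene_model, scen, grid=0.5)
        assert res.mass_balance_residual("benzene") < 1e-3


class TestSolverQuality:
    def test_tolerance_refinement_converged(self, benzene_model):
        """Refining tolerances 10x moves venous concentrations by < 0.01%."""
        scen = ExposureScenario.constant({"benzene": 100.0})
        grid = [0.0, 120.0, 240.0, 300.0, 360.0]
        a = simulate(benzene_model, scen, SolverSettings(rtol=1e-6, atol=1e-9), grid)
        b = simulate(benzene_model, scen, SolverSettings(rtol=1e-7, atol=1e-10), grid)
        va, vb = a.venous("benzene")[1:], b.venous("benzene")[1:]
        assert np.max(np.abs(va - vb) / vb) < 1e-4

    def test_agrees_with_scipy_lsoda(self, benzene_model):
        """Independent route: scipy LSODA on the reference RHS, segment by segment."""
        scen = ExposureScenario.constant({"benzene": 100.0}, 60.0, 90.0)
        res = simulate(benzene_model, scen, SolverSettings(rtol=1e-8, atol=1e-11),
                       grid=[0.0, 60.0, 90.0])
        y = benzene_model.y0.copy()
        for t0, t1, ppm in ((0.0, 60.0, 100.0), (60.0, 90.0, 0.0)):
            c_inh = np.array([ppm * 1e3 / 24450.0])
            sol = solve_ivp(lambda t, yy: benzene_model.rhs(t, yy, c_inh),
                            (t0, t1), y, method="LSODA", rtol=1e-8, atol=1e-11)
            y = sol.y[:, -1]
        mine = res.states[-1]
        scale = np.abs(y).max()
        assert np.max(np.abs(mine - y)) / scale < 1e-5


class TestVariantEquivalences:
    def test_type2_with_empty_second_pool_equals_type1(self):
        k = MicroconstantSet(k1=39.0, k2=1040.0, k3=7.8)
        m1 = _compose_single(build_type1_pathway("benzene", k), {"CYP2E1": 20.9})
        m2 = _compose_single(build_type2_pathway("benzene", k),
                             {"CYP2E1": 20.9, "CYPX": 0.0})
        scen = ExposureScenario.constant({"benzene": 100.0})
        grid = [0.0, 120.0, 240.0, 360.0]
        settings = SolverSettings(rtol=1e-8, atol=1e-11)
        v1 = simulate(m1, scen, settings, grid).venous("benzene")
        v2 = simulate(m2, scen, settings, grid).venous("benzene")
        np.testing.assert_allclose(v2[1:], v1[1:], rtol=1e-6)

    def test_type3_with_null_metabolite_branch_equals_type1(self):
        k = MicroconstantSet(k1=39.0, k2=1040.0, k3=7.8)
        k3_null = MicroconstantSet(k1=39.0, k2=1040.0, k3=7.8,
                                   km1=0.0, km2=0.0, km3=0.0, kh=0.0)
        m1 = _compose_single(build_type1_pathway("benzene", k), {"CYP2E1": 20.9})
        m3 = _compose_single(build_type3_pathway("benzene", k3_null), {"CYP2E1": 20.9})
        scen = ExposureScenario.constant({"benzene": 100.0})
        grid = [0.0, 120.0, 240.0, 360.0]
        settings = SolverSettings(rtol=1e-8, atol=1e-11)
        v1 = simulate(m1, scen, settings, grid).venous("benzene")
        v3 = simulate(m3, scen, settings, grid).venous("benzene")
        np.testing.assert_allclose(v3[1:], v1[1:], rtol=1e-6)

    def test_type3_metabolite_matter_conserved_when_kh_zero(self):
        """With kh = 0 the metabolite subsystem is closed: mass balance still holds."""
        k = MicroconstantSet(k1=39.0, k2=1040.0, k3=7.8, kh=0.0)
        m3 = _compose_single(build_type3_pathway("benzene", k), {"CYP2E1": 20.9})
        scen = ExposureScenario.constant({"benzene": 100.0})
        res = simulate(m3, scen, grid=0.5)
        assert res.mass_balance_residual("benzene") < 1e-3


def test_michaelis_menten_limit_of_initial_velocity():
    """Isolated liver, E << S: velocity matches Vmax*S/(Km+S) within 5%."""
    k = MicroconstantSet(k1=39.0, k2=1040.0, k3=7.8)
    pathway = build_type1_pathway("benzene", k)
    phys = derive_dependent_params(PhysiologyParams(
        alveolar_ventilation=1e-9, cardiac_output=1e-9,
        flow_fractions={"liver": 0.25, "fat": 0.09, "poor": 0.15},
        body_volume=250.0,
        tissue_volumes={"liver": 10.0, "fat": 17.5, "rich": 12.5}))
    e_total = 0.2
    model = compose([pathway], phys, {"benzene": default_transport("benzene")},
                    {"CYP2E1": e_total})
    mm = michaelis_reduction(model)["benzene"]
    liver = model.index("benzene", "Q_liver")
    cx = model.index("benzene", "benzene.CYP2E1")
    c_inh = np.zeros(1)
    for s0 in np.geomspace(0.1 * mm.km, 10 * mm.km, 5):
        y0 = model.y0.copy()
        y0[liver] = s0
        sol = solve_ivp(lambda t, y: model.rhs(t, y, c_inh), (0.0, 0.01), y0,
                        method="LSODA", rtol=1e-9, atol=1e-12)
        velocity = 7.8 * sol.y[cx, -1]  # k3 * complex at quasi-steady state
        expected = mm.vmax * s0 / (mm.km + s0)
        assert velocity == pytest.approx(expected, rel=0.05)


class TestInteractionRatio:
    def test_single_chemical_mixture_ratio_is_one(self, btex_model):
        mix = ExposureScenario.constant(
            {"benzene": 100.0, "toluene": 0.0, "ethylbenzene": 0.0, "m_xylene": 0.0})
        single = ExposureScenario.constant({"benzene": 100.0})
        r = mixture_interaction_ratio(btex_model, mix, {"benzene": single}, 240.0)
        assert r["benzene"] == pytest.approx(1.0, rel=1e-6)

    def test_competition_never_reduces_concentration(self, btex_model):
        """Purely competitive type I: co-exposure ratios are >= 1 everywhere."""
        ppm = {"benzene": 100.0, "toluene": 50.0, "ethylbenzene": 50.0, "m_xylene": 50.0}
        mix = ExposureScenario.constant(ppm)
        singles = {c: ExposureScenario.constant({c: ppm[c]}) for c in ppm}
        ratios = mixture_interaction_ratio(btex_model, mix, singles, 240.0)
        assert all(r >= 1.0 - 1e-9 for r in ratios.values())

    def test_mismatched_single_scenario_rejected(self, btex_model):
        mix = ExposureScenario.constant({"benzene": 100.0})
        single = ExposureScenario.constant({"benzene": 50.0})
        with pytest.raises(ConfigurationError):
            mixture_interaction_ratio(btex_model, mix, {"benzene": single}, 240.0)

    def test_zero_single_exposure_is_undefined(self, btex_model):
        mix = ExposureScenario.constant({"benzene": 0.0})
        single = ExposureScenario.constant({"benzene": 0.0})
        with pytest.raises(DomainError):
            mixture_interaction_ratio(btex_model, mix, {"benzene": single}, 240.0)
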