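"""Cumulated activity, per-cell activity, S-values and scenario doses."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import celldose as cd
from celldose.dosimetry import (ASSAY_DURATIONS_S, ActivitySchedule, SValue,
                                medium_s_value, scenario_preset)
from celldose.transport import TransportConfig

TP = 6.647  # days


def atilde(a0, dt_s):
    return cd.time_integrated_activity(ActivitySchedule(a0, TP, dt_s))


class TestTimeIntegratedActivity:
    def test_zero_duration(self):
        assert atilde(1.0, 0.0) == 0.0

    def test_saturation_limit_is_mean_life(self):
        # A0 T_p / ln 2, i.e. the rounded 1.44 T_p A0 form
        assert atilde(1.0, 1e4 * 86400) == pytest.approx(
            TP * 86400 / math.log(2.0), rel=1e-9)
        assert atilde(1.0, 1e4 * 86400) == pytest.approx(8.27e5, rel=5e-3)

    def test_half_life_gives_072_factor(self):
        # A_tilde(T_p) = T_p A0 / (2 ln 2) = 0.72 T_p A0
        assert atilde(1.0, TP * 86400) == pytest.approx(
            0.72 * TP * 86400, rel=5e-3)

    def test_4h_value(self):
        # 1.42e4 to three figures under the rounded 1.44/0.693 constants
        assert atilde(1.0, 4 * 3600) == pytest.approx(1.42e4, rel=0.01)

    def test_matches_numerical_decay_integral(self):
        lam = math.log(2.0) / (TP * 86400)
        for dt in (3600.0, 4 * 3600.0, 14 * 86400.0):
            oracle, _ = quad(lambda t: math.exp(-lam * t), 0.0, dt)
            assert atilde(1.0, dt) == pytest.approx(oracle, rel=1e-9)

    def test_concave_increasing_bounded(self):
        ts = np.linspace(0, 30 * 86400, 200)
        vals = np.array([atilde(1.0, t) for t in ts])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(vals, 2) < 1e-9)
        assert vals[-1] < TP * 86400 / math.log(2.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ActivitySchedule(-1.0, TP, 10.0)


class TestPerCellActivity:
    def test_zero_fraction(self, model):
        assert cd.per_cell_activity(1e6, 0.0, model) == 0.0

    def test_volume_share_value(self, model):
        # 0.7 MBq x V_cell / 200 uL
        got = cd.per_cell_activity(1e6, 0.7, model, "volume_share")
        assert got == pytest.approx(2.9e-2, rel=0.02)

    def test_per_seeded_cell_value(self, model):
        got = cd.per_cell_activity(1e6, 0.7, model, "per_seeded_cell",
                                   n_cells=50_000)
        assert got == pytest.approx(14.0)

    def test_unknown_convention(self, model):
        with pytest.raises(ValueError, match="convention"):
            cd.per_cell_activity(1.0, 0.5, model, "per_well")


class TestSValues:
    def test_1keV_nucleus_self_svalue_closed_form(self, model, rng):
        sv = cd.s_value("nucleus", "nucleus", "mono", model,
                        TransportConfig(), 10_000, rng, energy_keV=1.0,
                        particle_kind="electron")
        expected = 1.0 * 1.602176634e-16 / model.region_mass_kg("nucleus")
        assert sv.gy_per_decay == pytest.approx(expected, rel=0.01)

    def test_zero_yield_component_gives_zero(self, model, rng):
        sp = cd.EmissionSpectrum("X", 1.0, None,
                                 [cd.EmissionLine("gamma", 100.0, 0.0)])
        sv = cd.s_value("nucleus", "nucleus", "gamma", model,
                        TransportConfig(), 200, rng, spectrum=sp)
        assert sv.gy_per_decay == 0.0

    def test_distance_monotonicity(self, scenario_svalues):
        model, svs = scenario_svalues
        assert svs[("nucleus", "nucleus")].gy_per_decay \
            > svs[("cytoplasm", "nucleus")].gy_per_decay \
            > svs[("medium", "nucleus")].gy_per_decay

    def test_medium_bath_svalue_scale(self, model, lu):
        # equilibrium: absorbed energy per decay over the 200 uL mass
        sv = medium_s_value(model, lu)
        e_el = sum(cd.mean_energy_per_decay(lu, c)
                   for c in ("beta", "auger", "ic"))
        low = e_el * 1.602176634e-16 / 2e-4
        high = cd.mean_energy_per_decay(lu, "all") * 1.602176634e-16 / 2e-4
        assert low <= sv.gy_per_decay <= high


class TestCompartmentFractions:
    def test_constant_70_percent(self):
        up = pd.DataFrame({"internalized_pct": [70.0, 70.0, 70.0]})
        got = cd.derive_compartment_fractions(up)
        assert got["internalized"] == pytest.approx(0.70)
        assert got["medium"] == pytest.approx(0.30)

    def test_all_zero(self):
        up = pd.DataFrame({"internalized_pct": [0.0, 0.0]})
        assert cd.derive_compartment_fractions(up)["medium"] == 1.0

    def test_arithmetic_mean(self):
        up = pd.DataFrame({"internalized_pct": [60.0, 70.0, 80.0]})
        assert cd.derive_compartment_fractions(up)["internalized"] == \
            pytest.approx(0.70)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            cd.derive_compartment_fractions(pd.DataFrame(
                {"internalized_pct": []}))


def _analytic_svalues():
    """Synthetic S-value set for algebra-only scenario tests."""
    vals = {("nucleus", "cell"): 1.6e-4, ("nucleus", "nucleus"): 1.1e-3,
            ("cytoplasm", "cell"): 1.3e-4, ("cytoplasm", "nucleus"): 1.0e-4,
            ("medium", "cell"): 1.2e-10, ("medium", "nucleus"): 1.2e-10}
    return {k: SValue(k[0], k[1], "all", v) for k, v in vals.items()}


class TestScenarioDose:
    def test_zero_activity_zero_dose(self, model):
        rep = cd.scenario_dose(scenario_preset("1"), 0.0,
                               _analytic_svalues(), model)
        assert rep.dose_Gy["cell"] == 0.0

    def test_linear_in_a0(self, model):
        svs = _analytic_svalues()
        r1 = cd.scenario_dose(scenario_preset("2"), 1e6, svs, model)
        r2 = cd.scenario_dose(scenario_preset("2"), 2e6, svs, model)
        assert r2.dose_Gy["cell"] == pytest.approx(2 * r1.dose_Gy["cell"],
                                                   rel=1e-12)

    def test_nucleus_scenario_beats_cytoplasm(self, scenario_svalues):
        model, svs = scenario_svalues
        r1 = cd.scenario_dose(scenario_preset("1"), 1e6, svs, model)
        r2 = cd.scenario_dose(scenario_preset("2"), 1e6, svs, model)
        assert r1.dose_Gy["nucleus"] > r2.dose_Gy["nucleus"]

    def test_clonogenic_dose_exceeds_mtt(self, scenario_svalues):
        model, svs = scenario_svalues
        for name in ("1", "2", "1_efflux", "2_efflux", "cmo"):
            rc = cd.scenario_dose(scenario_preset(name, "clonogenic"), 1e6,
                                  svs, model)
            rm = cd.scenario_dose(scenario_preset(name, "mtt"), 1e6, svs,
                                  model)
            assert rc.dose_Gy["cell"] >= rm.dose_Gy["cell"]

    def test_cmo_matches_equilibrium_estimate(self, scenario_svalues, lu):
        # large-medium charged-particle-equilibrium oracle
        model, svs = scenario_svalues
        rep = cd.scenario_dose(scenario_preset("cmo"), 1e6, svs, model)
        e_dep = cd.mean_energy_per_decay(lu, "all")
        oracle = atilde(1e6, 4 * 3600) * e_dep * 1.602176634e-16 / 2e-4
        assert rep.dose_Gy["cell"] == pytest.approx(oracle, rel=0.20)

    def test_missing_svalue_names_pair(self, model):
        svs = _analytic_svalues()
        del svs[("medium", "cell")]
        with pytest.raises(KeyError, match="medium"):
            cd.scenario_dose(scenario_preset("cmo"), 1e6, svs, model)

    def test_internalized_fraction_recovery(self, model):
        # algebraic consistency: invert the dose for the input fraction
        svs = _analytic_svalues()
        f_true = 0.7

        def dose(f):
            d = ASSAY_DURATIONS_S["clonogenic"]
            scn = cd.Scenario("custom", "clonogenic",
                              (("nucleus", f, d["internal"]),
                               ("medium", 1 - f, d["medium"])))
            return cd.scenario_dose(scn, 1e6, svs, model).dose_Gy["cell"]

        d0, d1 = dose(0.0), dose(1.0)
        f_hat = (dose(f_true) - d0) / (d1 - d0)
        assert f_hat == pytest.approx(f_true, abs=1e-6)


class TestDoseRatio:
    def test_identity(self, model):
        rep = cd.scenario_dose(scenario_preset("1"), 1e6,
                               _analytic_svalues(), model)
        assert cd.dose_ratio(rep, rep) == 1.0

    def test_efflux_ratio_matches_analytic_medium_dominated_value(
            self, scenario_svalues):
        # 0.3 + 0.7 Atilde(14 d) / Atilde(4 h) ~ 31.5 under the
        # volume-share convention (internalized term negligible)
        model, svs = scenario_svalues
        r_eff = cd.scenario_dose(scenario_preset("1_efflux"), 1e6, svs, model)
        r_cmo = cd.scenario_dose(scenario_preset("cmo"), 1e6, svs, model)
        expected = 0.3 + 0.7 * atilde(1.0, 14 * 86400) / atilde(1.0, 4 * 3600)
        assert cd.dose_ratio(r_eff, r_cmo) == pytest.approx(expected, rel=0.10)

    def test_zero_denominator_raises(self, model):
        svs = _analytic_svalues()
        r = cd.scenario_dose(scenario_preset("1"), 1e6, svs, model)
        z = cd.scenario_dose(scenario_preset("cmo"), 0.0, svs, model)
        with pytest.raises(ZeroDivisionError):
            cd.dose_ratio(r, z)
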