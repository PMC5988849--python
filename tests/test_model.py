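"""Model assembly: parameters, interventions, cascade rate laws, Ca fluxes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from angiotriad.model import (
    PARAMETER_TABLE,
    CascadeDynamics,
    InitialState,
    InterventionSpec,
    ParameterSet,
    build_model,
    calcium_fluxes,
    downstream_rules,
    nominal_parameters,
)
from angiotriad.rulegraph import ValidationError, canonical_label


REPORTED_SENSITIVITY_SYMBOLS = [
    # receptor layer
    "ksingleR2_syn", "kVEGFNRP1_on", "kVEGFR2NRP1_off", "kr2_si", "kd_RR",
    "kdp_s", "kdp_i", "kdeg_i0", "kdeg_i0noP",
    # cascade
    "Src_0", "Axl_0", "PI3K_0", "PTEN_0", "PIP2_0",
    "kp_SrcAxl", "kp_Axlauto", "kdp_SrcAxl", "kdp_autoAxl",
    "kon_PI3KAxl", "koff_PI3KAxl", "kcat_PI3KPIP2", "km_PIP2PI3K",
    "kcat_PTENPIP3", "km_PIP3PTEN",
    # calcium / eNOS
    "kcat_PLCgDAG", "kdeg_ip3", "ICRAC_amp", "Iip3R_amp", "v_SERCA",
    "IPMCA_amp", "kon_eNOSCaCaM",
]


class TestParameterSet:
    def test_every_sensitivity_symbol_present_once(self):
        params = nominal_parameters()
        for name in REPORTED_SENSITIVITY_SYMBOLS:
            assert name in params
        # dict semantics guarantee uniqueness; table and set agree
        assert set(params) == set(PARAMETER_TABLE)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            ParameterSet({"kp_R2": -1.0})

    def test_hook_ranges_enforced(self):
        with pytest.raises(ValidationError):
            ParameterSet({"fTSP1_i2r": 1.5})
        with pytest.raises(ValidationError):
            ParameterSet({"fTSP1_deg": 0.5})

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValidationError):
            ParameterSet({"not_a_parameter": 1.0})

    def test_kd_derived_consistently(self):
        p = nominal_parameters()
        assert p.kd_tsp1_cd47_nM == p["koff_TSP1_CD47"] / p["kon_TSP1_CD47"]


class TestBuildModel:
    def test_cd47_depletion_scales_seed(self):
        m = build_model(
            intervention=InterventionSpec(cd47_depletion_fraction=0.5))
        cd47 = next(l for l in m.seed_amounts if "CD47" in l)
        assert m.seed_amounts[cd47] == pytest.approx(5000.0)

    def test_nrp1_knockout_zeroes_seed(self):
        m = build_model(intervention=InterventionSpec(nrp1_knockout=True))
        nrp1 = next(l for l in m.seed_amounts if "NRP1" in l)
        assert m.seed_amounts[nrp1] == 0.0

    def test_chx_zeroes_synthesis(self):
        m = build_model(intervention=InterventionSpec(chx=True))
        assert m.params["ksingleR2_syn"] == 0.0

    def test_kd_scale_multiplies_off_rate_only(self):
        base = build_model()
        scaled = build_model(intervention=InterventionSpec(kd_scale_tsp1cd47=10.0))
        assert scaled.params["koff_TSP1_CD47"] == pytest.approx(
            10.0 * base.params["koff_TSP1_CD47"])
        assert scaled.params["kon_TSP1_CD47"] == base.params["kon_TSP1_CD47"]

    def test_invalid_intervention_rejected(self):
        with pytest.raises(ValidationError):
            build_model(intervention=InterventionSpec(tsp1_depletion_fraction=1.5))
        with pytest.raises(ValidationError):
            build_model(intervention=InterventionSpec(kd_scale_tsp1cd47=0.5))

    def test_rule_rates_all_resolve(self):
        m = build_model()
        for rule in m.rules:
            for name in rule.rate:
                assert name in m.params, f"rule {rule.name} references {name}"

    def test_expected_rule_inventory(self):
        m = build_model()
        names = {r.name for r in m.rules}
        for expected in [
            "vegf_r2_bind", "dimer_r2r2", "dimer_r1r2", "vegf_nrp1_couple",
            "r1_nrp1_couple", "r2_cd47_couple", "tsp1_bind", "rr_couple",
            "r2_phos", "r2_dephos_pm", "r2_dephos_pm_tsp1", "r2_dephos_endo",
            "internalize_dimer", "internalize_const", "se1_to_se2",
            "se2_to_re", "se2_to_re_tsp1", "recycle",
            "deg_p", "deg_p_tsp1", "deg_u", "deg_u_tsp1", "r2_synthesis",
        ]:
            assert expected in names


def _integrate_cascade(cascade, params, drive, t_end=3600.0, y0=None):
    y0 = cascade.initial_state() if y0 is None else y0
    sol = solve_ivp(
        lambda t, y: cascade.fluxes(y, np.array([drive]), params),
        (0, t_end), y0, method="BDF", rtol=1e-8, atol=1e-10,
    )
    assert sol.success
    return sol.y[:, -1]


class TestCascade:
    def test_no_drive_stays_basal(self):
        """With phosphorylated receptor fixed at zero, every cascade output
        relaxes to a small basal level."""
        params = nominal_parameters()
        cascade = downstream_rules(params)
        y = _integrate_cascade(cascade, params, drive=0.0, t_end=2e4)
        idx = {n: i for i, n in enumerate(cascade.STATE_NAMES)}
        assert y[idx["pSrc"]] < 0.01 * params["Src_0"]
        assert y[idx["Akt_mS473"]] + y[idx["Akt_pp"]] < 0.01 * params["Akt_0"]
        assert y[idx["eNOS_p"]] < 0.01 * params["eNOS_0"]

    def test_pten_increase_decreases_pip3(self):
        params = nominal_parameters()
        cascade = downstream_rules(params)
        y_lo = _integrate_cascade(cascade, params, drive=500.0, t_end=2e4)
        params_hi = nominal_parameters(PTEN_0=10 * params["PTEN_0"])
        y_hi = _integrate_cascade(
            downstream_rules(params_hi), params_hi, drive=500.0, t_end=2e4)
        i = cascade.STATE_NAMES.index("PIP3")
        assert y_hi[i] < y_lo[i]

    def test_cacam_required_for_enos(self):
        """Without Ca/CaM no eNOS leaves caveolin, so S1177 stays basal even
        with strong Akt drive."""
        params = nominal_parameters(CaM_0=0.0)
        cascade = downstream_rules(params)
        y = _integrate_cascade(cascade, params, drive=5000.0, t_end=2e4)
        idx = {n: i for i, n in enumerate(cascade.STATE_NAMES)}
        assert y[idx["Akt_pp"]] > 0.05  # Akt is active
        assert y[idx["CaCaM"]] == pytest.approx(0.0, abs=1e-12)
        assert y[idx["eNOS_p"]] < 1e-6

    def test_jacobian_matches_finite_differences(self):
        params = nominal_parameters()
        cascade = CascadeDynamics(params)
        rng = np.random.default_rng(11)
        for _ in range(5):
            y = np.abs(rng.normal(0.2, 0.15, len(cascade.STATE_NAMES)))
            y[10] = 0.3
            y[11] = 250.0
            drv = np.array([float(rng.uniform(0, 2000))])
            J, Jd = cascade.jacobian(y, drv, params)
            f0 = cascade.fluxes(y, drv, params)
            for i in range(len(y)):
                eps = 1e-7 * max(abs(y[i]), 1e-3)
                yp = y.copy()
                yp[i] += eps
                col = (cascade.fluxes(yp, drv, params) - f0) / eps
                assert np.allclose(J[:, i], col, rtol=1e-4, atol=1e-6)
            dp = drv + 1e-4
            col = (cascade.fluxes(y, dp, params) - f0) / 1e-4
            assert np.allclose(Jd[:, 0], col, rtol=1e-4, atol=1e-8)


class TestCalciumFluxes:
    def test_rest_is_steady(self):
        params = nominal_parameters()
        fl = calcium_fluxes(
            {"Ca": params["Ca_rest"], "Ca_ER": params["Ca_ER_rest"],
             "IP3": params["IP3_rest"]}, params)
        assert abs(fl["dCa"]) < 1e-9
        # ER balance is steady by leak calibration
        assert abs(fl["dCa_ER"]) < 1e-9

    def test_no_ip3_full_er_means_no_release_no_crac(self):
        params = nominal_parameters()
        fl = calcium_fluxes(
            {"Ca": params["Ca_rest"], "Ca_ER": params["Ca_ER_rest"], "IP3": 0.0},
            params)
        assert fl["J_ip3r"] == 0.0
        assert fl["J_crac"] == 0.0

    def test_closed_two_pool_system_conserves_calcium(self):
        """With plasma-membrane fluxes off, cytosol + ER/beta is conserved."""
        params = nominal_parameters(ICRAC_amp=0.0, IPMCA_amp=0.0)
        rng = np.random.default_rng(5)
        for _ in range(10):
            state = {
                "Ca": float(rng.uniform(0.05, 2.0)),
                "Ca_ER": float(rng.uniform(50, 400)),
                "IP3": float(rng.uniform(0, 3)),
            }
            fl = calcium_fluxes(state, params)
            # J_in0 is calibrated to PMCA(rest) which is 0 when IPMCA_amp = 0
            total_rate = fl["dCa"] + fl["dCa_ER"] / params["beta_er"]
            assert abs(total_rate) < 1e-12

    def test_ip3_step_gives_transient_then_plateau(self):
        """Step IP3 from rest: cytosolic Ca rises to a peak, then declines
        toward a store-operated plateau above rest."""
        params = nominal_parameters()
        cascade = CascadeDynamics(params)
        y0 = cascade.initial_state()
        idx = {n: i for i, n in enumerate(cascade.STATE_NAMES)}

        def rhs(t, y):
            dy = cascade.fluxes(y, np.array([0.0]), params)
            dy[idx["IP3"]] = 0.0  # clamp IP3
            return dy

        y0[idx["IP3"]] = 2.5
        sol = solve_ivp(rhs, (0, 3600), y0, method="BDF", rtol=1e-8,
                        atol=1e-10, t_eval=np.arange(0, 3600, 5.0))
        ca = sol.y[idx["Ca"]]
        i_peak = int(np.argmax(ca))
        assert ca[i_peak] > 1.5 * params["Ca_rest"]
        assert 0 < i_peak < len(ca) - 1
        assert ca[-1] < 0.95 * ca[i_peak]  # declines after the peak
        assert ca[-1] > params["Ca_rest"]  # plateau above rest

    def test_negative_concentration_rejected(self):
        params = nominal_parameters()
        with pytest.raises(ValidationError):
            calcium_fluxes({"Ca": -0.1, "Ca_ER": 400.0, "IP3": 0.1}, params)
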