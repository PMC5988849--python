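"""ODE compilation and integration: mass-action correctness against an
independent recomputation, conservation laws, events and readouts."""

import numpy as np
import pytest

from angiotriad.model import build_model, nominal_parameters
from angiotriad.ode import (
    EventSchedule,
    SimulationError,
    compile_network,
    preequilibrate,
    readout,
    simulate,
    steady_state,
)
from angiotriad.rulegraph import (
    ModelSignature,
    MoleculeType,
    RxnRule,
    SiteDef,
    ValidationError,
    generate_network,
    parse_species,
)


def _toy_system(rules, seeds, sig, params, seed_amounts, cascade_params=None):
    """Compile a toy network through a minimal ModelSpec-like wrapper."""
    from angiotriad.model import CascadeDynamics, ModelSpec

    net = generate_network(seeds, rules, sig)
    p = nominal_parameters()
    spec = ModelSpec(
        signature=sig, seeds=seeds, seed_amounts=seed_amounts, clamped=[],
        rules=rules, params=p, init=None, intervention=None,
        cascade=CascadeDynamics(p),
    )
    spec.params.update(params)
    return compile_network(spec, net), net


class TestToyCompilation:
    def test_reversible_equilibrium_ratio(self):
        """Closed A<->B reaches B/A = kf/kr."""
        sig = ModelSignature([MoleculeType("A", (SiteDef("s", ("a", "b")),))])
        fwd = RxnRule("f", ["A(s~a)"], ["A(s~b)"], "kf", signature=sig)
        rev = RxnRule("r", ["A(s~b)"], ["A(s~a)"], "kr", signature=sig)
        seeds = [parse_species("A(s~a)", sig)]
        system, net = _toy_system(
            [fwd, rev], seeds, sig, {}, {net_label(seeds[0], sig): 100.0})
        system.model.params["kf"] = 0.03
        system.model.params["kr"] = 0.01
        system._k_cache = None
        traj = simulate(system, t_end=5000.0, dense=False)
        y = traj.y[: system.n_net, -1]
        a = y[net.index_of(parse_species("A(s~a)", sig))]
        b = y[net.index_of(parse_species("A(s~b)", sig))]
        assert b / a == pytest.approx(3.0, rel=1e-6)

    def test_synthesis_degradation_steady_state(self):
        """0 -> R at s, R -> 0 at d: steady state R = s/d."""
        sig = ModelSignature([MoleculeType("R", ())])
        synth = RxnRule("s", [], ["@PM:R()"], "ks", signature=sig)
        deg = RxnRule("d", ["R()"], [], "kd", signature=sig)
        system, net = _toy_system([synth, deg], [], sig, {}, {})
        system.model.params["ks"] = 5.0
        system.model.params["kd"] = 0.01
        system._k_cache = None
        traj = simulate(system, t_end=2e3, dense=False)
        assert traj.y[0, -1] == pytest.approx(500.0, rel=1e-6)


def net_label(sp, sig):
    from angiotriad.rulegraph import canonical_label

    return canonical_label(sp)


class TestMassActionOracle:
    def test_rates_match_bruteforce_recomputation(self, full_system, full_model):
        """Vectorized rate evaluation equals a per-reaction recomputation
        from the reaction list on random states."""
        rng = np.random.default_rng(42)
        net = full_system.network
        params = full_model.params
        for _ in range(100):
            x = rng.uniform(0, 1000, full_system.n_net)
            rates = full_system.evaluate_rates(x, params)
            j = rng.integers(full_system.n_rxn)
            rxn = net.reactions[j]
            expected = float(rxn.stat_factor)
            for nm in rxn.rate_params:
                expected *= params[nm]
            for s in rxn.reactants:
                expected *= x[s]
            assert rates[j] == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_stoichiometry_matches_reaction_list(self, full_system):
        """d(species)/dt assembled by the sparse matrix equals a loop over
        reactions (free species only; clamped rows are pinned)."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 500, full_system.n_net)
        rates = full_system.evaluate_rates(x)
        dx = full_system.S @ rates
        expected = np.zeros_like(dx)
        for j, rxn in enumerate(full_system.network.reactions):
            for s in rxn.reactants:
                expected[s] -= rates[j]
            for s in rxn.products:
                expected[s] += rates[j]
        expected[full_system.clamped_idx] = 0.0
        assert np.allclose(dx, expected, rtol=1e-12, atol=1e-9)


class TestFullModelDynamics:
    def test_conservation_detected(self, full_system):
        assert {"CD47", "NRP1", "VEGFR1"} <= set(full_system.conservation)
        # VEGFR2 is synthesized and degraded; VEGF and TSP1 are external
        assert "VEGFR2" not in full_system.conservation
        assert "VEGF" not in full_system.conservation

    def test_prestimulus_steady_state(self, full_system, rest_state, full_model):
        d = full_system.rhs(0.0, rest_state, full_model.params)
        scale = np.maximum(np.abs(rest_state), 1.0)
        assert float(np.max(np.abs(d) / scale)) < 1e-9

    def test_steady_from_steady_is_constant(self, full_system, rest_state):
        traj = simulate(full_system, EventSchedule(), t_end=600.0,
                        y0=rest_state, rtol=1e-8, atol=1e-10, dense=False)
        rel = np.abs(traj.y[:, -1] - rest_state) / np.maximum(np.abs(rest_state), 1e-6)
        assert float(np.max(rel)) < 1e-6

    def test_conservation_along_stimulated_trajectory(self, control_result, full_system):
        traj = control_result.trajectory
        for name, w in full_system.conservation.items():
            totals = w @ traj.y
            drift = np.max(np.abs(totals - totals[0])) / totals[0]
            assert drift < 1e-6, f"{name} drifts by {drift}"

    def test_readout_partition(self, control_result):
        traj = control_result.trajectory
        total = readout(traj, "pR2_total")
        parts = readout(traj, "pR2_surface") + readout(traj, "pR2_endosomal")
        assert np.allclose(total, parts, rtol=1e-12, atol=1e-9)

    def test_pip2_pip3_total_conserved(self, control_result, full_model):
        traj = control_result.trajectory
        total = readout(traj, "PIP2") + readout(traj, "PIP3")
        assert np.allclose(total, full_model.params["PIP2_0"], rtol=1e-9)

    def test_unknown_readout_lists_valid_names(self, control_result):
        with pytest.raises(ValidationError, match="pR2_total"):
            readout(control_result.trajectory, "nonsense")

    def test_pR2_transient_shape(self, control_result):
        """Phosphorylated receptor rises to a transient peak within the first
        ten minutes and relaxes to a lower quasi-steady level."""
        traj = control_result.trajectory
        post = traj.t >= 0
        s = readout(traj, "pR2_total")[post]
        t = traj.t[post]
        i_peak = int(np.argmax(s))
        assert t[i_peak] <= 600.0
        assert s[-1] < 0.6 * s[i_peak]

    def test_endosomal_signal_dominates(self, control_result):
        traj = control_result.trajectory
        post = traj.t >= 0
        endo = readout(traj, "pR2_endosomal")[post]
        surf = readout(traj, "pR2_surface")[post]
        assert np.trapezoid(endo) > np.trapezoid(surf)

    def test_event_on_unknown_species_raises(self, full_system, rest_state):
        sched = EventSchedule().add(10.0, "set_species", "NOPE", 1.0)
        with pytest.raises(ValidationError):
            simulate(full_system, sched, 20.0, y0=rest_state)

    def test_tolerance_halving_stability(self, full_system, rest_state, full_model):
        """Halving both tolerances moves every readout maximum by < 0.1%."""
        from angiotriad.model import VEGF_NG_ML_TO_NM

        vegf = next(l for l in full_model.clamped if "VEGF" in l)
        sched = EventSchedule().add(0.0, "set_species", vegf, 50 * VEGF_NG_ML_TO_NM)
        maxima = {}
        for tag, (rtol, atol) in {"a": (1e-6, 1e-8), "b": (5e-7, 5e-9)}.items():
            traj = simulate(full_system, sched, 1800.0, y0=rest_state,
                            rtol=rtol, atol=atol)
            maxima[tag] = {
                n: float(np.max(readout(traj, n)))
                for n in ("pR2_total", "pS473", "pS1177", "CaCaM")
            }
        for n in maxima["a"]:
            assert maxima["a"][n] == pytest.approx(maxima["b"][n], rel=1e-3)


class TestSteadyStateSolver:
    def test_newton_polish_agrees_with_long_integration(self, full_system):
        y_newton = preequilibrate(full_system, newton=True, rtol=1e-6, atol=1e-8)
        y_long = preequilibrate(full_system, newton=False, duration=3e5,
                                rtol=1e-8, atol=1e-10)
        nz = np.abs(y_long) > 1e-6
        rel = np.abs(y_newton[nz] - y_long[nz]) / np.abs(y_long[nz])
        assert float(np.max(rel)) < 1e-5

    def test_steady_state_preserves_conserved_totals(self, full_system, rest_state, full_model):
        params = full_model.params.copy()
        params["kdp_s"] *= 1.7
        y = steady_state(full_system, rest_state, params)
        assert y is not None
        for name, w in full_system.conservation.items():
            assert w @ y == pytest.approx(w @ rest_state, rel=1e-8)
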