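"""Compile a reaction network into a deterministic ODE system and simulate.

The network part is mass action (rate = k * product of reactant amounts,
with the statistical factor folded into k); the downstream cascade is an
explicit rate-law block coupled one-way through scalar "driver" signals
(here: total phosphorylated VEGFR2 on the membrane and signaling
endosomes).  Bath ligands are clamped boundary species whose value only
changes through scheduled events.  Integration uses a stiff solver (BDF)
with an analytic sparse Jacobian for the mass-action block and finite
differences for the cascade block, restarted at every event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sps
from scipy.integrate import solve_ivp

from .model import CascadeDynamics, ModelSpec, ParameterSet
from .rulegraph import ReactionNetwork, ValidationError

__all__ = [
    "ODESystem",
    "EventSchedule",
    "Event",
    "Trajectory",
    "SimulationError",
    "compile_network",
    "simulate",
    "readout",
    "preequilibrate",
    "READOUT_NAMES",
]

SIGNALING_COMPARTMENTS = ("PM", "SE1", "SE2")

READOUT_NAMES = (
    "pR2_total", "pR2_surface", "pR2_endosomal", "R2_total", "R2_surface",
    "pSrc", "pAxl", "pS473", "ppAkt", "pS1177", "Ca_cyt", "CaCaM",
    "pPLCg", "IP3", "PIP3", "PIP2",
)


class SimulationError(RuntimeError):
    """Structured solver failure: time of failure and worst-scaled state."""

    def __init__(self, message: str, t: float | None = None, worst_state: str | None = None):
        super().__init__(message)
        self.t = t
        self.worst_state = worst_state


@dataclass
class Event:
    time: float
    action: str  # set_species | set_param | scale_species
    target: str
    value: float


class EventSchedule:
    """Ordered list of timed actions (doses, depletions, parameter switches)."""

    def __init__(self, events: Iterable[Event] = ()):
        self.events = sorted(events, key=lambda e: e.time)

    def add(self, time: float, action: str, target: str, value: float) -> "EventSchedule":
        self.events.append(Event(time, action, target, value))
        self.events.sort(key=lambda e: e.time)
        return self

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # (n_states, n_times)
    names: list[str]
    readout_defs: dict[str, tuple[np.ndarray, float]]
    diagnostics: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.y[self.names.index(name)]


class ODESystem:
    """Compiled dynamical system: species index map, mass-action rates,
    cascade block, readout definitions and detected conservation laws."""

    def __init__(self, model: ModelSpec, network: ReactionNetwork):
        self.model = model
        self.network = network
        self.n_net = len(network.species)
        self.cascade: CascadeDynamics = model.cascade
        self.n_extra = len(self.cascade.STATE_NAMES)
        self.n = self.n_net + self.n_extra
        self.names = list(network.labels) + list(self.cascade.STATE_NAMES)

        self._build_reactions()
        self._build_clamps()
        self._build_drivers()
        self._build_readouts()
        self._detect_conservation()
        self._k_cache: tuple[tuple, np.ndarray] | None = None

    # -- construction -------------------------------------------------------

    def _build_reactions(self) -> None:
        rxns = self.network.reactions
        self.n_rxn = len(rxns)
        self.stat_factors = np.array([float(r.stat_factor) for r in rxns])
        self.rate_params = [r.rate_params for r in rxns]
        i1 = np.full(self.n_rxn, -1, dtype=np.int64)
        i2 = np.full(self.n_rxn, -1, dtype=np.int64)
        rows, cols, vals = [], [], []
        for j, r in enumerate(rxns):
            if len(r.reactants) > 2:
                raise ValidationError("only uni/bimolecular reactions supported")
            if len(r.reactants) >= 1:
                i1[j] = r.reactants[0]
            if len(r.reactants) == 2:
                i2[j] = r.reactants[1]
            for s in r.reactants:
                rows.append(s)
                cols.append(j)
                vals.append(-1.0)
            for s in r.products:
                rows.append(s)
                cols.append(j)
                vals.append(1.0)
        self.i1, self.i2 = i1, i2
        self.S_full = sps.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_net, self.n_rxn)
        ).tocsr()
        # Jacobian entry pattern for the mass-action block
        ent_j, ent_col, ent_partner = [], [], []
        for j in range(self.n_rxn):
            if i1[j] >= 0:
                ent_j.append(j)
                ent_col.append(i1[j])
                ent_partner.append(i2[j])
            if i2[j] >= 0:
                ent_j.append(j)
                ent_col.append(i2[j])
                ent_partner.append(i1[j])
        self._ent_j = np.array(ent_j, dtype=np.int64)
        self._ent_col = np.array(ent_col, dtype=np.int64)
        self._ent_partner = np.array(ent_partner, dtype=np.int64)

    def _build_clamps(self) -> None:
        self.clamped_idx = np.array(
            sorted(self.network._index[lbl] for lbl in self.model.clamped
                   if lbl in self.network._index),
            dtype=np.int64,
        )
        mask = np.ones(self.n, dtype=bool)
        mask[self.clamped_idx] = False
        self._free_mask = mask
        # clamped (bath) species have zero net derivative: zero their rows
        S = self.S_full.tolil(copy=True)
        for idx in self.clamped_idx:
            S[idx, :] = 0.0
        self.S = S.tocsr()

    def _species_weights(self, predicate) -> np.ndarray:
        w = np.zeros(self.n)
        for idx, sp in enumerate(self.network.species):
            w[idx] = predicate(sp)
        return w

    @staticmethod
    def _count_r2(sp, phos: bool | None, compartments) -> float:
        if sp.compartment not in compartments:
            return 0.0
        n = 0
        for mol in sp.molecules:
            if mol.type != "VEGFR2":
                continue
            if phos is None:
                n += 1
            else:
                k = mol.site_names.index("Y1175")
                if (mol.states[k] == "p") == phos:
                    n += 1
        return float(n)

    def _build_drivers(self) -> None:
        w = self._species_weights(
            lambda sp: self._count_r2(sp, True, SIGNALING_COMPARTMENTS)
        )
        self.driver_weights = w[np.newaxis, : self.n_net]  # (n_drivers, n_net)

    def _build_readouts(self) -> None:
        p = self.model.params
        ei = {n: self.n_net + i for i, n in enumerate(self.cascade.STATE_NAMES)}

        def unit(*names: str, scale: float = 1.0):
            w = np.zeros(self.n)
            for nm in names:
                w[ei[nm]] = scale
            return w

        defs: dict[str, tuple[np.ndarray, float]] = {}
        all_comp = ("PM", "SE1", "SE2", "RE")
        defs["pR2_total"] = (
            self._species_weights(lambda sp: self._count_r2(sp, True, SIGNALING_COMPARTMENTS)), 0.0)
        defs["pR2_surface"] = (
            self._species_weights(lambda sp: self._count_r2(sp, True, ("PM",))), 0.0)
        defs["pR2_endosomal"] = (
            self._species_weights(lambda sp: self._count_r2(sp, True, ("SE1", "SE2"))), 0.0)
        defs["R2_total"] = (
            self._species_weights(lambda sp: self._count_r2(sp, None, all_comp)), 0.0)
        defs["R2_surface"] = (
            self._species_weights(lambda sp: self._count_r2(sp, None, ("PM",))), 0.0)
        defs["pSrc"] = (unit("pSrc"), 0.0)
        defs["pAxl"] = (unit("pAxl1", "pAxl12"), 0.0)
        defs["pS473"] = (unit("Akt_mS473", "Akt_pp"), 0.0)
        defs["ppAkt"] = (unit("Akt_pp"), 0.0)
        defs["pS1177"] = (unit("eNOS_p"), 0.0)
        defs["Ca_cyt"] = (unit("Ca"), 0.0)
        defs["CaCaM"] = (unit("CaCaM"), 0.0)
        defs["pPLCg"] = (unit("pPLCg"), 0.0)
        defs["IP3"] = (unit("IP3"), 0.0)
        defs["PIP3"] = (unit("PIP3"), 0.0)
        defs["PIP2"] = (unit("PIP3", scale=-1.0), p["PIP2_0"])
        self.readout_defs = defs

    def _detect_conservation(self) -> None:
        """Molecule-type count vectors in the left null space of S (exact)."""
        self.conservation: dict[str, np.ndarray] = {}
        type_names = list(self.network.signature.types)
        counts = {
            t: np.array([sp.molecule_counts().get(t, 0) for sp in self.network.species])
            for t in type_names
        }
        clamped = set(int(i) for i in self.clamped_idx)
        for t, v in counts.items():
            ok = True
            for r in self.network.reactions:
                # clamped bath species are external: exclude them from the balance
                bal = sum(v[s] for s in r.products if s not in clamped) - sum(
                    v[s] for s in r.reactants if s not in clamped
                )
                if bal != 0:
                    ok = False
                    break
            if ok:
                w = np.zeros(self.n)
                w[: self.n_net] = v
                w[self.clamped_idx] = 0.0
                self.conservation[t] = w

    # -- rates and derivatives ---------------------------------------------

    def rate_constants(self, params: ParameterSet | None = None) -> np.ndarray:
        params = params if params is not None else self.model.params
        key = tuple(sorted(params.items()))
        if self._k_cache is not None and self._k_cache[0] == key:
            return self._k_cache[1]
        k = self.stat_factors.copy()
        for j, names in enumerate(self.rate_params):
            for nm in names:
                try:
                    k[j] *= params[nm]
                except KeyError:
                    raise ValidationError(
                        f"reaction {j} (rule {self.network.reactions[j].rule}): "
                        f"unresolved rate parameter {nm!r}"
                    ) from None
        self._k_cache = (key, k)
        return k

    def evaluate_rates(self, x: np.ndarray, params: ParameterSet | None = None) -> np.ndarray:
        """Per-reaction mass-action rates at network state x."""
        k = self.rate_constants(params)
        xs = np.maximum(x, 0.0)
        rates = k.copy()
        m1 = self.i1 >= 0
        rates[m1] *= xs[self.i1[m1]]
        m2 = self.i2 >= 0
        rates[m2] *= xs[self.i2[m2]]
        return rates

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n)
        for lbl, amount in self.model.seed_amounts.items():
            idx = self.network._index.get(lbl)
            if idx is None:
                raise ValidationError(f"seed species {lbl} missing from network")
            y0[idx] = amount
        y0[self.n_net:] = self.cascade.initial_state()
        return y0

    def rhs(self, t: float, y: np.ndarray, params: ParameterSet) -> np.ndarray:
        x = y[: self.n_net]
        rates = self.evaluate_rates(x, params)
        dy = np.empty(self.n)
        dy[: self.n_net] = self.S @ rates
        drivers = self.driver_weights @ np.maximum(x, 0.0)
        dy[self.n_net:] = self.cascade.fluxes(y[self.n_net:], drivers, params)
        dy[self.clamped_idx] = 0.0
        return dy

    def jac(self, t: float, y: np.ndarray, params: ParameterSet) -> sps.spmatrix:
        x = np.maximum(y[: self.n_net], 0.0)
        k = self.rate_constants(params)
        partner = self._ent_partner
        data = k[self._ent_j] * np.where(partner >= 0, x[np.maximum(partner, 0)], 1.0)
        W = sps.coo_matrix(
            (data, (self._ent_j, self._ent_col)), shape=(self.n_rxn, self.n_net)
        ).tocsr()
        Jnn = self.S @ W  # clamped rows of S are zero already
        ye = y[self.n_net:]
        drivers = self.driver_weights @ x
        Jee, Jed = self.cascade.jacobian(ye, drivers, params)
        Jen = sps.csr_matrix(Jed @ self.driver_weights)
        return sps.bmat(
            [[Jnn, None], [Jen, sps.csr_matrix(Jee)]], format="csc"
        )

    def readout_weights(self, name: str) -> tuple[np.ndarray, float]:
        try:
            return self.readout_defs[name]
        except KeyError:
            raise ValidationError(
                f"unknown readout {name!r}; valid names: {sorted(self.readout_defs)}"
            ) from None


def compile_network(model: ModelSpec, network: ReactionNetwork) -> ODESystem:
    """Compile model + generated network into an integrable ODE system."""
    if not network.converged:
        raise ValidationError("cannot compile a non-converged network")
    return ODESystem(model, network)


# ---------------------------------------------------------------------------
# simulation


def _apply_event(
    system: ODESystem, event: Event, y: np.ndarray, params: ParameterSet
) -> None:
    if event.action == "set_param":
        if event.target not in params:
            raise ValidationError(f"event sets unknown parameter {event.target!r}")
        params[event.target] = event.value
        system._k_cache = None
    elif event.action in ("set_species", "scale_species"):
        idx = system.network._index.get(event.target)
        if idx is None:
            # allow bare seed shorthand (e.g. "VEGF") by label search
            hits = [i for i, lbl in enumerate(system.network.labels)
                    if event.target in lbl]
            if len(hits) != 1:
                raise ValidationError(f"event targets unknown species {event.target!r}")
            idx = hits[0]
        if event.action == "set_species":
            y[idx] = event.value
        else:
            y[idx] *= event.value
    else:
        raise ValidationError(f"unknown event action {event.action!r}")


def simulate(
    system: ODESystem,
    schedule: EventSchedule | None = None,
    t_end: float = 3600.0,
    *,
    t_start: float = 0.0,
    y0: np.ndarray | None = None,
    params: ParameterSet | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_dt: float = 1.0,
    method: str = "BDF",
    dense: bool = True,
) -> Trajectory:
    """Integrate under an event schedule with stop-modify-restart semantics.

    Events before ``t_start`` are applied to the initial condition; the
    output grid is uniform with step ``grid_dt`` (plus event times), which
    stabilizes peak detection in downstream scans.
    """
    if t_end <= t_start:
        raise ValidationError("t_end must exceed t_start")
    schedule = schedule or EventSchedule()
    params = (params if params is not None else system.model.params).copy()
    y = (y0 if y0 is not None else system.initial_state()).astype(float).copy()

    events = list(schedule)
    for ev in [e for e in events if e.time <= t_start]:
        _apply_event(system, ev, y, params)
    events = [e for e in events if e.time > t_start]

    breakpoints = sorted({t_start, t_end, *[e.time for e in events if e.time < t_end]})
    ts_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    n_steps = 0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if dense:
            n_pts = max(int(round((b - a) / grid_dt)), 1)
            t_eval = np.linspace(a, b, n_pts + 1)
        else:
            t_eval = np.array([a, b])
        sol = solve_ivp(
            system.rhs, (a, b), y, method=method, t_eval=t_eval,
            jac=system.jac, rtol=rtol, atol=atol, args=(params,),
        )
        if not sol.success:
            yl = sol.y[:, -1] if sol.y.size else y
            worst = system.names[int(np.argmin(yl))]
            raise SimulationError(
                f"solver failed at t={sol.t[-1] if sol.t.size else a:.1f}s: {sol.message}",
                t=float(sol.t[-1]) if sol.t.size else a,
                worst_state=worst,
            )
        n_steps += sol.t.size
        y = sol.y[:, -1].copy()
        floor = -100.0 * atol * max(1.0, float(np.max(np.abs(y))))
        if float(np.min(y)) < floor:
            worst = system.names[int(np.argmin(y))]
            raise SimulationError(
                f"state {worst} went negative ({np.min(y):.3e}) at t={b:.1f}s",
                t=b, worst_state=worst,
            )
        np.clip(y, 0.0, None, out=y)
        keep = slice(None) if not ts_out else slice(1, None)
        ts_out.append(sol.t[keep])
        ys_out.append(sol.y[:, keep])
        for ev in [e for e in events if e.time == b]:
            _apply_event(system, ev, y, params)
            if ys_out:
                ys_out[-1][:, -1] = y
    t = np.concatenate(ts_out)
    Y = np.concatenate(ys_out, axis=1)
    return Trajectory(
        t=t, y=Y, names=system.names, readout_defs=system.readout_defs,
        diagnostics={
            "rtol": rtol, "atol": atol, "method": method,
            "n_solver_points": int(n_steps), "success": True,
        },
    )


def readout(traj: Trajectory, name: str, normalize: bool = False) -> np.ndarray:
    """Scalar time series of a named readout; optionally max-normalized."""
    try:
        w, offset = traj.readout_defs[name]
    except KeyError:
        raise ValidationError(
            f"unknown readout {name!r}; valid names: {sorted(traj.readout_defs)}"
        ) from None
    series = w @ np.maximum(traj.y, 0.0) + offset
    if normalize:
        m = float(np.max(series))
        if m > 0:
            series = series / m
    return series


def steady_state(
    system: ODESystem,
    y0: np.ndarray,
    params: ParameterSet | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> np.ndarray | None:
    """Polish a near-steady state by pseudo-transient continuation.

    Solves (I/h - J) dy = f with an increasing pseudo-timestep h; the implicit
    shift keeps the iteration regular despite the conserved totals (which make
    J exactly singular) and pins the solution to the conservation manifold of
    ``y0``.  Returns None if the iteration stalls or leaves the physical
    (nonnegative) region, in which case callers fall back to long integration.
    """
    import scipy.sparse.linalg as spl

    params = params if params is not None else system.model.params
    y = y0.astype(float).copy()
    h = 1e3
    scale = max(1.0, float(np.max(np.abs(y))))
    f = system.rhs(0.0, y, params)
    for _ in range(max_iter):
        resid = float(np.max(np.abs(f)))
        if resid < tol * scale:
            return np.maximum(y, 0.0)
        J = system.jac(0.0, y, params).tocsc()
        A = (sps.identity(system.n, format="csc") / h) - J
        try:
            dy = spl.spsolve(A, f)
        except RuntimeError:
            return None
        y_new = y + dy
        if not np.all(np.isfinite(y_new)) or float(np.min(y_new)) < -1e-6 * scale:
            h *= 0.25
            if h < 1e-2:
                return None
            continue
        f_new = system.rhs(0.0, np.maximum(y_new, 0.0), params)
        if float(np.max(np.abs(f_new))) < resid or h < 1e7:
            y = np.maximum(y_new, 0.0)
            f = f_new
            h = min(h * 10.0, 1e12)
        else:
            h *= 0.25
            if h < 1e-2:
                return None
    return None


def preequilibrate(
    system: ODESystem,
    *,
    duration: float = 1e5,
    params: ParameterSet | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0: np.ndarray | None = None,
    newton: bool = True,
) -> np.ndarray:
    """Relax the ligand-free model to its pre-stimulus steady state.

    A short transient integration moves the state into the attracting basin,
    then a pseudo-transient Newton polish replaces the long tail of the
    relaxation; when the polish fails the full ``duration`` is integrated.
    """
    if newton:
        traj = simulate(
            system, EventSchedule(), t_end=min(3000.0, duration), y0=y0,
            params=params, rtol=max(rtol, 1e-6), atol=max(atol, 1e-8),
            dense=False,
        )
        y = steady_state(system, traj.y[:, -1], params)
        if y is not None:
            return y
    traj = simulate(
        system, EventSchedule(), t_end=duration, y0=y0, params=params,
        rtol=rtol, atol=atol, dense=False,
    )
    return traj.y[:, -1].copy()
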