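"""Virtual experiments: stimulation protocols, mechanism scans and rescue curves.

The canonical protocol adds 2.2 nM TSP1 ten minutes before 50 ng/ml VEGF and
observes the following hour; "maximum" readouts are peaks over the post-VEGF
window on a dense 1 s grid.  Scans vary the TSP1 mechanism multipliers
(fTSP1_i2r, fTSP1_deg, fTSP1_dp) or the intervention axes (TSP1 depletion,
CD47 depletion, TSP1-CD47 Kd scaling); rescue curves express recovery as a
fraction of the TSP1-free control maximum under an inhibitory TSP1 regime.

Network generation and pre-equilibration are cached: the rule set (hence the
species list) never changes across scans, only rate-constant values and seed
amounts do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    InitialState,
    InterventionSpec,
    ModelSpec,
    ParameterSet,
    VEGF_NG_ML_TO_NM,
    build_model,
)
from .ode import (
    EventSchedule,
    ODESystem,
    SimulationError,
    Trajectory,
    compile_network,
    preequilibrate,
    readout,
    simulate,
)
from .rulegraph import ValidationError

__all__ = [
    "Protocol",
    "ScanResult",
    "ProtocolResult",
    "run_protocol",
    "scan_1d",
    "scan_2d",
    "rescue_curve",
    "SCANNABLE",
    "MAX_READOUTS",
    "INHIBITORY_REGIME",
]

MAX_READOUTS = ("pR2_total", "pS473", "ppAkt", "pS1177", "CaCaM")

SCANNABLE = (
    "fTSP1_i2r", "fTSP1_deg", "fTSP1_dp",
    "tsp1_depletion", "cd47_depletion", "kd_scale",
)

#: TSP1 mechanism regime identified as sufficient for full inhibition
INHIBITORY_REGIME = {"fTSP1_deg": 10.0, "fTSP1_dp": 10.0, "fTSP1_i2r": 1.0}

#: working integration tolerances for scans (the simulate() defaults are
#: tighter; scan peaks move by far less than the quantities compared)
SCAN_RTOL = 1e-6
SCAN_ATOL = 1e-8
PREEQ_DURATION = 1e5


@dataclass
class Protocol:
    """Timed stimulation protocol with optional interventions."""

    tsp1_nM: float = 2.2
    tsp1_pretreat_s: float = 600.0
    vegf_ng_ml: float = 50.0
    observe_s: float = 3600.0
    intervention: InterventionSpec = field(default_factory=InterventionSpec)

    def validate(self) -> None:
        if self.tsp1_nM < 0 or self.vegf_ng_ml < 0:
            raise ValidationError("doses must be >= 0")
        if self.tsp1_pretreat_s < 0 or self.observe_s <= 0:
            raise ValidationError("protocol durations must be positive")
        self.intervention.validate()

    @property
    def vegf_nM(self) -> float:
        return self.vegf_ng_ml * VEGF_NG_ML_TO_NM


@dataclass
class ProtocolResult:
    maxima: dict[str, float]
    trajectory: Trajectory
    protocol: Protocol

    def trace(self, name: str, normalize: bool = False) -> np.ndarray:
        return readout(self.trajectory, name, normalize=normalize)


@dataclass
class ScanResult:
    params: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    maxima: dict[str, np.ndarray]  # readout -> array over the grid(s)
    control: dict[str, float]
    failed: np.ndarray | None = None

    def normalized(self, name: str) -> np.ndarray:
        c = self.control[name]
        return self.maxima[name] / c if c > 0 else self.maxima[name]


# ---------------------------------------------------------------------------
# compiled-model and pre-equilibration caches


class _Compiled:
    def __init__(self, model: ModelSpec):
        self.model = model
        self.network = model.generate()
        if not self.network.converged:
            raise ValidationError("network generation did not converge")
        self.system = compile_network(model, self.network)
        self.vegf_label = next(l for l in model.clamped if "VEGF" in l)
        self.tsp1_label = next(l for l in model.clamped if "TSP1" in l)
        self.preeq_cache: dict[tuple, np.ndarray] = {}
        self.rest_ref: dict[tuple, np.ndarray] = {}


_compiled_cache: dict[int, _Compiled] = {}


def _compiled(model: ModelSpec) -> _Compiled:
    c = _compiled_cache.get(id(model))
    if c is None or c.model is not model:
        c = _Compiled(model)
        _compiled_cache.clear()  # hold at most one compiled model
        _compiled_cache[id(model)] = c
    return c


def _seed_amounts(c: _Compiled, intervention: InterventionSpec) -> dict[str, float]:
    init = c.model.init
    amounts = dict(c.model.seed_amounts)
    for lbl in list(amounts):
        if "CD47" in lbl and lbl != c.tsp1_label:
            amounts[lbl] = init.cd47_total * (1.0 - intervention.cd47_depletion_fraction)
        if "NRP1" in lbl:
            amounts[lbl] = 0.0 if intervention.nrp1_knockout else init.nrp1_total
    amounts[c.vegf_label] = 0.0
    amounts[c.tsp1_label] = 0.0
    return amounts


def _effective_params(
    base: ParameterSet,
    intervention: InterventionSpec,
    overrides: dict[str, float] | None,
) -> ParameterSet:
    p = base.copy()
    if overrides:
        p.update(overrides)
    if intervention.kd_scale_tsp1cd47 != 1.0:
        p["koff_TSP1_CD47"] = p["koff_TSP1_CD47"] * intervention.kd_scale_tsp1cd47
    return p


def _preequilibrated(c: _Compiled, params: ParameterSet, amounts: dict[str, float]) -> np.ndarray:
    amounts_key = tuple(sorted(amounts.items()))
    key = (tuple(sorted(params.items())), amounts_key)
    y = c.preeq_cache.get(key)
    if y is None:
        from .ode import steady_state

        # a rest state for the same seed amounts (any parameters) is a good
        # Newton starting point: conserved totals are amount-determined
        ref = c.rest_ref.get(amounts_key)
        if ref is not None:
            y = steady_state(c.system, ref, params)
        if y is None:
            y0 = np.zeros(c.system.n)
            for lbl, amount in amounts.items():
                y0[c.network_index(lbl)] = amount
            y0[c.system.n_net:] = c.system.cascade.initial_state()
            y = preequilibrate(
                c.system, duration=PREEQ_DURATION, y0=y0, params=params,
                rtol=SCAN_RTOL, atol=SCAN_ATOL,
            )
        if len(c.preeq_cache) > 64:
            c.preeq_cache.clear()
        c.preeq_cache[key] = y
        c.rest_ref.setdefault(amounts_key, y)
    return y.copy()


def _network_index(self: _Compiled, lbl: str) -> int:
    idx = self.network._index.get(lbl)
    if idx is None:
        raise ValidationError(f"species {lbl} missing from network")
    return idx


_Compiled.network_index = _network_index  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# protocol execution


def run_protocol(
    model: ModelSpec,
    protocol: Protocol | None = None,
    *,
    param_overrides: dict[str, float] | None = None,
    tsp1_dose_scale: float = 1.0,
    rtol: float = SCAN_RTOL,
    atol: float = SCAN_ATOL,
) -> ProtocolResult:
    """Pre-equilibrate, apply the dosing schedule, return peaks and traces.

    Peaks are maxima over the post-VEGF observation window on the dense
    output grid.  ``tsp1_dose_scale`` supports depletion scans without
    mutating the protocol.
    """
    protocol = protocol or Protocol()
    protocol.validate()
    c = _compiled(model)
    iv = protocol.intervention
    params = _effective_params(model.params, iv, param_overrides)
    amounts = _seed_amounts(c, iv)
    try:
        y0 = _preequilibrated(c, params, amounts)
    except SimulationError as err:
        raise SimulationError(
            f"pre-equilibration failed for protocol {protocol}: {err}",
            t=err.t, worst_state=err.worst_state,
        ) from err

    tsp1_dose = (
        protocol.tsp1_nM
        * (1.0 - iv.tsp1_depletion_fraction)
        * tsp1_dose_scale
    )
    t_start = -protocol.tsp1_pretreat_s if (tsp1_dose > 0 and protocol.tsp1_pretreat_s > 0) else 0.0
    sched = EventSchedule()
    if tsp1_dose > 0:
        sched.add(t_start, "set_species", c.tsp1_label, tsp1_dose)
    if iv.chx:
        sched.add(t_start, "set_param", "ksingleR2_syn", 0.0)
    if protocol.vegf_nM > 0:
        sched.add(0.0, "set_species", c.vegf_label, protocol.vegf_nM)
    try:
        traj = simulate(
            c.system, sched, protocol.observe_s, t_start=t_start, y0=y0,
            params=params, rtol=rtol, atol=atol,
        )
    except SimulationError as err:
        raise SimulationError(
            f"protocol simulation failed ({protocol}): {err}",
            t=err.t, worst_state=err.worst_state,
        ) from err
    post = traj.t >= 0.0
    maxima = {
        name: float(np.max(readout(traj, name)[post])) for name in MAX_READOUTS
    }
    return ProtocolResult(maxima=maxima, trajectory=traj, protocol=protocol)


def _apply_axis(
    protocol: Protocol, name: str, value: float
) -> tuple[Protocol, dict[str, float]]:
    """Map a scan axis value onto protocol/parameter space."""
    overrides: dict[str, float] = {}
    iv = protocol.intervention
    if name in ("fTSP1_i2r", "fTSP1_deg", "fTSP1_dp"):
        overrides[name] = float(value)
    elif name == "tsp1_depletion":
        iv = replace(iv, tsp1_depletion_fraction=float(value))
    elif name == "cd47_depletion":
        iv = replace(iv, cd47_depletion_fraction=float(value))
    elif name == "kd_scale":
        iv = replace(iv, kd_scale_tsp1cd47=float(value))
    else:
        raise ValidationError(
            f"unknown scan parameter {name!r}; valid: {SCANNABLE}"
        )
    return replace(protocol, intervention=iv), overrides


def _check_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValidationError("scan grid must be 1-D with at least 2 points")
    if not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
        raise ValidationError("scan grid must be strictly monotone")
    return g


def scan_1d(
    model: ModelSpec,
    protocol: Protocol,
    param_name: str,
    grid,
    *,
    base_overrides: dict[str, float] | None = None,
) -> ScanResult:
    """Peak readouts along a 1-D grid of one scannable parameter.

    The control point (mechanism hooks neutral, no intervention, no TSP1) is
    evaluated once and reported alongside; non-finite maxima are flagged per
    grid point rather than aborting the scan.
    """
    g = _check_grid(grid)
    control = run_protocol(
        model, replace(protocol, tsp1_nM=0.0), param_overrides=base_overrides
    )
    maxima = {name: np.full(len(g), np.nan) for name in MAX_READOUTS}
    failed = np.zeros(len(g), dtype=bool)
    for i, v in enumerate(g):
        proto_i, overrides = _apply_axis(protocol, param_name, v)
        if base_overrides:
            overrides = {**base_overrides, **overrides}
        try:
            res = run_protocol(model, proto_i, param_overrides=overrides)
        except SimulationError:
            failed[i] = True
            continue
        for name in MAX_READOUTS:
            maxima[name][i] = res.maxima[name]
            if not np.isfinite(res.maxima[name]):
                failed[i] = True
    return ScanResult(
        params=(param_name,), grids=(g,), maxima=maxima,
        control=control.maxima, failed=failed,
    )


def scan_2d(
    model: ModelSpec,
    protocol: Protocol,
    param_pair: tuple[str, str],
    grids: tuple,
) -> ScanResult:
    """Matrix of peak readouts over two scannable parameters."""
    na, nb = param_pair
    if na == nb:
        raise ValidationError("scan_2d needs two distinct parameters")
    ga, gb = _check_grid(grids[0]), _check_grid(grids[1])
    control = run_protocol(model, replace(protocol, tsp1_nM=0.0))
    maxima = {name: np.full((len(ga), len(gb)), np.nan) for name in MAX_READOUTS}
    failed = np.zeros((len(ga), len(gb)), dtype=bool)
    for i, va in enumerate(ga):
        for j, vb in enumerate(gb):
            proto_ij, overrides = _apply_axis(protocol, na, va)
            proto_ij, ov2 = _apply_axis(proto_ij, nb, vb)
            overrides.update(ov2)
            try:
                res = run_protocol(model, proto_ij, param_overrides=overrides)
            except SimulationError:
                failed[i, j] = True
                continue
            for name in MAX_READOUTS:
                maxima[name][i, j] = res.maxima[name]
    return ScanResult(
        params=param_pair, grids=(ga, gb), maxima=maxima,
        control=control.maxima, failed=failed,
    )


def rescue_curve(
    model: ModelSpec,
    protocol: Protocol,
    intervention_axis: str,
    grid,
    *,
    regime: dict[str, float] | None = None,
    fixed_intervention: InterventionSpec | None = None,
) -> ScanResult:
    """Recovery of peak signaling versus an intervention axis.

    The TSP1 mechanism hooks are set to the inhibitory regime (default
    fTSP1_deg = fTSP1_dp = 10); recovery for each readout is the peak under
    the intervention divided by the TSP1-free control peak (same regime
    parameters, zero TSP1), so complete rescue approaches 1.  A fixed
    intervention (e.g. 50% CD47 depletion) may be combined with the scanned
    axis.
    """
    regime = dict(INHIBITORY_REGIME if regime is None else regime)
    g = _check_grid(grid)
    if fixed_intervention is not None:
        protocol = replace(protocol, intervention=fixed_intervention)
    res = scan_1d(model, protocol, intervention_axis, g, base_overrides=regime)
    # control: no TSP1, neutral intervention, same regime values (inactive
    # without TSP1-bound complexes)
    control = run_protocol(
        model, replace(protocol, tsp1_nM=0.0, intervention=InterventionSpec()),
        param_overrides=regime,
    )
    res.control = control.maxima
    return res
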