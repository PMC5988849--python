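"""Objective construction against normalized time courses and pattern search.

Western-blot-style data are relative, so both data and simulation are
max-normalized before residuals.  The optimizer is a generalized pattern
search in log10 parameter space: poll +/- mesh along each coordinate in a
fixed order, move to the first improvement and expand the mesh (x2), or
contract (x0.5) after a full failed poll; deterministic given the start
point.  A synthetic fixture generator stands in for digitized blots:
trajectories from known parameters, sampled sparsely, with multiplicative
lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .experiments import Protocol, run_protocol
from .model import InterventionSpec, ModelSpec
from .ode import SimulationError, readout
from .rulegraph import ValidationError

__all__ = [
    "TimeCourseDataset",
    "FitResult",
    "objective",
    "pattern_search",
    "make_fixture",
    "fit_model",
    "CONDITIONS",
    "FIXTURE_PANEL",
]

#: condition tag -> (protocol kwargs, intervention kwargs)
CONDITIONS: dict[str, tuple[dict, dict]] = {
    "control": ({}, {}),                      # 50 ng/ml VEGF, no TSP1
    "no_vegf": ({"vegf_ng_ml": 0.0}, {}),
    "chx": ({"vegf_ng_ml": 0.0}, {"chx": True}),
    "chx_vegf": ({}, {"chx": True}),
    "nrp1_absent": ({}, {"nrp1_knockout": True}),
}

#: the fitted panel: (readout, condition) pairs mirroring receptor dynamics
#: under control/CHX/NRP1-absence and the signaling time courses
FIXTURE_PANEL: tuple[tuple[str, str], ...] = (
    ("R2_total", "control"),
    ("R2_surface", "control"),
    ("R2_total", "no_vegf"),
    ("R2_total", "chx"),
    ("R2_total", "chx_vegf"),
    ("R2_total", "nrp1_absent"),
    ("pR2_total", "control"),
    ("pPLCg", "control"),
    ("Ca_cyt", "control"),
    ("pSrc", "control"),
    ("pAxl", "control"),
    ("pS473", "control"),
    ("pT308", "control"),
    ("pS1177", "control"),
)

RECEPTOR_TIMES_S = (0, 600, 1200, 1800, 2700, 3600)
SIGNALING_TIMES_S = (0, 120, 300, 600, 900, 1800, 3600)

_ALIASES = {"pT308": "ppAkt"}


@dataclass
class TimeCourseDataset:
    """One normalized time course under one condition."""

    name: str  # readout name (pT308 allowed as alias of ppAkt)
    condition: str
    times_s: np.ndarray
    values: np.ndarray
    weight: float = 1.0
    source: str = "fixture"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValidationError("times and values must align")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("normalized values must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; valid: {sorted(CONDITIONS)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "readout": self.name,
                "time_s": self.times_s,
                "value": self.values,
            }
        )


def datasets_to_csv(datasets: list[TimeCourseDataset]) -> pd.DataFrame:
    return pd.concat([d.to_frame() for d in datasets], ignore_index=True)


def datasets_from_frame(df: pd.DataFrame) -> list[TimeCourseDataset]:
    out = []
    for (cond, name), g in df.groupby(["condition", "readout"], sort=False):
        g = g.sort_values("time_s")
        out.append(
            TimeCourseDataset(
                name=name, condition=cond,
                times_s=g["time_s"].to_numpy(), values=g["value"].to_numpy(),
                source="file",
            )
        )
    return out


def _condition_protocol(condition: str, base: Protocol | None = None) -> Protocol:
    proto_kw, iv_kw = CONDITIONS[condition]
    base = base or Protocol(tsp1_nM=0.0)
    return replace(
        base, tsp1_nM=0.0, intervention=InterventionSpec(**iv_kw), **proto_kw
    )


def _simulated_series(
    model: ModelSpec,
    condition: str,
    names: list[str],
    overrides: dict[str, float],
    observe_s: float,
) -> dict[str, np.ndarray]:
    proto = replace(_condition_protocol(condition), observe_s=observe_s)
    res = run_protocol(model, proto, param_overrides=overrides)
    traj = res.trajectory
    post = traj.t >= 0
    out = {"_t": traj.t[post]}
    for nm in names:
        out[nm] = readout(traj, _ALIASES.get(nm, nm))[post]
    return out


PENALTY = 1e6


def objective(
    model: ModelSpec,
    datasets: list[TimeCourseDataset],
    free_params: list[str],
    values,
    *,
    log_failures: list | None = None,
) -> float:
    """Weighted mean-squared error between max-normalized simulation and data.

    Conditions are mapped to interventions (CHX -> zero synthesis, NRP1
    absence -> zero NRP1).  A failed simulation contributes a large but
    finite penalty so the optimizer can back away.
    """
    if not datasets:
        raise ValidationError("datasets must be nonempty")
    unknown = set(free_params) - set(model.params)
    if unknown:
        raise ValidationError(f"unknown free parameters: {sorted(unknown)}")
    overrides = {k: float(v) for k, v in zip(free_params, values)}
    if any(v < 0 for v in overrides.values()):
        return PENALTY
    by_cond: dict[str, list[TimeCourseDataset]] = {}
    for d in datasets:
        by_cond.setdefault(d.condition, []).append(d)
    total = 0.0
    for cond, ds in by_cond.items():
        names = sorted({d.name for d in ds})
        t_max = max(float(d.times_s[-1]) for d in ds)
        try:
            sims = _simulated_series(model, cond, names, overrides, max(t_max, 60.0))
        except SimulationError as err:
            if log_failures is not None:
                log_failures.append((cond, overrides, str(err)))
            return PENALTY
        t = sims["_t"]
        for d in ds:
            # normalize by the maximum over the sampled time points, exactly
            # as blot densitometry (and the fixture generator) would
            sim_at = np.interp(d.times_s, t, sims[d.name])
            m = float(np.max(sim_at))
            if m > 0:
                sim_at = sim_at / m
            total += d.weight * float(np.mean((sim_at - d.values) ** 2))
    return total


# ---------------------------------------------------------------------------
# generalized pattern search


@dataclass
class FitResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_eval: int
    converged: bool
    history: list[tuple[int, float, float]] = field(default_factory=list)
    # (iteration, objective, mesh)
    free_params: list[str] | None = None

    @property
    def mesh_history(self) -> list[float]:
        return [m for (_, _, m) in self.history]

    def as_dict(self) -> dict:
        out = {
            "objective": self.fun,
            "n_iter": self.n_iter,
            "n_eval": self.n_eval,
            "converged": self.converged,
        }
        if self.free_params:
            out["parameters"] = dict(zip(self.free_params, map(float, self.x)))
        return out


def pattern_search(
    fun,
    x0,
    bounds,
    *,
    mesh0: float = 0.25,
    tol: float = 1e-3,
    max_iter: int = 200,
    expand: float = 2.0,
    contract: float = 0.5,
) -> FitResult:
    """Generalized pattern search with coordinate polls (+ before -).

    Operates directly on the supplied coordinates (callers fit in log10
    space); polls are clipped to the box bounds.  The incumbent objective is
    nonincreasing over accepted iterations; terminates when the mesh falls
    below ``tol`` or the iteration budget is reached.
    """
    x = np.asarray(x0, dtype=float).copy()
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValidationError("invalid bounds: low >= high")
    if np.any(x < lo) or np.any(x > hi):
        raise ValidationError("x0 outside bounds")
    mesh = float(mesh0)
    f = float(fun(x))
    n_eval = 1
    history = [(0, f, mesh)]
    converged = False
    for it in range(1, max_iter + 1):
        if mesh < tol:
            converged = True
            break
        improved = False
        for i in range(len(x)):
            for sign in (+1.0, -1.0):
                xt = x.copy()
                xt[i] = np.clip(xt[i] + sign * mesh, lo[i], hi[i])
                if xt[i] == x[i]:
                    continue
                ft = float(fun(xt))
                n_eval += 1
                if ft < f:
                    x, f = xt, ft
                    improved = True
                    break
            if improved:
                break
        mesh = mesh * expand if improved else mesh * contract
        history.append((it, f, mesh))
    return FitResult(
        x=x, fun=f, n_iter=len(history) - 1, n_eval=n_eval,
        converged=converged or mesh < tol, history=history,
    )


def fit_model(
    model: ModelSpec,
    datasets: list[TimeCourseDataset],
    free_params: list[str],
    *,
    x0: dict[str, float] | None = None,
    bounds_decades: float = 2.0,
    mesh0: float = 0.25,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> FitResult:
    """Fit free parameters in log10 space with box bounds +/- decades around
    the model's current values (or the supplied start point)."""
    start = np.array(
        [np.log10(x0[p] if x0 else model.params[p]) for p in free_params]
    )
    bounds = [(s - bounds_decades, s + bounds_decades) for s in start]

    def f(logx):
        return objective(model, datasets, free_params, 10.0 ** np.asarray(logx))

    res = pattern_search(f, start, bounds, mesh0=mesh0, tol=tol, max_iter=max_iter)
    res = FitResult(
        x=10.0 ** res.x, fun=res.fun, n_iter=res.n_iter, n_eval=res.n_eval,
        converged=res.converged, history=res.history, free_params=list(free_params),
    )
    return res


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_fixture(
    model: ModelSpec,
    true_params: dict[str, float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    panel: tuple[tuple[str, str], ...] = FIXTURE_PANEL,
    observe_s: float = 3600.0,
) -> list[TimeCourseDataset]:
    """Simulate the fitted panel at known parameters and add measurement noise.

    Receptor-level time courses are sampled at sparse 10-15 min intervals,
    signaling time courses at 2-15 min intervals; multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` emulates densitometry
    error; everything is max-normalized.  Reproducible under ``seed``.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    overrides = dict(true_params or {})
    by_cond: dict[str, list[str]] = {}
    for name, cond in panel:
        by_cond.setdefault(cond, []).append(name)
    datasets: list[TimeCourseDataset] = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for cond, names in by_cond.items():
        sims = _simulated_series(model, cond, names, overrides, observe_s)
        t = sims["_t"]
        for name in names:
            times = np.asarray(
                RECEPTOR_TIMES_S if name.startswith("R2") else SIGNALING_TIMES_S,
                dtype=float,
            )
            times = times[times <= observe_s]
            series = np.interp(times, t, sims[name])
            if noise_cv > 0:
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(times))
                series = series * noise
            m = float(np.max(series))
            if m > 0:
                series = series / m
            datasets.append(
                TimeCourseDataset(
                    name=name, condition=cond, times_s=times, values=series,
                    source="fixture",
                )
            )
    return datasets
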