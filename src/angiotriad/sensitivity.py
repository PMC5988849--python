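"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

Parameters are sampled log-uniformly over a multiplicative range around
their nominal values (default x0.1 .. x10) with one stratified draw per
decile-like stratum; a dummy parameter with no influence on the model is
always appended as a significance yardstick.  Partial rank correlation
coefficients are computed per readout: rank-transform everything, remove
the other parameters' ranks from both the parameter and the readout by
linear regression, and correlate the residuals; significance uses the
standard t transform with N - 2 - (#controlled) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .experiments import MAX_READOUTS, Protocol, run_protocol
from .model import ModelSpec
from .ode import SimulationError
from .rulegraph import ValidationError

__all__ = [
    "SampleDesign",
    "PRCCResult",
    "lhs_sample",
    "prcc",
    "rank_parameters",
    "DEFAULT_PRCC_PARAMS",
    "DUMMY",
]

DUMMY = "dummy_parameter"

#: default parameter set for the full-model analysis: the kinetic and
#: amplitude parameters of the signaling/calcium/receptor layers, excluding
#: structural totals fixed by measurement (receptor numbers) and protocol
#: constants.
DEFAULT_PRCC_PARAMS = (
    "ksingleR2_syn", "kVEGFNRP1_on", "kVEGFR2NRP1_off", "kr2_si", "kd_RR",
    "kp_R2", "kdp_s", "kdp_i", "kdeg_i0", "kdeg_i0noP",
    "kp_SrcAxl", "kdp_SrcAxl", "kp_Axlauto", "kdp_autoAxl", "Src_0", "Axl_0",
    "kon_PI3KAxl", "koff_PI3KAxl", "PI3K_0", "kcat_PI3KPIP2", "km_PIP2PI3K",
    "PTEN_0", "kcat_PTENPIP3", "km_PIP3PTEN", "PIP2_0",
    "kcat_PLCgDAG", "kdeg_ip3", "ICRAC_amp", "Iip3R_amp", "v_SERCA",
    "IPMCA_amp", "kon_eNOSCaCaM",
)


@dataclass
class SampleDesign:
    """LHS design: log-uniform multipliers around nominal values."""

    parameters: tuple[str, ...]
    n_samples: int = 1000
    range_lo: float = 0.1
    range_hi: float = 10.0
    seed: int = 42
    include_dummy: bool = True

    def __post_init__(self) -> None:
        self.parameters = tuple(self.parameters)
        if self.range_lo <= 0 or self.range_hi <= self.range_lo:
            raise ValidationError("sampling range must be positive with hi > lo")
        if self.n_samples < 2 + len(self.parameters):
            raise ValidationError(
                "need at least 2 + #parameters samples for PRCC"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return self.parameters + ((DUMMY,) if self.include_dummy else ())


def lhs_sample(design: SampleDesign, nominal: dict[str, float] | None = None) -> pd.DataFrame:
    """Latin hypercube of multiplier columns (or absolute values if nominal
    values are supplied), one stratified draw per stratum, reproducible
    under the design seed."""
    d = len(design.names)
    sampler = qmc.LatinHypercube(d=d, seed=design.seed)
    u = sampler.random(design.n_samples)
    log_lo, log_hi = np.log10(design.range_lo), np.log10(design.range_hi)
    mult = 10.0 ** (log_lo + (log_hi - log_lo) * u)
    df = pd.DataFrame(mult, columns=list(design.names))
    if nominal is not None:
        for name in design.parameters:
            df[name] = df[name] * nominal[name]
    return df


@dataclass
class PRCCResult:
    table: pd.DataFrame  # index: parameter; columns: prcc, p_value, rank
    readout: str | None = None
    n_samples: int = 0
    n_failed: int = 0

    def value(self, name: str) -> float:
        return float(self.table.loc[name, "prcc"])

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        return bool(self.table.loc[name, "p_value"] < alpha)

    def top(self, sign: int, k: int = 10) -> list[str]:
        t = self.table[np.sign(self.table["prcc"]) == sign]
        return list(t.reindex(t["prcc"].abs().sort_values(ascending=False).index).index[:k])


def prcc(X, y, names: list[str] | None = None) -> PRCCResult:
    """Partial rank correlation of each column of X with y.

    X: (n, p) parameter matrix; y: (n,) readout vector.  Raises on constant
    or collinear columns (naming the offending pair).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("X rows and y must be aligned")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"constant column {names[j]!r}")
    R = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    # collinearity check on rank-transformed columns
    C = np.corrcoef(R, rowvar=False)
    for a in range(p):
        for b in range(a + 1, p):
            if abs(C[a, b]) > 1 - 1e-10:
                raise ValidationError(
                    f"collinear parameter columns: {names[a]!r} and {names[b]!r}"
                )
    vals = np.empty(p)
    pvals = np.empty(p)
    dof = n - 2 - (p - 1)
    if dof <= 0:
        raise ValidationError("not enough samples for the number of parameters")
    for j in range(p):
        others = np.delete(R, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(A, R[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(A, ry, rcond=None)
        res_x = R[:, j] - A @ beta_x
        res_y = ry - A @ beta_y
        denom = np.sqrt(np.sum(res_x**2) * np.sum(res_y**2))
        r = float(np.sum(res_x * res_y) / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        vals[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r**2))
            pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
    order = np.argsort(-np.abs(vals))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {"prcc": vals, "p_value": pvals, "rank": rank}, index=list(names)
    )
    return PRCCResult(table=table, n_samples=n)


def rank_parameters(
    model: ModelSpec,
    design: SampleDesign,
    readouts: tuple[str, ...] = ("pS473", "ppAkt", "pS1177"),
    protocol: Protocol | None = None,
    max_failed_fraction: float = 0.2,
    progress=None,
) -> dict[str, PRCCResult]:
    """PRCC tables per readout from LHS model runs (VEGF stimulation, no TSP1).

    Failed simulations are excluded and counted; more than the allowed
    fraction aborts with diagnostics.
    """
    for r in readouts:
        if r not in MAX_READOUTS:
            raise ValidationError(f"readout {r!r} not among peak readouts {MAX_READOUTS}")
    protocol = protocol or Protocol(tsp1_nM=0.0)
    samples = lhs_sample(design)
    n = len(samples)
    Y = np.full((n, len(readouts)), np.nan)
    failed = 0
    for i in range(n):
        overrides = {
            name: model.params[name] * samples.iloc[i][name]
            for name in design.parameters
        }
        try:
            res = run_protocol(model, protocol, param_overrides=overrides)
            for j, r in enumerate(readouts):
                Y[i, j] = res.maxima[r]
        except SimulationError:
            failed += 1
        if progress is not None:
            progress(i + 1, n)
    if failed > max_failed_fraction * n:
        raise SimulationError(
            f"{failed}/{n} samples failed (limit {max_failed_fraction:.0%}); "
            "check parameter ranges"
        )
    ok = ~np.isnan(Y).any(axis=1)
    X = samples.loc[ok, list(design.names)].to_numpy()
    out: dict[str, PRCCResult] = {}
    for j, r in enumerate(readouts):
        result = prcc(X, Y[ok, j], names=list(design.names))
        result.readout = r
        result.n_failed = failed
        out[r] = result
    return out


def ranked_tables(results: dict[str, PRCCResult]) -> dict[str, pd.DataFrame]:
    """Separate positively/negatively correlated ranked lists per readout."""
    out = {}
    for r, res in results.items():
        t = res.table.sort_values("prcc", ascending=False)
        out[r] = pd.concat(
            [
                t[t["prcc"] > 0].assign(direction="positive"),
                t[t["prcc"] < 0].sort_values("prcc").assign(direction="negative"),
            ]
        )
    return out
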