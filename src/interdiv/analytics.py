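"""Exact closed-form relations among the cell-age PDF f, the observable
interdivision-time PDF g, and the unobservable (Powell) PDF h.

In a chemostat at steady state with dilution rate D the three densities on
cycle age a obey

    f(a) = 2 D e^{-Da} - D e^{-Da} int_0^a e^{Da'} g(a') da',   f(0) = 2D,
    g(a) = 2 e^{-Da} h(a),
    f(a) = 2 D e^{-Da} [1 - int_0^a h(a') da']        (Powell's form),

with the moment identities

    <a> + tau_obs = 1/D,          tau_obs <= ln(2)/D,
    tau_obs <= <a> ln(2)/(1 - ln 2),
    <a^2> = 2 <a>/D - <tau^2>,
    int e^{-Da} h = 1/2,          int a e^{-Da} h = tau_obs / 2.

A self-similar batch culture satisfies the same relations with the
population growth rate nu_m in place of D.  All operations work on
densities tabulated on a uniform age grid; cumulative integrals use the
trapezoid rule.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "LN2", "TAU_AGE_COEF",
    "AgePDF", "MomentSummary", "RelationCheck", "RelationReport",
    "f_from_g", "batch_f_from_g", "h_from_g", "g_from_h", "f_from_h_powell",
    "check_tau_bound_D", "check_sum_identity", "check_tau_bound_age",
    "check_second_moment_identity", "synchrony_feasibility",
    "moments_from_samples",
]

LN2 = math.log(2.0)
#: coefficient in tau_obs <= coef * <a>, equal to ln2/(1-ln2) ~= 2.2589
TAU_AGE_COEF = LN2 / (1.0 - LN2)

_NORM_TOL = 1e-6


@dataclass
class AgePDF:
    """A probability density on a uniform age grid (hr, density in 1/hr).

    kind is one of {"f", "g", "h"}; rate carries the context (D or nu_m).
    """

    grid: np.ndarray
    density: np.ndarray
    kind: str = "g"
    rate: float | None = None
    n_samples: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be matching 1-D arrays")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def integral(self) -> float:
        return float(trapezoid(self.density, self.grid))

    def is_normalized(self, tol: float = _NORM_TOL) -> bool:
        return abs(self.integral - 1.0) <= tol

    def normalized(self) -> "AgePDF":
        z = self.integral
        if z <= 0:
            raise ValueError("cannot normalize a density with non-positive mass")
        return AgePDF(self.grid, self.density / z, self.kind, self.rate,
                      self.n_samples, dict(self.meta))

    def moment(self, k: int = 1) -> float:
        return float(trapezoid(self.grid**k * self.density, self.grid))

    @classmethod
    def default_grid(cls, rate: float, n_bins: int = 2000, span: float = 6.0):
        """Uniform grid covering [0, span * ln2/rate]."""
        return np.linspace(0.0, span * LN2 / rate, n_bins)


@dataclass
class MomentSummary:
    """First and second moments of f and g plus diagnostics."""

    mean_age: float
    mean_age_sq: float
    tau_obs: float
    tau_sq: float
    rate: float
    tau_uno: float | None = None
    lambda_diag: float | None = None

    def __post_init__(self):
        vals = [self.mean_age, self.mean_age_sq, self.tau_obs, self.tau_sq]
        # nan marks an unmeasured moment (e.g. no age snapshot supplied)
        if any(np.isfinite(v) and v < 0 for v in vals) or \
           any(np.isinf(v) for v in vals):
            raise ValueError("moments must be finite and >= 0")


@dataclass
class RelationCheck:
    name: str
    lhs: float
    rhs: float
    residual: float
    relative_residual: float
    passed: bool
    tolerance: float
    kind: str = "equality"      # or "inequality"


@dataclass
class RelationReport:
    checks: list

    def __bool__(self):
        return all(c.passed for c in self.checks)

    def add(self, check: RelationCheck):
        self.checks.append(check)

    def to_dict(self):
        return {"passed": bool(self), "checks": [asdict(c) for c in self.checks]}

    def to_json(self, **kw):
        return json.dumps(self.to_dict(), indent=2, **kw)


def _require_normalized(p: AgePDF, label: str):
    if not p.is_normalized(1e-3):
        raise ValueError(f"{label} must be normalized (integral = "
                         f"{p.integral:.6f})")


def _exp_weighted_cumint(grid, density, rate):
    """e^{-rate a} * int_0^a e^{rate a'} dens(a') da', overflow-safe.

    Computed piecewise as sum_j exp(-rate (a_i - a_j)) w_j so only decaying
    exponentials of age differences appear.
    """
    x = rate * grid
    if x[-1] > 700.0:
        warnings.warn("grid truncated: e^{rate*a} overflows; shorten the grid",
                      RuntimeWarning, stacklevel=3)
    # log-space trick: shift by the running max to avoid overflow
    shift = np.maximum.accumulate(x)
    inner = cumulative_trapezoid(np.exp(x - shift[-1]) * density, grid, initial=0.0)
    return np.exp(-(x - shift[-1])) * inner


def f_from_g(g: AgePDF, D: float) -> AgePDF:
    """Cell-age PDF at chemostat steady state from the observable g.

        f(a) = 2 D e^{-Da} - D e^{-Da} int_0^a e^{Da'} g(a') da'

    f(0) = 2D always; the formula integrates to exactly 1 for any
    normalized g with int e^{Da} g <= 2.  If that integral exceeds 2 the
    pair (g, D) is inconsistent with a steady state: f turns negative at
    large age and the result is flagged in ``meta`` rather than raised
    (measured g's are noisy).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    _require_normalized(g, "g")
    cum = _exp_weighted_cumint(g.grid, g.density, D)
    dens = 2.0 * D * np.exp(-D * g.grid) - D * cum
    consistent = bool(dens.min() >= -1e-9)
    f = AgePDF(g.grid, dens, kind="f", rate=D,
               meta={"steady_state_consistent": consistent})
    if not consistent:
        f.meta["min_density"] = float(dens.min())
    return f


def batch_f_from_g(g: AgePDF, nu_m: float) -> AgePDF:
    """Self-similar batch cell-age PDF; same formula with nu_m for D."""
    f = f_from_g(g, nu_m)
    f.rate = nu_m
    return f


def h_from_g(g: AgePDF, D: float) -> AgePDF:
    """Powell's unobservable PDF from the observable one: h = e^{Da} g / 2.

    For a (g, D) pair exactly consistent with a steady state the result
    integrates to 1 without renormalization; the pre-normalization mass is
    reported as ``meta['consistency_residual']`` (its distance from 1).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    _require_normalized(g, "g")
    x = D * g.grid
    if x[-1] > 700.0:
        warnings.warn("grid truncated: e^{D a} overflows on this grid",
                      RuntimeWarning, stacklevel=2)
        x = np.minimum(x, 700.0)
    raw = 0.5 * np.exp(x) * g.density
    mass = float(trapezoid(raw, g.grid))
    h = AgePDF(g.grid, raw / mass, kind="h", rate=D,
               meta={"consistency_residual": abs(mass - 1.0)})
    return h


def g_from_h(h: AgePDF, D: float) -> AgePDF:
    """Observable PDF from Powell's: g = 2 e^{-Da} h, renormalized.

    The pre-normalization mass 2 int e^{-Da} h equals 1 exactly when h is
    the unobservable PDF of a steady-state chemostat (Powell's 1/2
    integral); the residual is reported in ``meta``.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    _require_normalized(h, "h")
    raw = 2.0 * np.exp(-D * h.grid) * h.density
    mass = float(trapezoid(raw, h.grid))
    return AgePDF(h.grid, raw / mass, kind="g", rate=D,
                  meta={"consistency_residual": abs(mass - 1.0)})


def f_from_h_powell(h: AgePDF, D: float) -> AgePDF:
    """Powell's law f(a) = 2 D e^{-Da} [1 - int_0^a h(a') da'].

    Agrees with f_from_g(g_from_h(h, D), D) on the grid whenever
    g = 2 e^{-Da} h carries unit mass.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    _require_normalized(h, "h")
    H = cumulative_trapezoid(h.density, h.grid, initial=0.0)
    dens = 2.0 * D * np.exp(-D * h.grid) * (1.0 - H)
    return AgePDF(h.grid, dens, kind="f", rate=D)


def lambda_diagnostic(f: AgePDF, rate: float, tail_fraction: float = 0.05) -> float:
    """Median of e^{rate a} f(a) over the last ``tail_fraction`` of the grid.

    e^{rate a} f(a) is non-increasing and bounded below by 0, so it has a
    limit lambda >= 0; a proper h corresponds to lambda = 0.
    """
    n = max(2, int(f.grid.size * tail_fraction))
    x = rate * f.grid[-n:]
    return float(np.median(np.exp(np.minimum(x, 700.0)) * f.density[-n:]))


def _check_equality(name, lhs, rhs, tol):
    scale = max(abs(lhs), abs(rhs), 1e-300)
    resid = lhs - rhs
    rel = resid / scale
    return RelationCheck(name, float(lhs), float(rhs), float(resid),
                         float(rel), bool(abs(rel) <= tol), tol, "equality")


def _check_inequality(name, lhs, bound, tol):
    # pass iff lhs <= bound within slack tol * scale
    scale = max(abs(lhs), abs(bound), 1e-300)
    slack = bound - lhs
    return RelationCheck(name, float(lhs), float(bound), float(-slack),
                         float(-slack / scale), bool(slack >= -tol * scale),
                         tol, "inequality")


def check_tau_bound_D(tau_obs: float, D: float, tolerance: float = 0.0) -> RelationCheck:
    """tau_obs <= ln(2)/D (equality only for a Dirac g)."""
    if tau_obs <= 0 or D <= 0:
        raise ValueError("tau_obs and D must be > 0")
    return _check_inequality("tau_obs <= ln2/rate", tau_obs, LN2 / D, tolerance)


def check_sum_identity(mean_age: float, tau_obs: float, rate: float,
                       tolerance: float = 1e-6) -> RelationCheck:
    """<a> + tau_obs = 1/rate (rate = D in chemostat, nu_m in batch)."""
    if min(mean_age, tau_obs, rate) <= 0:
        raise ValueError("all arguments must be > 0")
    return _check_equality("<a> + tau_obs = 1/rate",
                           mean_age + tau_obs, 1.0 / rate, tolerance)


def check_tau_bound_age(tau_obs: float, mean_age: float,
                        tolerance: float = 0.0) -> RelationCheck:
    """tau_obs <= <a> ln2/(1 - ln2) ~= 2.259 <a>."""
    if tau_obs <= 0 or mean_age <= 0:
        raise ValueError("arguments must be > 0")
    return _check_inequality("tau_obs <= 2.259 <a>", tau_obs,
                             TAU_AGE_COEF * mean_age, tolerance)


def check_second_moment_identity(moments: MomentSummary, D: float,
                                 tolerance: float = 1e-6) -> RelationCheck:
    """<a^2> = 2 <a>/D - <tau^2>."""
    return _check_equality("<a^2> = 2<a>/rate - <tau^2>",
                           moments.mean_age_sq,
                           2.0 * moments.mean_age / D - moments.tau_sq,
                           tolerance)


def synchrony_feasibility(mean_age: float, D: float):
    """Implied interdivision-time variance of an age-synchronised population.

    Under the zero-age-variance hypothesis the identities force

        <tau^2> - tau_obs^2 = -2 <a>^2 + 4 <a>/D - 1/D^2,

    which vanishes only at D<a> in {1 - sqrt2/2, 1 + sqrt2/2}.  The larger
    root violates D<a> < 1; at the smaller root the implied tau_obs =
    sqrt2/(2D) exceeds ln2/D.  Hence an age-synchronised steady state is
    infeasible: the returned flag is always False on the valid domain.

    Returns (implied_tau_variance, feasible).
    """
    x = D * mean_age
    if not (0 < x < 1):
        raise ValueError("require 0 < D*<a> < 1 (else <a> + tau_obs = 1/D "
                         "fails with tau_obs > 0)")
    implied = -2.0 * mean_age**2 + 4.0 * mean_age / D - 1.0 / D**2
    return implied, False


def moments_from_samples(ages: np.ndarray | None, taus: np.ndarray | None,
                         rate: float) -> MomentSummary:
    """MomentSummary from raw samples (ages: snapshot, taus: at division)."""
    ages = np.asarray(ages, dtype=float) if ages is not None else None
    taus = np.asarray(taus, dtype=float) if taus is not None else None
    return MomentSummary(
        mean_age=float(ages.mean()) if ages is not None else np.nan,
        mean_age_sq=float((ages**2).mean()) if ages is not None else np.nan,
        tau_obs=float(taus.mean()) if taus is not None else np.nan,
        tau_sq=float((taus**2).mean()) if taus is not None else np.nan,
        rate=rate,
    )
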