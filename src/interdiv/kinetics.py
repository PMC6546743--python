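"""Single-cell rate laws for a rod-shaped bacterium.

Cells are modelled as cylinders of constant diameter ``d`` whose only
geometric degree of freedom is the length ``l``.  Three laws define the
single-cell dynamics:

* an elongation rate that is nearly proportional to ``l`` over most of the
  cycle and shuts off smoothly at a hard upper length ``l_bar``,
* first-order adaptation dynamics for the substrate-uptake machinery
  (two components with characteristic times ``tau1``, ``tau2``),
* a length-dependent division frequency ``gamma(l)`` that is zero below a
  minimal rupture length and diverges as ``l`` approaches ``l_bar``.

At division the mother's length (and, in the dynamic-uptake mode, her uptake
state) is redistributed between the two daughters by a symmetric Beta
fraction, so the daughters' lengths sum exactly to the mother's.

Units: lengths in metres, times in hours, ``qS`` is the specific substrate
uptake rate in g substrate per g biomass per hour.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "DivisionLawParams",
    "KernelParams",
    "MonodParams",
    "elongation_rate",
    "uptake_derivatives",
    "division_frequency",
    "sample_division_split",
    "cell_volume",
    "cell_mass",
]


@dataclass(frozen=True)
class MonodParams:
    """Parameters of the uptake laws f1, f2 (Monod) and f3 (inhibition).

    f1(S) = qmax1 * S / (K1 + S)
    f2(S) = qmax2 * S / (K2 + S)
    f3(q) = 1 / (1 + q / K_I)

    Rates in g/g/hr, concentrations in g/L.  Only used in the dynamic
    uptake mode; the constant-saturating mode bypasses them entirely.
    """

    qmax1: float = 0.5
    K1: float = 0.05
    qmax2: float = 0.2
    K2: float = 0.05
    K_I: float = 1.0

    def f1(self, S):
        return self.qmax1 * S / (self.K1 + S)

    def f2(self, S):
        return self.qmax2 * S / (self.K2 + S)

    def f3(self, q):
        return 1.0 / (1.0 + q / self.K_I)


@dataclass(frozen=True)
class KineticParams:
    """Cell geometry, yield and uptake parameters.

    rho   -- cell mass density (kg m^-3)
    d     -- cell diameter (m); cells are cylinders of constant diameter
    Y_SX  -- substrate-to-biomass yield ratio (g substrate / g biomass)
    eta   -- elongation shape exponent (dimensionless, >= 0)
    l_bar -- maximum cell length (m); hard upper bound, null flux there
    tau1, tau2 -- uptake adaptation times (hr)
    monod -- parameters of f1, f2, f3 (dynamic mode only)
    qS_mode -- "constant-saturating" (single constant specific uptake rate)
               or "dynamic" (two-component relaxation dynamics)
    qS_constant -- the constant specific uptake rate (g/g/hr) used in
               constant-saturating mode; may be resolved from "auto" by the
               config loader through the renewal calibration
    """

    rho: float = 1.0e3
    d: float = 1.0e-6
    Y_SX: float = 1.0 / 0.42
    eta: float = 0.05
    l_bar: float = 18.0e-6
    tau1: float = 25.0 / 3600.0
    tau2: float = 5.0 / 3600.0
    monod: MonodParams = field(default_factory=MonodParams)
    qS_mode: str = "constant-saturating"
    qS_constant: float | None = None

    def __post_init__(self):
        for name in ("rho", "d", "Y_SX", "l_bar", "tau1", "tau2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KineticParams.{name} must be > 0")
        if self.eta < 0:
            raise ValueError("KineticParams.eta must be >= 0")
        if self.qS_mode not in ("constant-saturating", "dynamic"):
            raise ValueError(f"unknown qS_mode {self.qS_mode!r}")

    @property
    def cross_section(self) -> float:
        return np.pi * self.d**2 / 4.0


@dataclass(frozen=True)
class DivisionLawParams:
    """Division-frequency law gamma(l).

    gamma(l) = (1/T) * [(l_bar-l)^kappa - (l_bar-l_inf)^kappa]
                     / [(l_bar-l_c)^kappa - (l_bar-l_inf)^kappa]
    on [l_inf, l_bar), and 0 elsewhere.

    T     -- time constant (hr); gamma(l_c) = 1/T
    l_inf -- minimal length at rupture (m)
    l_c   -- characteristic division length (m)
    kappa -- shape exponent; kappa < 0 makes gamma diverge at l_bar
    """

    T: float = 2.0
    l_inf: float = 7.0e-6
    l_c: float = 11.0e-6
    kappa: float = -0.96

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("DivisionLawParams.T must be > 0")
        if not (0 < self.l_inf < self.l_c):
            raise ValueError("require 0 < l_inf < l_c")

    def validate_against(self, kin: KineticParams) -> None:
        """Joint invariants with the kinetic parameters.

        ``-kappa + eta > 1`` guarantees the cumulative division hazard
        diverges before l_bar faster than elongation can deliver cells
        there, i.e. every cell divides before reaching l_bar.
        """
        if not (self.l_c < kin.l_bar):
            raise ValueError("require l_c < l_bar")
        if not (-self.kappa + kin.eta > 1.0):
            raise ValueError(
                f"ill-posed configuration: -kappa + eta = "
                f"{-self.kappa + kin.eta:.4g} must exceed 1"
            )


@dataclass(frozen=True)
class KernelParams:
    """Symmetric-Beta redistribution kernel.

    A daughter receives a fraction x ~ Beta(alpha, alpha) of the mother's
    length; the other daughter receives 1 - x.  The same (independently
    drawn) law splits the uptake state in the dynamic mode.  The kernel is
    symmetric about 1/2 and normalized by construction.
    """

    alpha: float = 20.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("KernelParams.alpha must be > 0")


def cell_volume(l, p: KineticParams):
    """Cylinder volume pi d^2/4 * l (m^3)."""
    return p.cross_section * np.asarray(l)


def cell_mass(l, p: KineticParams):
    """Cell mass rho * V (kg)."""
    return p.rho * cell_volume(l, p)


def elongation_rate(l, qS, p: KineticParams):
    """Length growth rate dl/dt (m/hr).

        dl/dt = (qS / Y_SX) * l * (1 - l/l_bar)^eta

    where ``qS`` is the specific substrate uptake rate (g/g/hr), so that
    elongation is nearly proportional to ``l`` (exponential growth) over
    most of the cycle — the close-to-zero exponent ``eta`` only bends the
    law down near the maximal length, where the rate vanishes.  Written in
    terms of the total per-cell uptake Q = qS * rho * V(l), this is
    dl/dt = Q/(rho V Y_SX) * l * (1 - l/l_bar)^eta.

    Raises ValueError if any length is outside (0, l_bar] or qS < 0.
    """
    l = np.asarray(l, dtype=float)
    qS = np.asarray(qS, dtype=float)
    if np.any(l <= 0) or np.any(l > p.l_bar):
        raise ValueError("length must lie in (0, l_bar]")
    if np.any(qS < 0):
        raise ValueError("qS must be >= 0")
    rate = (qS / p.Y_SX) * l * (1.0 - l / p.l_bar) ** p.eta
    return rate


def uptake_derivatives(qS1, qS2, S, p: KineticParams):
    """Relaxation dynamics of the two uptake components (g/g/hr per hr).

        dqS1/dt = (f1(S) - qS1) / tau1
        dqS2/dt = (f2(S) f3(qS1) - qS2) / tau2

    The first component relaxes toward the Monod rate f1(S); the second
    toward f2(S) damped by the inhibition factor f3(qS1).
    """
    qS1 = np.asarray(qS1, dtype=float)
    qS2 = np.asarray(qS2, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(qS1 < 0) or np.any(qS2 < 0) or np.any(S < 0):
        raise ValueError("qS1, qS2 and S must be >= 0")
    d1 = (p.monod.f1(S) - qS1) / p.tau1
    d2 = (p.monod.f2(S) * p.monod.f3(qS1) - qS2) / p.tau2
    return d1, d2


def division_frequency(l, p: DivisionLawParams, l_bar: float):
    """Division frequency gamma(l) in hr^-1 (vectorized, total on l >= 0).

    Zero below l_inf, equals 1/T at l_c, and (for kappa < 0) increases
    without bound as l approaches l_bar.
    """
    l = np.asarray(l, dtype=float)
    scalar = l.ndim == 0
    l = np.atleast_1d(l)
    out = np.zeros_like(l)
    m = (l >= p.l_inf) & (l < l_bar)
    den = (l_bar - p.l_c) ** p.kappa - (l_bar - p.l_inf) ** p.kappa
    out[m] = (((l_bar - l[m]) ** p.kappa) - (l_bar - p.l_inf) ** p.kappa) / den / p.T
    return out[0] if scalar else out


def _beta_fractions(alpha: float, n: int, rng: np.random.Generator):
    return rng.beta(alpha, alpha, size=n)


def sample_division_split(mother, k: KernelParams, rng: np.random.Generator,
                          l_inf: float, l_bar: float):
    """Split a mother cell into two daughters.

    ``mother`` is any object with attributes ``length``, ``qS1``, ``qS2``.
    Returns two dicts of daughter fields.  The length fraction
    x ~ Beta(alpha, alpha) gives daughter lengths x*l and (1-x)*l, summing
    exactly to the mother's length.  An independent symmetric-Beta fraction
    splits the (extensive) uptake state the same way; since the per-cell
    uptake Q is qS * mass and mass splits with the length fraction x, the
    daughters' specific rates become qS * y/x and qS * (1-y)/(1-x).
    """
    l = float(mother.length)
    if not (l_inf < l < l_bar):
        raise ValueError("mother length must lie in (l_inf, l_bar)")
    x = float(_beta_fractions(k.alpha, 1, rng)[0])
    y = float(_beta_fractions(k.alpha, 1, rng)[0])
    qS1 = float(getattr(mother, "qS1", 0.0))
    qS2 = float(getattr(mother, "qS2", 0.0))
    y2 = float(_beta_fractions(k.alpha, 1, rng)[0])
    a = dict(length=x * l, qS1=qS1 * y / x, qS2=qS2 * y2 / x, age=0.0)
    b = dict(length=(1.0 - x) * l, qS1=qS1 * (1.0 - y) / (1.0 - x),
             qS2=qS2 * (1.0 - y2) / (1.0 - x), age=0.0)
    return a, b
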