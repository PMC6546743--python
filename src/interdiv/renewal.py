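"""Deterministic renewal (birth-length eigenvalue) companion of the simulator.

A cell born at length x elongates deterministically, dl/dt = v(l), and
divides with hazard gamma(l).  Along the length axis the survival against
division from x to y is exp(-(G(y)-G(x))) with G(l) = int gamma/v dl, and
the age accumulated is A(y)-A(x) with A(l) = int dl/v.  Discounting each
division event by exp(-nu * age) and splitting the division length with the
symmetric-Beta kernel yields a positive linear operator on birth-length
densities,

    (M_nu psi)(x') = 2 * int int psi(x) k(y|x) e^{-nu a(x,y)} B(x'|y) dy dx,

whose leading eigenvalue rho(nu) is decreasing in nu.  The population's
Malthusian rate is the root rho(nu) = 1.  In a chemostat, nu is the
dilution rate D (uniform washout discounts lineages at exactly rate D), so
a steady state exists iff rho(D) = 1 — which pins down the specific uptake
rate qS.  The same root condition with nu = nu_m calibrates batch growth.

This module is the noise-free cross-check for the Monte-Carlo engine: it
predicts the growth rate, the age-at-division density g and its moments
without sampling error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import beta as _beta

from .kinetics import (DivisionLawParams, KernelParams, KineticParams,
                       division_frequency, elongation_rate)

__all__ = ["RenewalModel", "calibrate_uptake_rate"]


def _default_grid(l_bar: float):
    # dense geometric refinement near l_bar where gamma diverges
    lin = np.linspace(l_bar / 60.0, l_bar * 11.0 / 12.0, 800)
    edge = l_bar - np.geomspace(l_bar / 12.0, l_bar * 1e-4, 220)
    return np.unique(np.concatenate([lin, edge]))


@dataclass
class RenewalModel:
    """Renewal eigenproblem for one (kinetics, division law, kernel) triple."""

    kinetics: KineticParams
    division: DivisionLawParams
    kernel: KernelParams
    n_power_iter: int = 400

    def __post_init__(self):
        self.grid = _default_grid(self.kinetics.l_bar)
        g = division_frequency(self.grid, self.division, self.kinetics.l_bar)
        self._gamma = g
        self._dy = np.gradient(self.grid)
        # Beta daughter-split matrix: row = division length y, col = birth x'
        Y = self.grid[:, None]
        Xp = self.grid[None, :]
        B = _beta.pdf(Xp / Y, self.kernel.alpha, self.kernel.alpha) / Y
        self._B = B * self._dy[None, :]

    def _paths(self, qS: float):
        v = elongation_rate(self.grid, qS, self.kinetics)
        G = cumulative_trapezoid(self._gamma / v, self.grid, initial=0.0)
        A = cumulative_trapezoid(1.0 / v, self.grid, initial=0.0)
        return v, G, A

    def _kernel_matrix(self, nu: float, qS: float):
        """K[i, j] = hazard(y_j)/v(y_j) * exp(-(dG + nu dA)) * dy_j for y >= x."""
        v, G, A = self._paths(qS)
        W = G + nu * A
        E = W[:, None] - W[None, :]          # W(x) - W(y), >= -inf for y >= x
        idx = np.arange(self.grid.size)
        E = np.where(idx[None, :] >= idx[:, None], E, -np.inf)
        K = np.exp(E) * (self._gamma / v)[None, :] * self._dy[None, :]
        return K, A

    def leading_eigen(self, nu: float, qS: float):
        """Leading eigenvalue and birth-length eigenfunction of M_nu."""
        K, _ = self._kernel_matrix(nu, qS)
        l = self.grid
        psi = np.exp(-(((l - l.mean() / 2.0) / (l.mean() / 4.0)) ** 2))
        psi /= psi.sum()
        lam = 1.0
        for _ in range(self.n_power_iter):
            nxt = 2.0 * (psi @ K) @ self._B
            lam_new = nxt.sum()
            nxt /= lam_new
            if np.abs(nxt - psi).max() < 1e-12 and abs(lam_new - lam) < 1e-12:
                psi, lam = nxt, lam_new
                break
            psi, lam = nxt, lam_new
        return lam, psi

    def malthusian_rate(self, qS: float, bracket=(1e-4, 5.0)) -> float:
        """Growth rate nu with unit leading eigenvalue, given qS."""
        f = lambda nu: self.leading_eigen(nu, qS)[0] - 1.0
        return brentq(f, *bracket, xtol=1e-10)

    def calibrate_qS(self, nu_target: float, bracket=(1e-2, 2.0)) -> float:
        """Specific uptake rate qS (g/g/hr) such that the Malthusian rate
        equals ``nu_target``.  Root-found in log space (qS spans decades)."""
        f = lambda lq: self.leading_eigen(nu_target, 10.0**lq)[0] - 1.0
        lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
        return 10.0 ** brentq(f, lo, hi, xtol=1e-10)

    def division_statistics(self, nu: float, qS: float):
        """Discount-weighted division statistics at growth rate nu.

        Returns a dict with tau_obs (mean age at recorded rupture), the
        mean division length, the discounted-offspring integral
        int e^{-nu a} h(a) da (equals 1/2 when rho(nu) = 1), and a sampled
        age-at-division density (ages, pdf) on an age grid.
        """
        K, A = self._kernel_matrix(nu, qS)
        lam, psi = self.leading_eigen(nu, qS)
        Wt = psi[:, None] * K          # joint weight over (birth x, division y)
        tot = Wt.sum()
        age = A[None, :] - A[:, None]
        age = np.where(np.isfinite(age), age, 0.0)
        tau_obs = float((Wt * age).sum() / tot)
        mean_ldiv = float((Wt.sum(axis=0) * self.grid).sum() / tot)
        ages = age[Wt > 0]
        wts = Wt[Wt > 0]
        amax = ages.max()
        bins = np.linspace(0.0, amax, 400)
        hist, edges = np.histogram(ages, bins=bins, weights=wts, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        return {
            "eigenvalue": float(lam),
            "tau_obs": tau_obs,
            "mean_division_length": mean_ldiv,
            "discounted_offspring": float(tot),
            "g_grid": centers,
            "g_density": hist,
        }


def calibrate_uptake_rate(kinetics: KineticParams,
                          division: DivisionLawParams,
                          kernel: KernelParams,
                          nu_target: float) -> float:
    """Convenience wrapper: qS (g/g/hr) giving Malthusian rate nu_target."""
    model = RenewalModel(kinetics, division, kernel)
    return model.calibrate_qS(nu_target)
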