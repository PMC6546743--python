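"""Seeded generators of synthetic test inputs.

Closed-form age distributions (Dirac, exponential, gamma/Pearson type-III,
truncated Gaussian) paired with exact grid densities, clipped-Gaussian
initial-population specs, and deliberately mis-attributed datasets —
interdivision times sampled from Powell's unobservable PDF h but analysed
as if they were observable g samples, the classic confusion this package
exists to untangle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import trapezoid

from .analytics import AgePDF, LN2
from .simulate import InitSpec

__all__ = [
    "DistributionSpec",
    "make_initial_population_spec",
    "sample_from_spec",
    "make_misattributed_dataset",
    "sample_g_from_h_spec",
]

_FAMILIES = ("dirac", "exponential", "gamma", "pearson3", "truncated-gaussian")


@dataclass(frozen=True)
class DistributionSpec:
    """A closed-form distribution on [0, inf) (ages / interdivision times).

    family: one of dirac(loc), exponential(rate), gamma|pearson3(shape,
    scale), truncated-gaussian(mean, sd, lo, hi).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {_FAMILIES}")
        self._frozen()  # validates parameters eagerly

    def _frozen(self):
        p = self.params
        if self.family == "dirac":
            loc = p["loc"]
            if loc < 0:
                raise ValueError("dirac loc must be >= 0")
            return None
        if self.family == "exponential":
            if p["rate"] <= 0:
                raise ValueError("exponential rate must be > 0")
            return stats.expon(scale=1.0 / p["rate"])
        if self.family in ("gamma", "pearson3"):
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError("gamma shape and scale must be > 0")
            return stats.gamma(a=p["shape"], scale=p["scale"])
        lo, hi = p.get("lo", 0.0), p.get("hi", np.inf)
        if not (lo < hi) or p["sd"] <= 0:
            raise ValueError("truncated-gaussian requires lo < hi, sd > 0")
        a, b = (lo - p["mean"]) / p["sd"], (hi - p["mean"]) / p["sd"]
        return stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"])

    @property
    def mean(self) -> float:
        if self.family == "dirac":
            return float(self.params["loc"])
        return float(self._frozen().mean())

    def upper_quantile(self, q: float = 1e-8) -> float:
        """Age beyond which only mass q remains (grid-span helper)."""
        if self.family == "dirac":
            return float(self.params["loc"])
        return float(self._frozen().ppf(1.0 - q))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "dirac":
            return np.full(n, float(self.params["loc"]))
        return self._frozen().rvs(size=n, random_state=rng)

    def pdf_on_grid(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if self.family == "dirac":
            # unit mass in the bin containing loc (trapezoid-normalized spike)
            loc = float(self.params["loc"])
            i = int(np.clip(np.searchsorted(grid, loc), 1, grid.size - 2))
            dens = np.zeros_like(grid)
            dens[i] = 1.0
            z = trapezoid(dens, grid)
            return dens / z
        return self._frozen().pdf(grid)


def make_initial_population_spec(mean_length: float, sd_length: float,
                                 mean_age: float = 0.0, sd_age: float = 0.0,
                                 bounds: tuple = (2.0e-6, 1.6e-5)) -> InitSpec:
    """Clipped-Gaussian initial condition for the simulator.

    Clipping is rejection sampling (redraw until inside bounds), i.e. a
    truncated Gaussian: clamping to the bounds would pile unphysical atoms
    of probability onto the boundary lengths.
    """
    lo, hi = bounds
    return InitSpec(mean_length=mean_length, sd_length=sd_length,
                    min_length=lo, max_length=hi,
                    mean_age=mean_age, sd_age=sd_age)


def sample_from_spec(spec: DistributionSpec, n: int, seed: int = 0,
                     grid: np.ndarray | None = None, kind: str = "g",
                     rate: float | None = None):
    """Draw ``n`` samples plus the exact density on a grid.

    The paired output calibrates estimators: histogram the samples and
    compare against the exact AgePDF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = spec.sample(n, rng)
    if grid is None:
        hi = max(float(np.max(samples)) * 1.2, spec.upper_quantile(), 1.0)
        grid = np.linspace(0.0, hi, 8001)
    exact = AgePDF(grid, spec.pdf_on_grid(grid), kind=kind, rate=rate)
    return samples, exact


def make_misattributed_dataset(h_spec: DistributionSpec, D: float, n: int,
                               seed: int = 0) -> np.ndarray:
    """Interdivision times drawn from the UNOBSERVABLE PDF h.

    Analysing these as if they were observable ages-at-rupture (g samples)
    reproduces the classic mis-specification: since g = 2 e^{-Da} h puts
    more weight on short times, h-samples are biased long, so
    <a> + tau = 1/D fails from above and the sample mean tends to exceed
    ln(2)/D (tau_uno >= ln2/D >= tau_obs).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    rng = np.random.default_rng(seed)
    return h_spec.sample(n, rng)


def sample_g_from_h_spec(h_spec: DistributionSpec, D: float, n: int,
                         seed: int = 0, grid: np.ndarray | None = None):
    """Samples from the observable g implied by h: g(a) ∝ e^{-Da} h(a).

    Inverse-CDF sampling on a fine grid.  The control arm of the
    mis-specification experiment: these samples DO satisfy the observable
    identities at rate D (exactly so when 2 int e^{-Da} h = 1).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    rng = np.random.default_rng(seed)
    if grid is None:
        hi = max(h_spec.mean * 8.0, 4.0 * LN2 / D)
        grid = np.linspace(0.0, hi, 20001)
    raw = np.exp(-D * grid) * h_spec.pdf_on_grid(grid)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (raw[1:] + raw[:-1])
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)
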