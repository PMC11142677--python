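"""Mean-field analytical layer for the Red Queen equilibrium.

In the weak-erosion limit the fraction of active targets of an allele at
frequency ``f`` erodes as ``d theta/dt = -rho f theta`` with
``rho = N v d / (2 h) = 4 N v g`` and a net per-meiosis conversion rate
``g = d / (8 h)``. The frequency-weighted cumulated time
``z(t) = rho * Int_0^t f dt'`` is the allele's *intrinsic age*, an analytical
proxy for its cumulated erosion ``1 - theta``. The linearized frequency
dynamics couple an age term with slope ``alpha`` (log fitness response to
erosion) and a dosage term with coefficient ``sigma0``; the equilibrium
regime is predicted from ``4Nu`` (mutational input) and ``sigma0 * tau``
(cumulated homozygote advantage over one allele lifetime, ``tau`` being the
mean time between successive invasions).

``alpha`` is estimated numerically (fresh homozygote, sites eroded in
decreasing-affinity order, finite-difference slope of ``ln w``). Closed-form
equilibrium approximations for mean erosion, diversity and tau exist in the
underlying theory but are exposed only as user-registrable formula plugins
(``APPROXIMATIONS``); none is enabled by default, and ``tau`` is measured
empirically from trajectories as the mean spacing between generations at
which a new allele first exceeds the invasion threshold frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .summary_stats import fertility, moments, q_hom, sigma0

__all__ = ["MeanFieldParams", "erosion_ode", "intrinsic_age", "estimate_alpha",
           "measure_tau", "regime_predictor", "meanfield_report",
           "APPROXIMATIONS"]

#: optional closed-form equilibrium formulas: name -> callable(MeanFieldParams)
APPROXIMATIONS: dict[str, Callable] = {}


@dataclass
class MeanFieldParams:
    """Parameters of the mean-field description.

    ``g = d / (8h)`` is the net conversion rate per site per meiosis and
    ``rho = N v d / (2h) = 4 N v g`` the net erosion rate per generation.
    """

    N: int
    u: float
    v: float
    d: float
    h: int
    alpha: float | None = None
    sigma0: float | None = None

    @property
    def g(self) -> float:
        return self.d / (8.0 * self.h)

    @property
    def rho(self) -> float:
        return self.N * self.v * self.d / (2.0 * self.h)

    @property
    def fourNu(self) -> float:
        return 4.0 * self.N * self.u


def erosion_ode(theta: float, f: float, params: MeanFieldParams) -> float:
    """Instantaneous erosion rate d(theta)/dt = -rho * f * theta."""
    return -params.rho * f * theta


def intrinsic_age(frequency_trajectory: np.ndarray,
                  params: MeanFieldParams, dt: float = 1.0) -> np.ndarray:
    """Intrinsic age z(t) = rho * Int f dt (trapezoidal accumulation).

    Returns z at every point of the input trajectory (z[0] = 0).
    """
    f = np.asarray(frequency_trajectory, dtype=float)
    if f.size == 0:
        return np.zeros(0)
    return params.rho * cumulative_trapezoid(f, dx=dt, initial=0.0)


def estimate_alpha(config, n_rep: int = 100, step: float = 0.01,
                   rng: np.random.Generator | None = None,
                   sampler=None) -> float:
    """Numerical slope alpha = -d ln w / dz at z -> 0 for fresh homozygotes.

    For each replicate allele the top fraction ``z`` of sites by affinity is
    inactivated (high-affinity sites are the ones preferentially converted),
    and alpha is the central finite-difference slope of ``ln w(z)`` around
    ``z = step``, averaged over ``n_rep`` alleles. Dosage is not part of the
    no-dosage mean-field layer, so occupancies use c = 1.
    """
    rng = np.random.default_rng() if rng is None else rng
    h, d = config.h, config.d
    if sampler is None:
        from .summary_stats import _fresh_allele_distribution
        dist = _fresh_allele_distribution(config)
        sampler = lambda r, n: dist.sample(n, r)
    acc = 0.0
    for _ in range(n_rep):
        y = np.sort(sampler(rng, h))[::-1]
        lw = []
        for z in (0.0, 2.0 * step):
            active = np.ones(h)
            active[: int(round(z * h))] = 0.0
            w = fertility(q_hom(moments(y, 1.0, active=active)), d)
            lw.append(np.log(max(w, 1e-300)))
        acc += -(lw[1] - lw[0]) / (2.0 * step)
    return acc / n_rep


def measure_tau(invasion_generations) -> float:
    """Mean time between successive invasions (first crossings of the
    invasion threshold by new alleles); NaN with fewer than two events."""
    t = np.asarray(sorted(invasion_generations), dtype=float)
    if t.size < 2:
        return float("nan")
    return float(np.mean(np.diff(t)))


def regime_predictor(params: MeanFieldParams, tau: float) -> str:
    """Predicted equilibrium regime from 4Nu and sigma0 * tau.

    monomorphic if 4Nu <= 10; else polymorphic if sigma0 * tau < 3; else
    eviction (dosage-driven elimination of minor alleles). With sigma0 = 0
    (no dosage) eviction is never predicted.
    """
    if params.sigma0 is None:
        raise ValueError("params.sigma0 is required for the regime predictor")
    if not params.fourNu > 10.0:
        return "monomorphic"
    if params.sigma0 * tau < 3.0:
        return "polymorphic"
    return "eviction"


def meanfield_report(config, tau: float | None = None,
                     n_rep: int = 100,
                     rng: np.random.Generator | None = None) -> dict:
    """Assemble the mean-field summary for a simulation configuration.

    ``tau`` is normally measured from a simulation trajectory; if omitted the
    regime is classified only when 4Nu <= 10 (where tau is irrelevant).
    Any registered APPROXIMATIONS are evaluated and included by name.
    """
    rng = np.random.default_rng() if rng is None else rng
    s0_dos = sigma0(config, n_rep=n_rep, rng=rng)
    p = MeanFieldParams(N=config.N, u=config.u, v=config.v, d=config.d,
                        h=config.h, sigma0=s0_dos)
    p.alpha = estimate_alpha(config, n_rep=n_rep, rng=rng)
    rep = {
        "g": p.g,
        "rho": p.rho,
        "alpha": p.alpha,
        "sigma0": p.sigma0,
        "fourNu": p.fourNu,
        "tau": tau if tau is not None else float("nan"),
        "sigma0_tau": (p.sigma0 * tau) if tau is not None else float("nan"),
    }
    if tau is not None or p.fourNu <= 10.0:
        rep["regime"] = regime_predictor(p, rep["tau"])
    else:
        rep["regime"] = "unknown (tau not supplied)"
    for name, fn in APPROXIMATIONS.items():
        rep[name] = fn(p)
    return rep
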